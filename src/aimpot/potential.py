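"""Assembled potential: U_Total = U_Local + U_Disp + U_Coul.

The learned short-range term supplies the partial charges that feed the
electrostatics, so forces are computed as the exact gradient of the whole
implemented energy — including the charge-equilibration and
coordination-number chains — through the autodiff graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .core import (ModelConfig, forward_batch, init_params, load_checkpoint,
                   save_checkpoint, wrap_params)
from .longrange import CoulombSpec, D3Params, coulomb_graph, d3_energy_graph
from .system import MolecularSystem
from .units import species_index


@dataclass
class EnergyBreakdown:
    """Prediction record: energy terms (eV), charges (e), forces (eV/Å)."""

    u_local: float
    u_coul: float
    u_disp: float
    u_total: float
    charges: np.ndarray
    forces: np.ndarray | None = None
    members: dict | None = None    # per-member stacks when ensembled


class NeuralPotential:
    """A trained (or freshly initialized) model bound to its physics terms.

    ``long_range_cutoff`` (Å) engages for periodic systems; isolated
    molecules use the full pair sums.
    """

    def __init__(self, params: dict | None = None,
                 config: ModelConfig | None = None,
                 coulomb: CoulombSpec | None = None,
                 d3: D3Params | str | None = "b97-3c",
                 long_range_cutoff: float = 15.0):
        self.config = config or ModelConfig()
        self.params = params if params is not None else init_params(self.config)
        self.coulomb = coulomb or CoulombSpec(mode="direct")
        if isinstance(d3, str):
            d3 = D3Params.load(d3)
        self.d3 = d3
        self.long_range_cutoff = long_range_cutoff

    # -- persistence --------------------------------------------------------
    def save(self, path, extra: dict | None = None):
        meta = {"coulomb": self.coulomb.to_dict(),
                "long_range_cutoff": self.long_range_cutoff}
        meta.update(extra or {})
        save_checkpoint(path, self.params, self.config, extra=meta)

    @classmethod
    def load(cls, path, d3: D3Params | str | None = "b97-3c"):
        params, config, extra = load_checkpoint(path)
        coulomb = CoulombSpec.from_dict(extra["coulomb"]) \
            if "coulomb" in extra else None
        return cls(params=params, config=config, coulomb=coulomb, d3=d3,
                   long_range_cutoff=extra.get("long_range_cutoff", 15.0))

    # -- batched graph evaluation (shared by predict / training) ------------
    def batch_graph(self, zidx: np.ndarray, coords: ad.Tensor,
                    total_charge: np.ndarray, cell=None, pbc=None,
                    params_t: dict | None = None, include_d3: bool = True):
        """Energy graph for a same-size batch; returns dict of Tensors.

        ``energy`` excludes the dispersion term when ``include_d3`` is
        False (training precomputes it per sample instead, since it has no
        learnable parameters).
        """
        pt = params_t if params_t is not None else wrap_params(self.params)
        out = forward_batch(pt, zidx, coords, total_charge, self.config,
                            cell=cell, pbc=pbc)
        periodic = pbc is not None and np.any(pbc)
        cspec = self.coulomb
        if periodic and cspec.mode == "direct":
            cspec = CoulombSpec(mode="dsf",
                                cutoff=min(self.long_range_cutoff,
                                           0.45 * float(np.min(cell))),
                                alpha=self.coulomb.alpha)
        u_coul = coulomb_graph(out["charges"], out["r"], out["offdiag"], cspec)
        u_disp = None
        if include_d3 and self.d3 is not None:
            u_disp = d3_energy_graph(
                coords, zidx, self.d3, cell=cell, pbc=pbc,
                cutoff=self.long_range_cutoff if periodic else None)
        total = out["energy_local"] + u_coul
        if u_disp is not None:
            total = total + u_disp
        return {"u_local": out["energy_local"], "u_coul": u_coul,
                "u_disp": u_disp, "energy": total,
                "charges": out["charges"], "aim": out["aim"]}

    # -- public single-system interface --------------------------------------
    def predict(self, system: MolecularSystem,
                with_forces: bool = True) -> EnergyBreakdown:
        zidx = species_index(system.atomic_numbers)[None]
        coords = ad.tensor(system.coords[None], requires_grad=with_forces)
        pbc = system.pbc if (system.pbc is not None and system.pbc.any()) \
            else None
        g = self.batch_graph(zidx, coords, np.array([system.charge]),
                             cell=system.cell, pbc=pbc)
        forces = None
        if with_forces:
            forces = -ad.grad(ad.sum_(g["energy"]), coords).data[0]
        u_local = float(g["u_local"].data[0])
        u_coul = float(g["u_coul"].data[0])
        u_disp = float(g["u_disp"].data[0]) if g["u_disp"] is not None else 0.0
        return EnergyBreakdown(u_local=u_local, u_coul=u_coul, u_disp=u_disp,
                               u_total=u_local + u_coul + u_disp,
                               charges=g["charges"].data[0].copy(),
                               forces=forces)

    def forces(self, system: MolecularSystem) -> np.ndarray:
        return self.predict(system, with_forces=True).forces

    def energy_forces(self, system: MolecularSystem):
        """(energy eV, forces eV/Å) — the driver protocol used by dynamics."""
        b = self.predict(system, with_forces=True)
        return b.u_total, b.forces


def ensemble_predict(system: MolecularSystem, members) -> EnergyBreakdown:
    """Mean prediction and query-by-committee disagreement over members.

    Returns the member-mean breakdown; ``members['std_*']`` carries the
    unbiased standard deviation of total energy, forces and charges — the
    committee disagreement score used for active-learning selection.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("an ensemble needs at least 2 members")
    shapes = {m.config.d for m in members}
    if len(shapes) != 1:
        raise ValueError("ensemble members disagree in architecture")
    preds = [m.predict(system, with_forces=True) for m in members]
    e = np.array([p.u_total for p in preds])
    f = np.stack([p.forces for p in preds])
    q = np.stack([p.charges for p in preds])
    stats = {
        "u_total": e, "forces": f, "charges": q,
        "std_u_total": float(np.std(e, ddof=1)),
        "std_forces": np.std(f, axis=0, ddof=1),
        "std_charges": np.std(q, axis=0, ddof=1),
    }
    return EnergyBreakdown(
        u_local=float(np.mean([p.u_local for p in preds])),
        u_coul=float(np.mean([p.u_coul for p in preds])),
        u_disp=float(np.mean([p.u_disp for p in preds])),
        u_total=float(e.mean()),
        charges=q.mean(axis=0), forces=f.mean(axis=0), members=stats)
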