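"""Point-charge electrostatics: direct sum and damped-shifted-force (DSF).

Direct mode sums k_e q_i q_j / r_ij over all pairs with no cutoff — the
appropriate choice for isolated systems.  DSF mode uses the erfc-damped,
energy- and force-shifted pair potential

    phi(r) = erfc(a r)/r - erfc(a Rc)/Rc
             + [erfc(a Rc)/Rc^2 + 2a/sqrt(pi) exp(-a^2 Rc^2)/Rc] (r - Rc)

which vanishes together with its derivative at the cutoff Rc, giving O(N)
electrostatics suitable for periodic MD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfc as _erfc

from .. import autodiff as ad
from ..system import DegenerateGeometryError, MolecularSystem
from ..units import KE_COULOMB


@dataclass
class CoulombSpec:
    mode: str = "direct"          # "direct" | "dsf"
    cutoff: float = 15.0          # Å, DSF only
    alpha: float = 0.2            # Å^-1, DSF damping
    k_e: float = KE_COULOMB       # eV·Å/e²

    def __post_init__(self):
        if self.mode not in ("direct", "dsf"):
            raise ValueError(f"unknown Coulomb mode {self.mode!r}")
        if self.mode == "dsf" and self.cutoff <= 0:
            raise ValueError("DSF requires a positive cutoff")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")

    def to_dict(self):
        return {"mode": self.mode, "cutoff": self.cutoff,
                "alpha": self.alpha, "k_e": self.k_e}

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


def _dsf_shift_consts(spec: CoulombSpec):
    a, rc = spec.alpha, spec.cutoff
    e_shift = _erfc(a * rc) / rc
    f_shift = e_shift / rc + 2.0 * a / np.sqrt(np.pi) * np.exp(
        -(a * rc) ** 2) / rc
    return e_shift, f_shift


def _pair_data(coords, cell, pbc):
    d = coords[None, :, :] - coords[:, None, :]
    if pbc is not None and np.any(pbc):
        for ax in range(3):
            if pbc[ax]:
                L = cell[ax]
                d[..., ax] -= L * np.round(d[..., ax] / L)
    r = np.linalg.norm(d, axis=-1)
    return d, r


def coulomb_energy(coords: np.ndarray, charges: np.ndarray,
                   spec: CoulombSpec, cell=None, pbc=None):
    """Electrostatic energy and forces at fixed charges.

    Returns ``(energy eV, forces (N,3) eV/Å)`` where the forces are the
    exact negative gradient of the implemented pair energy with respect to
    the coordinates (charges held fixed).
    """
    coords = np.asarray(coords, dtype=np.float64)
    q = np.asarray(charges, dtype=np.float64)
    n = len(coords)
    d, r = _pair_data(coords, cell, pbc)
    np.fill_diagonal(r, np.inf)
    if np.any(r < 1e-8):
        if np.any(np.abs(np.outer(q, q)[r < 1e-8]) > 0):
            raise DegenerateGeometryError("coincident charged atoms")
        r[r < 1e-8] = np.inf
    qq = np.outer(q, q)
    if spec.mode == "direct":
        phi = 1.0 / r
        dphi = -1.0 / r ** 2                      # d(phi)/dr
    else:
        if pbc is not None and np.any(pbc):
            half = np.asarray(cell)[np.asarray(pbc)].min() / 2
            if spec.cutoff >= half:
                raise ValueError("DSF cutoff must be below half the box")
        a, rc = spec.alpha, spec.cutoff
        e_shift, f_shift = _dsf_shift_consts(spec)
        inside = r < rc
        phi = np.where(inside,
                       _erfc(a * np.minimum(r, rc)) / r - e_shift
                       + f_shift * (r - rc), 0.0)
        dphi = np.where(
            inside,
            -_erfc(a * np.minimum(r, rc)) / r ** 2
            - 2.0 * a / np.sqrt(np.pi) * np.exp(-(a * r) ** 2) / r + f_shift,
            0.0)
    energy = 0.5 * spec.k_e * np.sum(qq * phi)
    # F_i = -dE/dr_i; dr/dr_i = -d_ij/r (with d_ij = r_j - r_i)
    with np.errstate(invalid="ignore"):
        coef = np.where(np.isfinite(r), qq * dphi / r, 0.0)
    forces = spec.k_e * np.einsum("ij,ijx->ix", coef, d)
    return float(energy), forces


def coulomb_graph(q: ad.Tensor, r: ad.Tensor, offdiag: np.ndarray,
                  spec: CoulombSpec) -> ad.Tensor:
    """Autodiff Coulomb energy for a same-size batch.

    ``q``: (B, N); ``r``: (B, N, N) with safe diagonal; ``offdiag``: the
    constant off-diagonal mask from the featurizer.  Gradients flow through
    both the distances and the charges, so predicted-charge electrostatics
    contribute their full force terms.
    """
    B, N = q.shape
    qq = ad.einsum("bi,bj->bij", q, q)
    rinv = r ** -1.0
    if spec.mode == "direct":
        phi = rinv
        mask = offdiag
    else:
        a, rc = spec.alpha, spec.cutoff
        e_shift, f_shift = _dsf_shift_consts(spec)
        phi = ad.erfc(r * a) * rinv - e_shift + (r - rc) * f_shift
        mask = offdiag * (r.data < rc)
    return ad.sum_(qq * phi * mask, axis=(1, 2)) * (0.5 * spec.k_e)
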