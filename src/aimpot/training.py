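"""Weighted multi-target training of the potential.

The loss is a weighted MSE over energy, force components, partial charges,
dipole and quadrupole:

    L = w_E mean_m[((E_m - E*_m)/sqrt(N_m))^2] + w_F mean[(F - F*)^2]
      + w_q mean[(q - q*)^2] + w_D mean[(mu - mu*)^2] + w_T mean[(Th - Th*)^2]

The per-molecule energy error is divided by sqrt(N) before squaring so
per-atom energy noise weighs comparably across molecule sizes.  Weights
default to 1.0 / 0.2 / 0.05 / 0.02 for E, F, dipole, quadrupole plus a
direct charge term at 1.0: for molecules that fit inside the local cutoff
the energy provides no constraint on the charge assignment (the local head
can absorb any electrostatic contribution), so without a direct term the
charges are pinned only by the weakly weighted multipoles.  All weights
are normalized so the active set sums to 1.

Minibatches contain molecules of identical atom count; gradient
accumulation provides the effective batch; optimization is decoupled
weight-decay Adam with a reduce-on-plateau learning-rate schedule.
Dispersion carries no learnable parameters, so its per-sample energies and
forces are precomputed once and moved to the label side.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from .core import wrap_params
from .multipoles import multipoles_of
from .system import Dataset, group_by_size
from .units import species_index


@dataclass
class LossWeights:
    w_e: float = 1.0      # energy
    w_f: float = 0.2      # force components
    w_d: float = 0.05     # dipole
    w_t: float = 0.02     # quadrupole
    w_q: float = 1.0      # direct partial-charge term

    def __post_init__(self):
        vals = [self.w_e, self.w_f, self.w_d, self.w_t, self.w_q]
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be non-negative")
        if sum(vals) <= 0:
            raise ValueError("at least one loss weight must be positive")

    def normalized(self) -> "LossWeights":
        s = self.w_e + self.w_f + self.w_d + self.w_t + self.w_q
        return LossWeights(self.w_e / s, self.w_f / s, self.w_d / s,
                           self.w_t / s, self.w_q / s)


@dataclass
class TrainConfig:
    batch_size: int = 128
    accumulate: int = 1           # gradient-accumulation count
    lr: float = 1e-3
    weight_decay: float = 1e-4
    plateau_factor: float = 0.5
    plateau_patience: int = 10
    min_lr: float = 1e-5
    max_epochs: int = 100
    val_fraction: float = 0.1
    seed: int = 0
    dtype: str = "float32"        # training precision (inference is float64)
    weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        if min(self.batch_size, self.accumulate, self.max_epochs) < 1:
            raise ValueError("batch_size/accumulate/max_epochs must be >= 1")
        if self.lr <= 0 or self.plateau_factor <= 0:
            raise ValueError("lr and plateau_factor must be positive")


class AdamW:
    """Decoupled weight-decay Adam over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict):
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (
                self.m[k] / c1 / (np.sqrt(self.v[k] / c2) + self.eps)
                + self.weight_decay * params[k])


# ---------------------------------------------------------------------------
# batch assembly
# ---------------------------------------------------------------------------

class _Batch:
    """Stacked same-size samples with label arrays and multipole origins."""

    __slots__ = ("zidx", "coords", "q_total", "energy", "forces", "charges",
                 "dipole", "quad", "origin", "n", "feat")

    def __init__(self, samples, d3_cache=None, indices=None):
        systems = [s.system for s in samples]
        self.n = systems[0].n_atoms
        self.zidx = np.stack([species_index(s.atomic_numbers)
                              for s in systems])
        self.coords = np.stack([s.coords for s in systems])
        self.q_total = np.array([s.charge for s in systems], dtype=float)
        self.energy = np.array([s.energy for s in samples])
        self.forces = np.stack([s.forces for s in samples])
        self.charges = np.stack([s.charges for s in samples])
        self.origin = np.stack([s.center_of_mass() for s in systems])
        dip, quad = [], []
        for s in samples:
            if s.dipole is None or s.quadrupole is None:
                d, t = multipoles_of(s.system, s.charges)
            else:
                d, t = s.dipole, s.quadrupole
            dip.append(d)
            quad.append(t)
        self.dipole = np.stack(dip)
        self.quad = np.stack(quad)
        if d3_cache is not None and indices is not None:
            for k, gi in enumerate(indices):
                e_d3, f_d3 = d3_cache[gi]
                self.energy[k] -= e_d3
                self.forces[k] -= f_d3
        self.feat = None

    def build_features(self, basis):
        """Precompute pair features and their coordinate Jacobians.

        Training geometries are fixed, so ``g``, ``u`` and ``r`` enter the
        graph as leaves; forces are assembled by the chain rule from
        dE/dg, dE/du, dE/dr and these cached constants.  Isolated systems
        only (training samples are molecules/conformers).
        """
        c = self.coords
        B, N = c.shape[:2]
        diff = c[:, None, :, :] - c[:, :, None, :]        # r_j - r_i
        eye = np.eye(N)[None]
        r = np.sqrt((diff ** 2).sum(-1) + eye)
        mask = ((r < basis.cutoff) & (eye < 0.5)).astype(float)
        fc = 0.5 * (np.cos(np.pi * r / basis.cutoff) + 1.0)
        dfc = -0.5 * np.pi / basis.cutoff * np.sin(np.pi * r / basis.cutoff)
        dr = r[..., None] - basis.centers
        gauss = np.exp(-basis.eta * dr * dr)
        g = gauss * (fc * mask)[..., None]
        dgdr = (-2.0 * basis.eta * dr * gauss * fc[..., None]
                + gauss * dfc[..., None]) * mask[..., None]
        u = diff / r[..., None]
        # du_x/dd_y = (delta_xy - u_x u_y)/r
        jac_u = (np.eye(3)[None, None, None]
                 - u[..., :, None] * u[..., None, :]) / r[..., None, None]
        self.feat = {"g": g, "u": u, "r": r,
                     "offdiag": (eye < 0.5).astype(float),
                     "dgdr": dgdr, "jac_u": jac_u}

    def astype(self, dtype):
        """Cast all arrays (labels, geometry, cached features) in place."""
        for name in ("coords", "q_total", "energy", "forces", "charges",
                     "dipole", "quad", "origin"):
            setattr(self, name, getattr(self, name).astype(dtype))
        if self.feat is not None:
            self.feat = {k: v.astype(dtype) for k, v in self.feat.items()}
        return self


def _cached_predictions(potential, batch: _Batch, params_t,
                        need_forces=True):
    """Batch evaluation over cached features (training fast path).

    Equivalent to :func:`_batch_predictions` (tested against it); forces
    come from dE/d(g,u,r) contracted with the cached Jacobians, which
    keeps the per-step graph free of the N² featurization ops.
    """
    if batch.feat is None:
        batch.build_features(potential.config.basis)
    ft = batch.feat
    g_t = ad.tensor(ft["g"], requires_grad=need_forces)
    u_t = ad.tensor(ft["u"], requires_grad=need_forces)
    r_t = ad.tensor(ft["r"], requires_grad=need_forces)
    from .core import forward_features
    out = forward_features(params_t, batch.zidx, g_t, u_t, r_t,
                           ft["offdiag"], batch.q_total, potential.config)
    from .longrange import coulomb_graph
    u_coul = coulomb_graph(out["charges"], r_t, ft["offdiag"],
                           potential.coulomb)
    energy = out["energy_local"] + u_coul
    preds = {"energy": energy, "charges": out["charges"]}
    if need_forces:
        eg, eu, er = ad.grad(ad.sum_(energy), [g_t, u_t, r_t])
        w = ad.sum_(eg * ft["dgdr"], axis=3) + er          # (B,N,N)
        s = ad.reshape(w, (*ft["r"].shape, 1)) * ft["u"]   # (B,N,N,3)
        t = ad.einsum("bijx,bijxy->bijy", eu, ft["jac_u"])
        p = s + t
        dedr = ad.sum_(p, axis=1) - ad.sum_(p, axis=2)     # (B,N,3)
        preds["forces"] = dedr * (-1.0)
    x = batch.coords - batch.origin[:, None, :]
    q = preds["charges"]
    preds["dipole"] = ad.einsum("bi,bix->bx", q, x)
    qx = ad.reshape(q, (*q.shape, 1)) * x
    theta = ad.einsum("bix,biy->bxy", qx, x) * 1.5
    r2 = np.sum(x * x, axis=2)
    tr = ad.einsum("bi,bi->b", q, r2)
    eye = np.eye(3, dtype=x.dtype)[None]
    preds["quadrupole"] = theta - ad.reshape(tr, (-1, 1, 1)) * (0.5 * eye)
    return preds


def _batch_predictions(potential, batch: _Batch, params_t=None,
                       need_forces=True):
    """Graph evaluation of one batch; returns dict of Tensors."""
    coords = ad.tensor(batch.coords, requires_grad=True)
    g = potential.batch_graph(batch.zidx, coords, batch.q_total,
                              params_t=params_t, include_d3=False)
    preds = {"energy": g["energy"], "charges": g["charges"]}
    if need_forces:
        preds["forces"] = ad.grad(ad.sum_(g["energy"]), coords) * (-1.0)
    x = coords - batch.origin[:, None, :]
    q = g["charges"]
    preds["dipole"] = ad.einsum("bi,bix->bx", q, x)
    qx = ad.reshape(q, (*q.shape, 1)) * x
    theta = ad.einsum("bix,biy->bxy", qx, x) * 1.5
    r2 = ad.sum_(x * x, axis=2)
    tr = ad.einsum("bi,bi->b", q, r2)
    eye = np.eye(3)[None]
    preds["quadrupole"] = theta - ad.reshape(tr, (-1, 1, 1)) * (0.5 * eye)
    return preds


def loss(preds: dict, batch: _Batch, weights: LossWeights):
    """Weighted multi-target MSE; returns (scalar Tensor, per-term dict)."""
    w = weights.normalized()
    n = batch.n
    terms = {}
    de = (preds["energy"] - batch.energy) * float(1.0 / np.sqrt(n))
    terms["energy"] = ad.sum_(de * de) * (1.0 / len(batch.energy))
    if "forces" in preds and w.w_f > 0:
        df = preds["forces"] - batch.forces
        terms["forces"] = ad.sum_(df * df) * (1.0 / batch.forces.size)
    dq = preds["charges"] - batch.charges
    terms["charges"] = ad.sum_(dq * dq) * (1.0 / batch.charges.size)
    dd = preds["dipole"] - batch.dipole
    terms["dipole"] = ad.sum_(dd * dd) * (1.0 / batch.dipole.size)
    dt = preds["quadrupole"] - batch.quad
    terms["quadrupole"] = ad.sum_(dt * dt) * (1.0 / batch.quad.size)
    total = terms["energy"] * w.w_e + terms["charges"] * w.w_q \
        + terms["dipole"] * w.w_d + terms["quadrupole"] * w.w_t
    if "forces" in terms:
        total = total + terms["forces"] * w.w_f
    report = {k: float(v.data) for k, v in terms.items()}
    return total, report


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

def _d3_cache(potential, dataset):
    """Per-sample dispersion energies/forces, computed in size batches."""
    if potential.d3 is None:
        return None
    from .longrange import d3_energy_graph
    cache = {}
    for idx in group_by_size(dataset, 256):
        systems = [dataset.samples[i].system for i in idx]
        if any(s.pbc is not None and s.pbc.any() for s in systems):
            from .longrange import d3_dispersion
            for i in idx:
                cache[i] = d3_dispersion(dataset.samples[i].system,
                                         potential.d3)
            continue
        zidx = np.stack([species_index(s.atomic_numbers) for s in systems])
        coords = ad.tensor(np.stack([s.coords for s in systems]),
                           requires_grad=True)
        e = d3_energy_graph(coords, zidx, potential.d3)
        if coords.shape[1] == 1:
            forces = np.zeros_like(coords.data)
        else:
            forces = -ad.grad(ad.sum_(e), coords).data
        for k, i in enumerate(idx):
            cache[i] = (float(e.data[k]), forces[k])
    return cache


def init_element_energies(potential, dataset, d3_cache=None):
    """Least-squares regression of energies on element counts -> E0(z)."""
    n_species = len(potential.params["e0"])
    A = np.zeros((len(dataset), n_species))
    y = np.zeros(len(dataset))
    for i, s in enumerate(dataset.samples):
        zi = species_index(s.system.atomic_numbers)
        np.add.at(A[i], zi, 1.0)
        y[i] = s.energy - (d3_cache[i][0] if d3_cache else 0.0)
    e0, *_ = np.linalg.lstsq(A, y, rcond=None)
    present = A.sum(axis=0) > 0
    potential.params["e0"] = np.where(present, e0, 0.0)


def train(dataset: Dataset, potential, config: TrainConfig | None = None):
    """Fit the potential to a labeled dataset.

    Returns ``(potential, log)``: the potential carries the
    best-validation parameters; the log is one dict per epoch with
    train/val loss terms and the learning rate.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    n = len(dataset)
    if n < 2:
        train_ds = val_ds = dataset
        train_idx = np.arange(n)
    else:
        perm = rng.permutation(n)
        n_val = max(1, int(round(config.val_fraction * n)))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        train_ds, val_ds = dataset[train_idx], dataset[val_idx]

    d3_tr = _d3_cache(potential, train_ds)
    d3_va = _d3_cache(potential, val_ds)
    if np.all(potential.params["e0"] == 0):
        init_element_energies(potential, train_ds, d3_tr)

    dtype = np.dtype(config.dtype)
    potential.params = {k: v.astype(dtype)
                        for k, v in potential.params.items()}
    opt = AdamW(potential.params, lr=config.lr,
                weight_decay=config.weight_decay)
    val_batches = [
        _Batch([val_ds.samples[i] for i in idx], d3_va, idx)
        for idx in group_by_size(val_ds, config.batch_size)]
    # batch membership is fixed across epochs (features are cached per
    # batch); the visiting order is reshuffled every epoch
    batches = [
        _Batch([train_ds.samples[i] for i in idx], d3_tr, idx)
        for idx in group_by_size(train_ds, config.batch_size,
                                 seed=int(rng.integers(2 ** 31)))]
    for b in batches + val_batches:
        b.build_features(potential.config.basis)
        b.astype(dtype)

    best_val = np.inf
    best_params = copy.deepcopy(potential.params)
    log = []
    stale = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(batches))
        tr_loss, tr_terms, nb = 0.0, {}, 0
        acc_grads = None
        acc_count = 0
        for bi in order:
            batch = batches[bi]
            pt = wrap_params(potential.params)
            preds = _cached_predictions(potential, batch, pt,
                                        need_forces=config.weights.w_f > 0)
            total, report = loss(preds, batch, config.weights)
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"loss diverged at epoch {epoch}, batch {bi}")
            names = list(pt)
            grads = ad.grad(total, [pt[k] for k in names])
            gd = {k: g.data for k, g in zip(names, grads)}
            if acc_grads is None:
                acc_grads = gd
            else:
                for k in gd:
                    acc_grads[k] = acc_grads[k] + gd[k]
            acc_count += 1
            if acc_count == config.accumulate:
                opt.step(potential.params,
                         {k: v / acc_count for k, v in acc_grads.items()})
                acc_grads, acc_count = None, 0
            tr_loss += float(total.data)
            for k, v in report.items():
                tr_terms[k] = tr_terms.get(k, 0.0) + v
            nb += 1
        if acc_count:
            opt.step(potential.params,
                     {k: v / acc_count for k, v in acc_grads.items()})

        val_loss = 0.0
        for batch in val_batches:
            pt = wrap_params(potential.params)
            preds = _cached_predictions(potential, batch, pt,
                                        need_forces=config.weights.w_f > 0)
            total, _ = loss(preds, batch, config.weights)
            val_loss += float(total.data)
        val_loss /= max(1, len(val_batches))

        entry = {"epoch": epoch, "lr": opt.lr,
                 "train_loss": tr_loss / max(1, nb),
                 "val_loss": val_loss}
        entry.update({f"train_{k}": v / max(1, nb)
                      for k, v in tr_terms.items()})
        log.append(entry)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = copy.deepcopy(potential.params)
            stale = 0
        else:
            stale += 1
            if stale > config.plateau_patience:
                opt.lr = max(config.min_lr, opt.lr * config.plateau_factor)
                stale = 0
    potential.params = {k: v.astype(np.float64)
                        for k, v in best_params.items()}
    return potential, log


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(potential, dataset: Dataset, batch_size: int = 256,
             forces: bool = True):
    """Per-sample error table and aggregate statistics.

    Returns ``(table, aggregates)``: a DataFrame with one row per sample
    (|ΔE| total and per sqrt(N), RMS and max force error, charge RMSE)
    and a dict of dataset-level MAE/RMSE values.
    """
    d3c = _d3_cache(potential, dataset)
    rows = [None] * len(dataset)
    for idx in group_by_size(dataset, batch_size):
        batch = _Batch([dataset.samples[i] for i in idx], d3c, idx)
        pt = {k: ad.tensor(v) for k, v in potential.params.items()}
        periodic = any(dataset.samples[i].system.pbc is not None
                       and dataset.samples[i].system.pbc.any() for i in idx)
        if periodic:
            preds = _batch_predictions(potential, batch, params_t=pt,
                                       need_forces=forces)
        else:
            preds = _cached_predictions(potential, batch, pt,
                                        need_forces=forces)
        de = preds["energy"].data - batch.energy
        dq = preds["charges"].data - batch.charges
        if forces:
            df = preds["forces"].data - batch.forces
        for k, gi in enumerate(idx):
            row = {"index": int(gi), "n_atoms": batch.n,
                   "abs_de": abs(de[k]),
                   "abs_de_scaled": abs(de[k]) / np.sqrt(batch.n),
                   "charge_rmse": float(np.sqrt((dq[k] ** 2).mean()))}
            if forces:
                row["force_rms"] = float(np.sqrt((df[k] ** 2).mean()))
                row["force_max"] = float(np.abs(df[k]).max())
                row["force_mae"] = float(np.abs(df[k]).mean())
            rows[gi] = row
    table = pd.DataFrame(rows)
    agg = {"energy_mae": float(table["abs_de"].mean()),
           "energy_rmse": float(np.sqrt((table["abs_de"] ** 2).mean())),
           "charge_rmse": float(np.sqrt((table["charge_rmse"] ** 2).mean()))}
    if forces:
        agg["force_mae"] = float(table["force_mae"].mean())
        agg["force_mae_rms"] = float(table["force_rms"].mean())
        agg["force_rmse"] = float(np.sqrt((table["force_rms"] ** 2).mean()))
    return table, agg
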