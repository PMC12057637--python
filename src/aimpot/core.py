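"""The learned short-range model.

Each atom carries a 2-D embedding ``a_ds`` (d feature channels × s radial
shells) looked up by element and refined over message passes.  Per pass the
model builds

* a scalar (l = 0) contraction ``v_isd = Σ_j g_ijs a_ds(j)``,
* a vector (l = 1) contraction: per-pair messages ``Σ_s g_ijs a_ds(j) w_dsh``
  are accumulated along the unit bond vectors and reduced by a Euclidean
  norm over the Cartesian axis, which restores rotation invariance,
* (passes ≥ 2) the same two contractions with the neighbor embedding
  replaced by its current partial charge,

feeds their concatenation through a small MLP, and emits an embedding
update plus a raw charge ``q̃`` and a non-negative weight ``f``.  Every
charge update is followed by Neural Charge Equilibration,

    q_i = q̃_i + f_i (Q - Σ_j q̃_j) / Σ_j f_j,

so the predicted charges sum to the exact molecular charge after every
pass.  The final pass yields the per-atom AIM vector, from which a
feed-forward head infers atomic energies on top of per-element reference
energies E0(z).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .featurize import RadialBasisSpec, dense_geometry_graph
from .units import SUPPORTED_Z, species_index

_NORM_EPS = 1e-12   # softening inside the l=1 vector norm


class EquilibrationDegenerateError(ValueError):
    pass


@dataclass
class ModelConfig:
    d: int = 16                   # embedding feature channels
    h: int = 8                    # l=1 vector channels
    n_passes: int = 3
    hidden: tuple = (256, 128)    # update / energy MLP widths
    charge_hidden: int = 64       # dedicated charge-head width
    basis: RadialBasisSpec = field(default_factory=RadialBasisSpec)
    seed: int = 0

    @property
    def s(self) -> int:
        return self.basis.n_shells

    @property
    def aim_dim(self) -> int:
        return self.d * self.s + 1

    def input_dim(self, pass_index: int) -> int:
        base = self.d * self.s + self.d * self.h
        if pass_index >= 2:
            base += self.s + self.d * self.h
        return base

    def to_dict(self) -> dict:
        return {"d": self.d, "h": self.h, "n_passes": self.n_passes,
                "hidden": list(self.hidden),
                "charge_hidden": self.charge_hidden,
                "basis": self.basis.to_dict(), "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(d=d["d"], h=d["h"], n_passes=d["n_passes"],
                   hidden=tuple(d["hidden"]),
                   charge_hidden=d.get("charge_hidden", 64),
                   basis=RadialBasisSpec.from_dict(d["basis"]),
                   seed=d.get("seed", 0))


def _mlp_params(rng, sizes, out_scale=1.0, prefix=""):
    params = {}
    for k in range(len(sizes) - 1):
        fan_in = sizes[k]
        scale = 1.0 / np.sqrt(fan_in)
        if k == len(sizes) - 2:
            scale *= out_scale
        params[f"{prefix}W{k}"] = rng.normal(0.0, scale,
                                             size=(sizes[k], sizes[k + 1]))
        params[f"{prefix}b{k}"] = np.zeros(sizes[k + 1])
    return params


def init_params(config: ModelConfig) -> dict:
    """Seeded scaled-normal initialization of all learnable arrays."""
    rng = np.random.default_rng(config.seed)
    d, s, h = config.d, config.s, config.h
    params = {
        "embed": rng.normal(0.0, 1.0, size=(len(SUPPORTED_Z), d, s)),
        "e0": np.zeros(len(SUPPORTED_Z)),
    }
    for p in range(1, config.n_passes + 1):
        params[f"w_dsh_{p}"] = rng.normal(0.0, 1.0 / np.sqrt(s),
                                          size=(d, s, h))
        if p >= 2:
            params[f"wq_dsh_{p}"] = rng.normal(0.0, 1.0 / np.sqrt(s),
                                               size=(d, s, h))
        sizes = (config.input_dim(p), *config.hidden, d * s)
        params.update(_mlp_params(rng, sizes, out_scale=0.1,
                                  prefix=f"pass{p}_"))
        # dedicated small head for (q̃, f): keeps the charge channel from
        # competing with the energy trunk for gradient signal
        params.update(_mlp_params(
            rng, (config.input_dim(p), config.charge_hidden, 2),
            out_scale=0.1, prefix=f"charge{p}_"))
    params.update(_mlp_params(rng, (config.aim_dim, *config.hidden, 1),
                              out_scale=0.1, prefix="energy_"))
    return params


def wrap_params(params: dict) -> dict:
    return {k: ad.tensor(v, requires_grad=True) for k, v in params.items()}


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _gelu(x):
    return x * ad.sigmoid(x * 1.702)


def _mlp(pt: dict, prefix: str, x: ad.Tensor, n_layers: int) -> ad.Tensor:
    B, N, F = x.shape
    y = ad.reshape(x, (B * N, F))
    for k in range(n_layers):
        y = ad.matmul(y, pt[f"{prefix}W{k}"]) + pt[f"{prefix}b{k}"]
        if k < n_layers - 1:
            y = _gelu(y)
    return ad.reshape(y, (B, N, y.shape[-1]))


def scalar_conv(g: ad.Tensor, a: ad.Tensor) -> ad.Tensor:
    """l=0 contraction: (B,N,N,S), (B,N,D,S) -> (B,N,D,S) summed over j."""
    return ad.einsum("bijs,bjds->bids", g, a)


def vector_conv(g: ad.Tensor, u: ad.Tensor, a: ad.Tensor,
                w: ad.Tensor) -> ad.Tensor:
    """l=1 contraction with channel mixing ``w`` (D,S,H) -> (B,N,D,H).

    Per-pair messages Σ_s g a w are accumulated along the unit vectors and
    reduced by a (softened) Euclidean norm over the Cartesian axis, making
    the output rotation invariant and odd contributions cancel.
    """
    B, N = g.shape[0], g.shape[1]
    aw = ad.reshape(a, (B, N, a.shape[2], a.shape[3], 1)) * w  # (B,N,D,S,H)
    t = ad.einsum("bijs,bjdsh->bijdh", g, aw)
    m = ad.einsum("bijx,bijdh->bixdh", u, t)
    return ad.sqrt(ad.sum_(m * m, axis=2) + _NORM_EPS)


def charge_conv(g: ad.Tensor, u: ad.Tensor, q: ad.Tensor, wq: ad.Tensor):
    """Charge-carrier contractions: the neighbor descriptor is its charge.

    Returns scalar (B,N,S) and vector (B,N,D,H) charge features.
    """
    B, N = g.shape[0], g.shape[1]
    v_s = ad.einsum("bijs,bj->bis", g, q)
    aq = ad.einsum("bj,dsh->bjdsh", q, wq)
    t = ad.einsum("bijs,bjdsh->bijdh", g, aq)
    m = ad.einsum("bijx,bijdh->bixdh", u, t)
    return v_s, ad.sqrt(ad.sum_(m * m, axis=2) + _NORM_EPS)


def nqe(q_tilde: ad.Tensor, f: ad.Tensor, Q) -> ad.Tensor:
    """Neural Charge Equilibration over the atom axis (last axis).

    Redistributes the surplus/deficit ``Q - Σ q̃`` in proportion to the
    non-negative weights ``f`` so the result sums exactly to Q.
    """
    if np.any(ad.astensor(f).data.sum(axis=-1) <= 0):
        raise EquilibrationDegenerateError("sum of NQE weights is zero")
    q_tilde, f = ad.astensor(q_tilde), ad.astensor(f)
    surplus = ad.astensor(Q) - ad.sum_(q_tilde, axis=-1, keepdims=True)
    return q_tilde + f * surplus * ad.sum_(f, axis=-1, keepdims=True) ** -1.0


# ---------------------------------------------------------------------------
# full forward
# ---------------------------------------------------------------------------

def forward_batch(pt: dict, zidx: np.ndarray, coords: ad.Tensor,
                  total_charge: np.ndarray, config: ModelConfig,
                  cell: np.ndarray | None = None,
                  pbc: np.ndarray | None = None) -> dict:
    """Run the full message-passing stack on a same-size batch.

    ``pt``: parameter Tensors (see :func:`wrap_params`); ``zidx``: (B, N)
    species indices; ``coords``: Tensor (B, N, 3); ``total_charge``: (B,).

    Returns dict with ``energy_local`` (B,), ``charges`` (B, N), ``f``
    (B, N), ``aim`` (B, N, aim_dim) and the pairwise ``r``/``offdiag``
    (reused by the electrostatics term).
    """
    g, u, r, offdiag = dense_geometry_graph(coords, config.basis, cell, pbc)
    return forward_features(pt, zidx, g, u, r, offdiag, total_charge, config)


def forward_features(pt: dict, zidx: np.ndarray, g, u, r, offdiag,
                     total_charge: np.ndarray, config: ModelConfig) -> dict:
    """Message passing on precomputed pair features.

    ``g``/``u``/``r`` may be graph Tensors from the featurizer or leaf
    Tensors over cached arrays (the trainer exploits the latter: the
    geometry never changes during training, so the featurization and its
    coordinate Jacobian are computed once per batch).
    """
    B, N = zidx.shape
    g, u = ad.astensor(g), ad.astensor(u)
    n_layers = len(config.hidden) + 1
    a = pt["embed"][zidx]                       # (B, N, D, S)
    Q = np.asarray(total_charge,
                   dtype=pt["embed"].data.dtype).reshape(B, 1)

    q = None
    for p in range(1, config.n_passes + 1):
        v_s = scalar_conv(g, a)
        v_v = vector_conv(g, u, a, pt[f"w_dsh_{p}"])
        feats = [ad.reshape(v_s, (B, N, config.d * config.s)),
                 ad.reshape(v_v, (B, N, config.d * config.h))]
        if p >= 2:
            vq_s, vq_v = charge_conv(g, u, q, pt[f"wq_dsh_{p}"])
            feats += [vq_s, ad.reshape(vq_v, (B, N, config.d * config.h))]
        x = ad.concatenate(feats, axis=2)
        da = _mlp(pt, f"pass{p}_", x, n_layers)
        qf = _mlp(pt, f"charge{p}_", x, 2)
        a = a + ad.reshape(da, (B, N, config.d, config.s))
        q_tilde = qf[:, :, 0] if p == 1 else q + qf[:, :, 0]
        f = ad.softplus(qf[:, :, 1]) + 1e-6
        q = nqe(q_tilde, f, Q)

    aim = ad.concatenate(
        [ad.reshape(a, (B, N, config.d * config.s)),
         ad.reshape(q, (B, N, 1))], axis=2)
    e_atom = _mlp(pt, "energy_", aim, n_layers)       # (B, N, 1)
    e0 = pt["e0"][zidx]                               # (B, N)
    energy_local = ad.sum_(ad.reshape(e_atom, (B, N)) + e0, axis=1)
    if not np.all(np.isfinite(energy_local.data)):
        bad = np.nonzero(~np.isfinite(e_atom.data.reshape(B, N)))
        raise FloatingPointError(f"non-finite atomic energy at {bad}")
    return {"energy_local": energy_local, "charges": q, "f": f, "aim": aim,
            "r": r, "offdiag": offdiag}


def forward_system(pt, system, config: ModelConfig,
                   coords_t: ad.Tensor | None = None) -> dict:
    """Single-system convenience wrapper around :func:`forward_batch`."""
    zidx = species_index(system.atomic_numbers)[None, :]
    if coords_t is None:
        coords_t = ad.tensor(system.coords[None], requires_grad=True)
    pbc = system.pbc if (system.pbc is not None and system.pbc.any()) else None
    return forward_batch(pt, zidx, coords_t, np.array([system.charge]),
                         config, cell=system.cell, pbc=pbc)


# ---------------------------------------------------------------------------
# checkpoint I/O
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: dict, config: ModelConfig,
                    extra: dict | None = None):
    """Self-describing checkpoint: JSON header + raw float64 arrays (npz)."""
    header = {"schema": 1, "elements": list(SUPPORTED_Z),
              "config": config.to_dict(), "extra": extra or {}}
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **params)


def load_checkpoint(path):
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        params = {k: z[k].copy() for k in z.files if k != "__header__"}
    return params, ModelConfig.from_dict(header["config"]), header["extra"]
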