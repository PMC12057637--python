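"""Radial symmetry basis: Gaussian distance shells damped by a cosine cutoff.

An atom's radial environment is encoded as
``g_ijs = exp(-eta (r_ij - r_s)^2) * f_c(r_ij)`` over ``s`` shell centers,
with ``f_c(r) = 1/2 (cos(pi r / R_c) + 1)`` for ``r < R_c`` and 0 beyond,
so every feature (and its derivative) vanishes smoothly at the cutoff.

Defaults: 16 shells evenly spaced on [0.8, 5.0] Å; width ``eta = 1/(2 Δ²)``
with Δ the shell spacing (~50% overlap between adjacent Gaussians).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .system import DegenerateGeometryError, MolecularSystem, NeighborList


def _default_centers() -> np.ndarray:
    return np.linspace(0.8, 5.0, 16)


@dataclass
class RadialBasisSpec:
    centers: np.ndarray = field(default_factory=_default_centers)  # r_s, Å
    eta: float | None = None      # Å^-2; default from shell spacing
    cutoff: float = 5.0           # R_c, Å

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.centers.ndim != 1 or len(self.centers) < 1:
            raise ValueError("centers must be a non-empty 1-D array")
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("centers must be strictly increasing")
        if self.centers[-1] >= self.cutoff + 1e-12:
            raise ValueError("all centers must lie below the cutoff")
        if self.eta is None:
            delta = self.centers[1] - self.centers[0] if len(self.centers) > 1 \
                else self.cutoff / 2
            self.eta = 1.0 / (2.0 * delta * delta)
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        self.cutoff = float(self.cutoff)

    @property
    def n_shells(self) -> int:
        return len(self.centers)

    def to_dict(self) -> dict:
        return {"centers": self.centers.tolist(), "eta": self.eta,
                "cutoff": self.cutoff}

    @classmethod
    def from_dict(cls, d: dict) -> "RadialBasisSpec":
        return cls(centers=np.array(d["centers"]), eta=d["eta"],
                   cutoff=d["cutoff"])


def cosine_cutoff(r, cutoff: float):
    """Smooth damping weight in [0, 1]; C1-continuous zero at the cutoff."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    w = 0.5 * (np.cos(np.pi * np.minimum(r, cutoff) / cutoff) + 1.0)
    return np.where(r < cutoff, w, 0.0)


def radial_basis(r_ij, spec: RadialBasisSpec) -> np.ndarray:
    """g_ijs for scalar or array distances; shape (..., n_shells)."""
    r = np.asarray(r_ij, dtype=np.float64)
    if np.any(r <= 0):
        raise DegenerateGeometryError("coincident atoms (r = 0)")
    fc = cosine_cutoff(r, spec.cutoff)
    g = np.exp(-spec.eta * (r[..., None] - spec.centers) ** 2)
    return g * fc[..., None]


def pair_geometry(system: MolecularSystem, nlist: NeighborList,
                  spec: RadialBasisSpec):
    """Per-pair radial features and unit displacement vectors.

    Returns ``(g, u)`` with ``g`` of shape (n_pairs, n_shells) and
    ``u[k] = (r_j - r_i)/r_ij`` for pair k.
    """
    r = nlist.distances
    if np.any(r <= 1e-10):
        raise DegenerateGeometryError("coincident atoms in neighbor list")
    return radial_basis(r, spec), nlist.vectors / r[:, None]


# ---------------------------------------------------------------------------
# graph (autodiff) versions used inside the learned model
# ---------------------------------------------------------------------------

def dense_geometry_graph(coords: ad.Tensor, spec: RadialBasisSpec,
                         cell: np.ndarray | None = None,
                         pbc: np.ndarray | None = None):
    """All-pairs featurization for a batch of same-size systems.

    ``coords``: Tensor (B, N, 3).  Returns ``(g, u, r, offdiag)`` where
    ``g`` is (B, N, N, S) with the diagonal and beyond-cutoff entries
    exactly zero, ``u`` (B, N, N, 3) unit vectors (junk on the masked
    entries, which never contribute), ``r`` (B, N, N) distances and
    ``offdiag`` the constant off-diagonal mask.
    """
    B, N, _ = coords.shape
    ci = ad.reshape(coords, (B, 1, N, 3))
    cj = ad.reshape(coords, (B, N, 1, 3))
    diff = ci - cj  # [b, i, j] = r_j - r_i
    if cell is not None and pbc is not None and np.any(pbc):
        shift = np.zeros((B, N, N, 3))
        d = diff.data
        for ax in range(3):
            if pbc[ax]:
                L = cell[ax]
                shift[..., ax] = -L * np.round(d[..., ax] / L)
        diff = diff + shift  # constant image shifts
    eye = np.eye(N)[None, :, :]
    r2 = ad.sum_(diff * diff, axis=-1) + eye  # keep sqrt off zero on diagonal
    r = ad.sqrt(r2)
    mask = ((r.data < spec.cutoff) & (eye < 0.5)).astype(np.float64)
    fc = 0.5 * (ad.cos(r * (np.pi / spec.cutoff)) + 1.0)
    dr = ad.reshape(r, (B, N, N, 1)) - spec.centers
    g = ad.exp(dr * dr * (-spec.eta)) * ad.reshape(fc * mask, (B, N, N, 1))
    u = diff * ad.reshape(r, (B, N, N, 1)) ** -1.0
    offdiag = (eye < 0.5).astype(np.float64)
    return g, u, r, offdiag
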