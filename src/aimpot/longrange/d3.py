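"""Two-body D3 dispersion with rational (Becke-Johnson) damping.

    E = -1/2 Σ_{i≠j} [ s6 C6_ij / (r^6 + f(R0)^6) + s8 C8_ij / (r^8 + f(R0)^8) ]
    f(R0) = a1 R0 + a2,  R0 = sqrt(C8/C6),  C8 = 3 C6 r4r2_i r4r2_j

C6 coefficients are interpolated over per-element coordination-number (CN)
reference points with Gaussian weights exp(-k3 (CN - CN_ref)^2); the CN is
the standard smooth counting function over covalent radii,

    CN_i = Σ_{j≠i} 1 / (1 + exp(-k1 (4/3 (Rcov_i + Rcov_j) / r_ij - 1))).

All internals are atomic units; inputs/outputs are Å and eV.  The shipped
reference tables are a synthetic stand-in (see data/d3_params.json); the
damping-parameter sets are selectable by functional name.

Forces are exact gradients of the implemented energy, including the CN
dependence of C6, obtained through the autodiff graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .. import autodiff as ad
from ..system import MolecularSystem, UnsupportedElementError
from ..units import BOHR, HARTREE, SUPPORTED_Z, SPECIES_INDEX


@dataclass
class D3Params:
    s6: float
    s8: float
    a1: float
    a2: float                       # Bohr
    k1: float
    k3: float
    rcov: np.ndarray                # (n_elem,) Bohr
    r4r2: np.ndarray                # (n_elem,)
    ref_cn: np.ndarray              # (n_elem, max_refs), padded
    ref_c6sqrt: np.ndarray          # (n_elem, max_refs), sqrt of C6 refs
    ref_mask: np.ndarray            # (n_elem, max_refs) 0/1

    @classmethod
    def load(cls, functional: str = "b97-3c") -> "D3Params":
        raw = json.loads(resources.files("aimpot.data")
                         .joinpath("d3_params.json").read_text())
        if functional not in raw["damping"]:
            raise KeyError(f"unknown functional {functional!r}; "
                           f"have {sorted(raw['damping'])}")
        damp = raw["damping"][functional]
        n = len(SUPPORTED_Z)
        max_refs = max(len(raw["elements"][str(z)]["c6_refs"])
                       for z in SUPPORTED_Z)
        rcov = np.zeros(n)
        r4r2 = np.zeros(n)
        ref_cn = np.zeros((n, max_refs))
        ref_c6s = np.zeros((n, max_refs))
        ref_mask = np.zeros((n, max_refs))
        for z in SUPPORTED_Z:
            i = SPECIES_INDEX[z]
            el = raw["elements"][str(z)]
            rcov[i] = el["rcov"] / BOHR
            r4r2[i] = el["r4r2"]
            for k, (cn, c6) in enumerate(el["c6_refs"]):
                ref_cn[i, k] = cn
                ref_c6s[i, k] = np.sqrt(c6)
                ref_mask[i, k] = 1.0
        return cls(s6=damp["s6"], s8=damp["s8"], a1=damp["a1"],
                   a2=damp["a2"], k1=raw["k1"], k3=raw["k3"], rcov=rcov,
                   r4r2=r4r2, ref_cn=ref_cn, ref_c6sqrt=ref_c6s,
                   ref_mask=ref_mask)


def _switch(r_data: np.ndarray, cutoff: float | None) -> np.ndarray:
    """Constant smoothing mask: 1 inside 0.9*cutoff, cosine taper to 0."""
    if cutoff is None:
        return np.ones_like(r_data)
    r_on = 0.9 * cutoff
    x = np.clip((r_data - r_on) / (cutoff - r_on), 0.0, 1.0)
    return 0.5 * (np.cos(np.pi * x) + 1.0) * (r_data < cutoff)


def d3_energy_graph(coords: ad.Tensor, zidx: np.ndarray, params: D3Params,
                    cell=None, pbc=None, cutoff: float | None = None
                    ) -> ad.Tensor:
    """Dispersion energy (eV) for a same-size batch; coords (B, N, 3) in Å.

    When a ``cutoff`` (Å) is given, pair terms are tapered to zero by a
    cosine switch over the last 10% of the cutoff, keeping MD forces
    continuous; isolated systems default to the full sum.
    """
    B, N = zidx.shape
    if np.any(zidx < 0) or np.any(zidx >= len(params.rcov)):
        raise UnsupportedElementError("species outside dispersion tables")
    ci = ad.reshape(coords, (B, 1, N, 3))
    cj = ad.reshape(coords, (B, N, 1, 3))
    diff = ci - cj
    if cell is not None and pbc is not None and np.any(pbc):
        shift = np.zeros((B, N, N, 3))
        for ax in range(3):
            if pbc[ax]:
                L = cell[ax]
                shift[..., ax] = -L * np.round(diff.data[..., ax] / L)
        diff = diff + shift
    eye = np.eye(N)[None]
    r2 = ad.sum_(diff * diff, axis=-1) + eye
    r = ad.sqrt(r2) * (1.0 / BOHR)                      # Bohr
    offdiag = (eye < 0.5).astype(np.float64)
    sw = _switch(r.data * BOHR, cutoff) * offdiag

    # coordination numbers
    rcov_i = params.rcov[zidx]                           # (B, N)
    rc_pair = rcov_i[:, :, None] + rcov_i[:, None, :]    # (B, N, N)
    x = ad.sigmoid(((r ** -1.0) * (rc_pair * (4.0 / 3.0)) - 1.0) * params.k1)
    cn = ad.sum_(x * sw, axis=2)                         # (B, N)

    # Gaussian-weight interpolation of sqrt(C6) over CN reference points
    ref_cn = params.ref_cn[zidx]                         # (B, N, R)
    ref_c6s = params.ref_c6sqrt[zidx]
    ref_mask = params.ref_mask[zidx]
    dcn = ad.reshape(cn, (B, N, 1)) - ref_cn
    w = ad.exp(dcn * dcn * (-params.k3)) * ref_mask
    wsum = ad.sum_(w, axis=2)
    c6s = ad.sum_(w * ref_c6s, axis=2) * wsum ** -1.0    # (B, N)

    c6 = ad.einsum("bi,bj->bij", c6s, c6s)               # (B, N, N)
    qq = 3.0 * np.einsum("bi,bj->bij", params.r4r2[zidx], params.r4r2[zidx])
    f0 = params.a1 * np.sqrt(qq) + params.a2             # constant (B, N, N)
    r6 = r2 * r2 * r2 * (1.0 / BOHR) ** 6
    r8 = r6 * r2 * (1.0 / BOHR) ** 2
    e6 = c6 * (r6 + f0 ** 6) ** -1.0
    e8 = c6 * qq * (r8 + f0 ** 8) ** -1.0
    e_pair = (e6 * params.s6 + e8 * params.s8) * sw
    return ad.sum_(e_pair, axis=(1, 2)) * (-0.5 * HARTREE)


def d3_dispersion(system: MolecularSystem, params: D3Params,
                  cutoff: float | None = None):
    """Dispersion energy (eV) and exact-gradient forces (eV/Å)."""
    from ..units import species_index
    zidx = species_index(system.atomic_numbers)[None]
    coords = ad.tensor(system.coords[None], requires_grad=True)
    pbc = system.pbc if (system.pbc is not None and system.pbc.any()) else None
    e = d3_energy_graph(coords, zidx, params, cell=system.cell, pbc=pbc,
                        cutoff=cutoff)
    if system.n_atoms == 1:
        return float(e.data[0]), np.zeros((1, 3))
    g = ad.grad(ad.sum_(e), coords)
    return float(e.data[0]), -g.data[0]
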