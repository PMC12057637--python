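"""Charge-derived molecular multipoles (used as training targets).

dipole:      mu = Σ q_i (r_i - origin)                          [e·Å]
quadrupole:  Θ_ab = 1/2 Σ q_i (3 x_a x_b - r² δ_ab)             [e·Å²]

The quadrupole is traceless and symmetric by construction.  The default
origin is the center of mass.
"""

from __future__ import annotations

import numpy as np


def dipole_from_charges(coords, charges, origin) -> np.ndarray:
    x = np.asarray(coords) - np.asarray(origin)
    return np.asarray(charges) @ x


def quadrupole_from_charges(coords, charges, origin) -> np.ndarray:
    x = np.asarray(coords) - np.asarray(origin)
    q = np.asarray(charges)
    r2 = np.sum(x * x, axis=1)
    theta = 1.5 * np.einsum("i,ia,ib->ab", q, x, x)
    theta -= 0.5 * np.diag([1.0, 1.0, 1.0]) * (q @ r2)
    return theta


def multipoles_of(system, charges):
    origin = system.center_of_mass()
    return (dipole_from_charges(system.coords, charges, origin),
            quadrupole_from_charges(system.coords, charges, origin))
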