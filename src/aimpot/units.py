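"""Unit system and element data.

Internal units everywhere: energy eV, length Å, charge e, time fs,
mass amu, temperature K.
"""

import numpy as np

# e^2 / (4 pi eps0), eV * Angstrom (CODATA)
KE_COULOMB = 14.399645478425668

# Boltzmann constant, eV / K
KB = 8.617333262e-5

# 1 eV/(Å·amu) in Å/fs^2 (force-to-acceleration conversion)
ACC_UNIT = 9.648533212331338e-3

BOHR = 0.529177210903          # Å
HARTREE = 27.211386245988      # eV

# the supported element set
SUPPORTED_Z = (1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 33, 34, 35, 53)

SYMBOLS = {1: "H", 5: "B", 6: "C", 7: "N", 8: "O", 9: "F", 14: "Si",
           15: "P", 16: "S", 17: "Cl", 33: "As", 34: "Se", 35: "Br", 53: "I"}
Z_FROM_SYMBOL = {s: z for z, s in SYMBOLS.items()}

# standard atomic weights, amu
MASSES = {1: 1.008, 5: 10.81, 6: 12.011, 7: 14.007, 8: 15.999, 9: 18.998,
          14: 28.085, 15: 30.974, 16: 32.06, 17: 35.45, 33: 74.922,
          34: 78.971, 35: 79.904, 53: 126.904}

# single-bond covalent radii, Å (used for bond guessing and CN counting)
COVALENT_RADII = {1: 0.32, 5: 0.85, 6: 0.75, 7: 0.71, 8: 0.63, 9: 0.64,
                  14: 1.16, 15: 1.11, 16: 1.03, 17: 0.99, 33: 1.21,
                  34: 1.16, 35: 1.14, 53: 1.33}

# Pauling electronegativities (toy charge rule)
ELECTRONEGATIVITY = {1: 2.20, 5: 2.04, 6: 2.55, 7: 3.04, 8: 3.44, 9: 3.98,
                     14: 1.90, 15: 2.19, 16: 2.58, 17: 3.16, 33: 2.18,
                     34: 2.55, 35: 2.96, 53: 2.66}

# typical valences (toy molecular graphs)
VALENCE = {1: 1, 5: 3, 6: 4, 7: 3, 8: 2, 9: 1, 14: 4, 15: 3, 16: 2,
           17: 1, 33: 3, 34: 2, 35: 1, 53: 1}

# species index used by the model (row in embedding tables)
SPECIES_INDEX = {z: i for i, z in enumerate(SUPPORTED_Z)}

_zmap = np.full(max(SUPPORTED_Z) + 1, -1, dtype=np.int64)
for _z, _i in SPECIES_INDEX.items():
    _zmap[_z] = _i


def species_index(atomic_numbers: np.ndarray) -> np.ndarray:
    """Map atomic numbers to contiguous species indices (raises on unsupported)."""
    z = np.asarray(atomic_numbers, dtype=np.int64)
    if z.min() < 1 or z.max() >= len(_zmap) or np.any(_zmap[z] < 0):
        bad = sorted(set(int(x) for x in z if x >= len(_zmap) or x < 1 or _zmap[x] < 0))
        raise ValueError(f"unsupported atomic numbers: {bad}")
    return _zmap[z]


def masses_of(atomic_numbers) -> np.ndarray:
    return np.array([MASSES[int(z)] for z in atomic_numbers])
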