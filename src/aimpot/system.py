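"""Core domain records: molecular systems, labeled samples, datasets,
neighbor lists.

All quantities are in eV / Å / e.  Coordinates are 0-indexed Cartesian.
Periodic support is orthorhombic (per-axis box lengths) with the
minimum-image convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import SUPPORTED_Z, masses_of


class UnsupportedElementError(ValueError):
    pass


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class MolecularSystem:
    """Atomic coordinates, species, net charge and optional orthorhombic cell.

    ``bonds`` is an optional (n_bonds, 2) connectivity table; it is carried
    for the toy potential and environment hashing but takes no part in the
    learned model, which sees only geometry.
    """

    coords: np.ndarray                  # (N, 3) Å
    atomic_numbers: np.ndarray          # (N,) int
    charge: int = 0                     # total charge Q, e
    cell: np.ndarray | None = None      # (3,) box lengths, Å
    pbc: np.ndarray | None = None       # (3,) bool
    bonds: np.ndarray | None = None     # (n_bonds, 2) int, optional

    def __post_init__(self):
        self.coords = np.ascontiguousarray(self.coords, dtype=np.float64)
        self.atomic_numbers = np.ascontiguousarray(self.atomic_numbers,
                                                   dtype=np.int64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if len(self.atomic_numbers) != len(self.coords):
            raise ValueError("atomic_numbers/coords length mismatch")
        if len(self.coords) < 1:
            raise ValueError("system must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        bad = set(self.atomic_numbers.tolist()) - set(SUPPORTED_Z)
        if bad:
            raise UnsupportedElementError(
                f"unsupported atomic numbers: {sorted(bad)}")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=np.float64).reshape(3)
        if self.pbc is None:
            self.pbc = np.zeros(3, dtype=bool) if self.cell is None \
                else np.ones(3, dtype=bool)
        else:
            self.pbc = np.asarray(self.pbc, dtype=bool).reshape(3)
        if self.pbc.any():
            if self.cell is None:
                raise ValueError("pbc requires a cell")
            if np.any(self.cell[self.pbc] <= 0):
                raise ValueError("periodic cell lengths must be positive")
        if self.bonds is not None:
            self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.charge = int(self.charge)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def masses(self) -> np.ndarray:
        return masses_of(self.atomic_numbers)

    def center_of_mass(self) -> np.ndarray:
        m = self.masses
        return m @ self.coords / m.sum()

    def displacements(self) -> np.ndarray:
        """All-pairs displacement r_j - r_i, minimum image under pbc. (N,N,3)"""
        d = self.coords[None, :, :] - self.coords[:, None, :]
        if self.pbc is not None and self.pbc.any():
            for ax in range(3):
                if self.pbc[ax]:
                    L = self.cell[ax]
                    d[..., ax] -= L * np.round(d[..., ax] / L)
        return d

    def copy(self, coords: np.ndarray | None = None) -> "MolecularSystem":
        return MolecularSystem(
            coords=self.coords.copy() if coords is None else np.asarray(coords),
            atomic_numbers=self.atomic_numbers.copy(),
            charge=self.charge,
            cell=None if self.cell is None else self.cell.copy(),
            pbc=None if self.pbc is None else self.pbc.copy(),
            bonds=None if self.bonds is None else self.bonds.copy(),
        )


@dataclass
class LabeledSample:
    """A system plus reference labels used in training."""

    system: MolecularSystem
    energy: float                        # eV
    forces: np.ndarray                   # (N, 3) eV/Å
    charges: np.ndarray                  # (N,) e
    dipole: np.ndarray | None = None     # (3,) e·Å
    quadrupole: np.ndarray | None = None  # (3, 3) traceless, e·Å²
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.energy = float(self.energy)
        self.forces = np.asarray(self.forces, dtype=np.float64)
        self.charges = np.asarray(self.charges, dtype=np.float64).reshape(-1)
        if self.forces.shape != self.system.coords.shape:
            raise ValueError("forces shape must match coords")
        if len(self.charges) != self.system.n_atoms:
            raise ValueError("charges length must match atom count")
        if abs(self.charges.sum() - self.system.charge) > 1e-8:
            raise ValueError(
                f"charges sum {self.charges.sum():.2e} != Q {self.system.charge}")
        if self.dipole is not None:
            self.dipole = np.asarray(self.dipole, dtype=np.float64).reshape(3)
        if self.quadrupole is not None:
            self.quadrupole = np.asarray(self.quadrupole,
                                         dtype=np.float64).reshape(3, 3)
            if abs(np.trace(self.quadrupole)) > 1e-8:
                raise ValueError("quadrupole must be traceless")


@dataclass
class Dataset:
    """Ordered collection of labeled samples plus free-form provenance."""

    samples: list
    metadata: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.samples)

    def __getitem__(self, i):
        if isinstance(i, (list, np.ndarray)):
            return Dataset([self.samples[j] for j in i], dict(self.metadata))
        return self.samples[i]

    def __iter__(self):
        return iter(self.samples)

    def sizes(self) -> np.ndarray:
        return np.array([s.system.n_atoms for s in self.samples])


@dataclass
class NeighborList:
    """Directed neighbor pairs within a cutoff (minimum image under pbc)."""

    pairs: np.ndarray        # (n_pairs, 2) int, directed, sorted by (i, j)
    distances: np.ndarray    # (n_pairs,) Å
    vectors: np.ndarray      # (n_pairs, 3) r_j - r_i (+ image shift), Å
    cutoff: float


def build_neighbor_list(system: MolecularSystem, cutoff: float) -> NeighborList:
    """Exact directed neighbor list: all (i, j), i != j, with minimum-image
    distance < cutoff, sorted by (i, j).

    Under pbc the cutoff must be below half the smallest periodic box length
    so the minimum image is the only image in range.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if system.pbc is not None and system.pbc.any():
        half = system.cell[system.pbc].min() / 2.0
        if cutoff >= half:
            raise ValueError(
                f"cutoff {cutoff} >= half-box {half}; minimum image violated")
    d = system.displacements()
    r = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(r, np.inf)
    ii, jj = np.nonzero(r < cutoff)
    order = np.lexsort((jj, ii))
    ii, jj = ii[order], jj[order]
    return NeighborList(pairs=np.stack([ii, jj], axis=1),
                        distances=r[ii, jj],
                        vectors=d[ii, jj],
                        cutoff=float(cutoff))


def group_by_size(dataset: Dataset, batch_size: int, seed: int | None = None):
    """Partition a dataset into minibatches of identical atom count.

    Returns a list of index arrays.  Order within each size group follows
    dataset order, or a seeded shuffle when ``seed`` is given.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    sizes = dataset.sizes()
    rng = np.random.default_rng(seed) if seed is not None else None
    batches = []
    for n in np.unique(sizes):
        idx = np.nonzero(sizes == n)[0]
        if rng is not None:
            rng.shuffle(idx)
        for k in range(0, len(idx), batch_size):
            batches.append(idx[k:k + batch_size])
    return batches
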