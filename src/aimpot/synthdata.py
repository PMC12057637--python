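"""Analytic toy reference potential and structure generators.

The toy potential stands in for quantum-chemical labels so every other
module can be trained and tested at desk scale.  It contains the same
three physical channels the learned decomposition targets:

* bonded Morse terms plus harmonic (cosine) angle bending — short range,
* a damped r^-6 dispersion tail with exponential Pauli repulsion on
  nonbonded pairs (1-2 and 1-3 excluded),
* point-charge Coulomb over all pairs, with ground-truth charges from a
  fixed electronegativity rule
      q_i = (chibar - chi_i)/kappa + Q/N
  (uniform redistribution of the net charge), which sums to Q exactly.

Energies and forces are hand-derived, mutually consistent analytics —
independent of the autodiff engine the learned model uses — so a training
failure is attributable to the model or trainer, never the labels.

Generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .longrange.coulomb import CoulombSpec, coulomb_energy
from .multipoles import multipoles_of
from .system import Dataset, LabeledSample, MolecularSystem
from .units import (COVALENT_RADII, ELECTRONEGATIVITY, SUPPORTED_Z, VALENCE,
                    Z_FROM_SYMBOL)


class GenerationError(RuntimeError):
    pass


class PackingError(RuntimeError):
    pass


# per-element Morse well depths (eV) and dispersion C6 (eV·Å^6) — toy scale
_D_E = {1: 4.5, 5: 3.4, 6: 3.7, 7: 3.3, 8: 3.5, 9: 4.0, 14: 3.2, 15: 3.1,
        16: 3.0, 17: 3.6, 33: 2.8, 34: 2.9, 35: 3.2, 53: 2.8}
_C6 = {1: 1.5, 5: 12.0, 6: 15.0, 7: 12.0, 8: 10.0, 9: 7.0, 14: 35.0,
       15: 28.0, 16: 25.0, 17: 20.0, 33: 40.0, 34: 38.0, 35: 32.0, 53: 55.0}


@dataclass
class ToyPotentialSpec:
    a_morse: float = 1.8          # Å^-1
    kappa: float = 5.0            # e per electronegativity unit
    k_angle: float = 3.0          # eV per (cos theta)^2
    cos0: float = -1.0 / 3.0      # tetrahedral reference angle
    rep_a: float = 800.0          # eV, Pauli prefactor
    rep_b: float = 3.5            # Å^-1
    disp_r0: float = 2.0          # Å, dispersion damping radius
    dsf_alpha: float = 0.2        # Å^-1, periodic electrostatics
    d_e: dict = field(default_factory=lambda: dict(_D_E))
    c6: dict = field(default_factory=lambda: dict(_C6))

    def morse(self, zi: int, zj: int):
        """(D_e, a, r_e) for an element pair."""
        d = np.sqrt(self.d_e[zi] * self.d_e[zj])
        re = COVALENT_RADII[zi] + COVALENT_RADII[zj]
        return d, self.a_morse, re

    def pair_c6(self, zi: int, zj: int):
        return np.sqrt(self.c6[zi] * self.c6[zj])


class ToyPotential:
    """Analytic reference potential over systems carrying a bond graph."""

    def __init__(self, spec: ToyPotentialSpec | None = None):
        self.spec = spec or ToyPotentialSpec()
        self._topo_cache = {}

    def _topology(self, system):
        """Index arrays for bonded/angle/nonbonded terms (cached per graph)."""
        key = (system.bonds.tobytes(), system.atomic_numbers.tobytes())
        topo = self._topo_cache.get(key)
        if topo is not None:
            return topo
        sp = self.spec
        n = system.n_atoms
        z = system.atomic_numbers
        adj = [[] for _ in range(n)]
        for i, j in system.bonds:
            adj[i].append(int(j))
            adj[j].append(int(i))
        bi = system.bonds[:, 0]
        bj = system.bonds[:, 1]
        b_par = np.array([sp.morse(int(z[i]), int(z[j]))
                          for i, j in system.bonds])  # (nb, 3): D, a, re
        trip = []
        excl = {(min(i, j), max(i, j)) for i, j in system.bonds}
        for jc in range(n):
            nb = adj[jc]
            for a_ in range(len(nb)):
                for b_ in range(a_ + 1, len(nb)):
                    trip.append((nb[a_], jc, nb[b_]))
                    excl.add((min(nb[a_], nb[b_]), max(nb[a_], nb[b_])))
        trip = np.array(trip, dtype=np.int64).reshape(-1, 3)
        iu, ju = np.triu_indices(n, k=1)
        keep = np.array([(int(i), int(j)) not in excl
                         for i, j in zip(iu, ju)], dtype=bool)
        ni, nj = iu[keep], ju[keep]
        c6 = np.array([sp.pair_c6(int(z[i]), int(z[j]))
                       for i, j in zip(ni, nj)])
        topo = (bi, bj, b_par, trip, ni, nj, c6)
        if len(self._topo_cache) > 64:
            self._topo_cache.clear()
        self._topo_cache[key] = topo
        return topo

    # -- ground-truth charges ------------------------------------------------
    def charges(self, system: MolecularSystem) -> np.ndarray:
        chi = np.array([ELECTRONEGATIVITY[int(z)]
                        for z in system.atomic_numbers])
        n = system.n_atoms
        return (chi.mean() - chi) / self.spec.kappa + system.charge / n

    # -- energy & analytic forces -------------------------------------------
    def energy_forces(self, system: MolecularSystem):
        if system.bonds is None:
            raise ValueError("toy potential needs a bond graph")
        sp = self.spec
        n = system.n_atoms
        coords = system.coords
        energy = 0.0
        forces = np.zeros((n, 3))
        periodic = system.pbc is not None and system.pbc.any()
        bi, bj, b_par, trip, ni, nj, c6_nb = self._topology(system)

        def pair_disp(ii, jj):
            d = coords[jj] - coords[ii]
            if periodic:
                for ax in range(3):
                    if system.pbc[ax]:
                        L = system.cell[ax]
                        d[:, ax] -= L * np.round(d[:, ax] / L)
            return d

        # Morse bonds
        if len(bi):
            d = pair_disp(bi, bj)
            r = np.linalg.norm(d, axis=1)
            d_e, a, re = b_par[:, 0], b_par[:, 1], b_par[:, 2]
            ex = np.exp(-a * (r - re))
            energy += float(np.sum(d_e * ((1.0 - ex) ** 2 - 1.0)))
            dedr = 2.0 * d_e * a * ex * (1.0 - ex)
            fvec = (dedr / r)[:, None] * d     # force on i along +d
            np.add.at(forces, bi, fvec)
            np.add.at(forces, bj, -fvec)

        # angle bending at every bonded triple i-j-k (center j)
        if len(trip):
            ti, tj, tk = trip[:, 0], trip[:, 1], trip[:, 2]
            u = pair_disp(tj, ti)             # r_i - r_j
            v = pair_disp(tj, tk)
            ru = np.linalg.norm(u, axis=1)
            rv = np.linalg.norm(v, axis=1)
            c = np.sum(u * v, axis=1) / (ru * rv)
            diff = c - sp.cos0
            energy += float(np.sum(0.5 * sp.k_angle * diff * diff))
            dedc = sp.k_angle * diff
            gi = dedc[:, None] * (v / (ru * rv)[:, None]
                                  - c[:, None] * u / (ru ** 2)[:, None])
            gk = dedc[:, None] * (u / (ru * rv)[:, None]
                                  - c[:, None] * v / (rv ** 2)[:, None])
            np.add.at(forces, ti, -gi)
            np.add.at(forces, tk, -gk)
            np.add.at(forces, tj, gi + gk)

        # nonbonded dispersion + repulsion (1-2, 1-3 excluded)
        if len(ni):
            d = pair_disp(ni, nj)
            r = np.linalg.norm(d, axis=1)
            den = r ** 6 + sp.disp_r0 ** 6
            e_disp = -c6_nb / den
            de_disp = 6.0 * c6_nb * r ** 5 / den ** 2
            e_rep = sp.rep_a * np.exp(-sp.rep_b * r)
            de_rep = -sp.rep_b * e_rep
            sw = np.ones_like(r)
            dsw = np.zeros_like(r)
            if periodic:                      # cosine taper over last 10%
                rc = 0.45 * float(system.cell[system.pbc].min())
                r_on = 0.9 * rc
                xsw = np.clip((r - r_on) / (rc - r_on), 0.0, 1.0)
                sw = np.where(r < rc, 0.5 * (np.cos(np.pi * xsw) + 1.0), 0.0)
                dsw = np.where((r > r_on) & (r < rc),
                               -0.5 * np.pi * np.sin(np.pi * xsw)
                               / (rc - r_on), 0.0)
            e_pair = e_disp + e_rep
            energy += float(np.sum(e_pair * sw))
            dedr = (de_disp + de_rep) * sw + e_pair * dsw
            fvec = (dedr / r)[:, None] * d
            np.add.at(forces, ni, fvec)
            np.add.at(forces, nj, -fvec)

        # Coulomb over all pairs (ground-truth charges)
        q = self.charges(system)
        if periodic:
            cspec = CoulombSpec(mode="dsf", cutoff=rc, alpha=sp.dsf_alpha)
            e_c, f_c = coulomb_energy(coords, q, cspec, cell=system.cell,
                                      pbc=system.pbc)
        else:
            e_c, f_c = coulomb_energy(coords, q, CoulombSpec(mode="direct"))
        energy += e_c
        forces += f_c
        return float(energy), forces

    # -- labeling -------------------------------------------------------------
    def label(self, system: MolecularSystem, **metadata) -> LabeledSample:
        e, f = self.energy_forces(system)
        q = self.charges(system)
        dip, quad = multipoles_of(system, q)
        return LabeledSample(system=system, energy=e, forces=f, charges=q,
                             dipole=dip, quadrupole=quad,
                             metadata=dict(metadata))


def label_with_toy(system: MolecularSystem,
                   spec: ToyPotentialSpec | None = None) -> LabeledSample:
    return ToyPotential(spec).label(system)


# ---------------------------------------------------------------------------
# structure generators
# ---------------------------------------------------------------------------

DEFAULT_ELEMENT_WEIGHTS = {"H": 0.32, "C": 0.32, "N": 0.12, "O": 0.14,
                           "F": 0.04, "S": 0.03, "Cl": 0.03}

_MIN_DIST = 0.7    # Å, clash threshold


def _weights_to_arrays(element_weights):
    if element_weights is None:
        element_weights = DEFAULT_ELEMENT_WEIGHTS
    zs, ws = [], []
    for k, w in element_weights.items():
        z = Z_FROM_SYMBOL[k] if isinstance(k, str) else int(k)
        if z not in SUPPORTED_Z:
            raise ValueError(f"unsupported element {k}")
        zs.append(z)
        ws.append(float(w))
    ws = np.array(ws)
    return np.array(zs), ws / ws.sum()


def generate_molecule(n_atoms: int, element_weights=None, charge: int = 0,
                      seed: int = 0, saturate: bool = True,
                      ring_prob: float = 0.15,
                      spec: ToyPotentialSpec | None = None) -> MolecularSystem:
    """Random bonded molecule: a valence-limited tree (plus an occasional
    ring closure) over ``n_atoms`` backbone atoms, hydrogen-saturated by
    default, embedded in 3-D and relaxed free of clashes.

    Deterministic for a fixed seed.
    """
    if n_atoms < 1:
        raise GenerationError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    zs, ws = _weights_to_arrays(element_weights)
    spec = spec or ToyPotentialSpec()

    z_list = bonds = free = None
    for _attempt in range(50):   # redraw when a valence draw dead-ends
        z_list = [int(rng.choice(zs, p=ws))]
        bonds = []
        free = [VALENCE[z_list[0]]]
        for _ in range(1, n_atoms):
            open_atoms = [i for i, v in enumerate(free) if v > 0]
            if not open_atoms:
                z_list = None
                break
            znew = int(rng.choice(zs, p=ws))
            parent = int(rng.choice(open_atoms))
            idx = len(z_list)
            z_list.append(znew)
            bonds.append((parent, idx))
            free[parent] -= 1
            free.append(VALENCE[znew] - 1)
        if z_list is not None:
            break
    if z_list is None:
        raise GenerationError(
            "no open valence left to grow the graph (infeasible element "
            "weights for the requested size)")
    # optional ring closure between two open atoms not already bonded
    if len(z_list) >= 4 and rng.random() < ring_prob:
        open_atoms = [i for i, v in enumerate(free) if v > 0]
        rng.shuffle(open_atoms)
        have = {tuple(sorted(b)) for b in bonds}
        for a in range(len(open_atoms)):
            for b in range(a + 1, len(open_atoms)):
                i, j = open_atoms[a], open_atoms[b]
                if tuple(sorted((i, j))) not in have:
                    bonds.append((i, j))
                    free[i] -= 1
                    free[j] -= 1
                    open_atoms = None
                    break
            if open_atoms is None:
                break
    if saturate:
        for i in range(n_atoms):
            for _ in range(free[i]):
                idx = len(z_list)
                z_list.append(1)
                bonds.append((i, idx))

    z = np.array(z_list)
    n = len(z)
    adj = [[] for _ in range(n)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)

    # sequential embedding: each atom at bond length from its parent,
    # direction repelled from the parent's existing bonds
    coords = np.zeros((n, 3))
    placed = {0}
    order = [0]
    parent_of = {0: None}
    stack = [0]
    while stack:
        cur = stack.pop()
        for nb in adj[cur]:
            if nb not in placed:
                placed.add(nb)
                parent_of[nb] = cur
                order.append(nb)
                stack.append(nb)
    for idx in order[1:]:
        p = parent_of[idx]
        _, _, re = spec.morse(int(z[p]), int(z[idx]))
        best, best_score = None, -np.inf
        others = [coords[o] - coords[p] for o in adj[p]
                  if o in placed and o != idx]
        for _ in range(24):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            cand = coords[p] + re * v
            score = min((np.linalg.norm(cand - coords[o])
                         for o in placed if o != idx), default=np.inf)
            for o in others:
                on = np.linalg.norm(o)
                if on > 1e-10:
                    score = min(score, 2.0 - float(v @ o) / on)
            if score > best_score:
                best, best_score = cand, score
        coords[idx] = best

    system = MolecularSystem(coords=coords, atomic_numbers=z, charge=charge,
                             bonds=np.array(bonds))
    if n > 1:
        system = _relax_geometry(system, ToyPotential(spec), steps=300)
    return system


def _relax_geometry(system, pot, steps=300, step0=5e-3, fcap=5.0):
    """Damped steepest descent to clean up generated geometry."""
    coords = system.coords.copy()
    work = system.copy()
    step = step0
    e_prev = None
    for _ in range(steps):
        work.coords = coords
        e, f = pot.energy_forces(work)
        fmax = np.abs(f).max()
        if fmax < 1e-2:
            break
        f = np.clip(f, -fcap, fcap)
        if e_prev is not None:
            step = step * (1.2 if e < e_prev else 0.5)
        e_prev = e
        coords = coords + step * f
    return system.copy(coords=coords)


def _rotatable_bonds(system):
    """Internal tree bonds (both ends non-terminal, not in a ring)."""
    n = system.n_atoms
    deg = np.zeros(n, dtype=int)
    for i, j in system.bonds:
        deg[i] += 1
        deg[j] += 1
    out = []
    for i, j in system.bonds:
        if deg[i] > 1 and deg[j] > 1 and _splits_graph(system, i, j):
            out.append((int(i), int(j)))
    return out


def _splits_graph(system, i, j):
    """True if removing bond (i, j) disconnects j's side from i (no ring)."""
    n = system.n_atoms
    adj = [[] for _ in range(n)]
    for a, b in system.bonds:
        if {int(a), int(b)} == {int(i), int(j)}:
            continue
        adj[a].append(b)
        adj[b].append(a)
    seen = {int(j)}
    stack = [int(j)]
    while stack:
        cur = stack.pop()
        for nb in adj[cur]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return int(i) not in seen


def _side_atoms(system, i, j):
    """Atoms on j's side when bond (i, j) is cut."""
    n = system.n_atoms
    adj = [[] for _ in range(n)]
    for a, b in system.bonds:
        if {int(a), int(b)} == {int(i), int(j)}:
            continue
        adj[a].append(b)
        adj[b].append(a)
    seen = {int(j)}
    stack = [int(j)]
    while stack:
        cur = stack.pop()
        for nb in adj[cur]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return sorted(seen)


def _rotate_about_axis(coords, origin, axis, angle):
    axis = axis / np.linalg.norm(axis)
    k = axis
    x = coords - origin
    cosa, sina = np.cos(angle), np.sin(angle)
    return (origin + x * cosa + np.cross(k, x) * sina
            + np.outer(x @ k, k) * (1.0 - cosa))


def sample_conformers(system: MolecularSystem, n: int, scale: float = 0.08,
                      seed: int = 0, twist: float = 0.25,
                      max_tries: int = 50):
    """Near-equilibrium conformers: seeded Gaussian Cartesian displacement
    plus random torsion twists about rotatable bonds, clash-rejected."""
    if scale < 0:
        raise ValueError("scale must be non-negative")
    rng = np.random.default_rng(seed)
    rotatable = _rotatable_bonds(system) if system.bonds is not None else []
    side_cache = {b: _side_atoms(system, *b) for b in rotatable}
    out = []
    for _ in range(n):
        for _try in range(max_tries):
            coords = system.coords.copy()
            for (i, j) in rotatable:
                ang = rng.normal(0.0, twist)
                axis = coords[j] - coords[i]
                side = side_cache[(i, j)]
                coords[side] = _rotate_about_axis(coords[side], coords[j],
                                                  axis, ang)
            coords = coords + rng.normal(0.0, scale, size=coords.shape) \
                if scale > 0 else coords
            d = np.linalg.norm(coords[None] - coords[:, None], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() >= _MIN_DIST:
                break
        out.append(system.copy(coords=coords))
    return out


def build_cluster(pool, seed: int = 0, cell_range=(20.0, 30.0),
                  n_molecules=(2, 5), clearance: float = 1.5,
                  max_attempts: int = 500) -> MolecularSystem:
    """Randomly pack 2–5 pool molecules into a rectangular periodic cell.

    Molecule choice is skewed toward fewer heavy atoms; placements are
    redrawn until no intermolecular atom pair is closer than ``clearance``
    under the minimum image.
    """
    if not pool:
        raise PackingError("empty molecule pool")
    rng = np.random.default_rng(seed)
    cell = rng.uniform(*cell_range, size=3)
    nmol = int(rng.integers(n_molecules[0], n_molecules[1] + 1))
    heavies = np.array([np.sum(m.atomic_numbers > 1) + 1 for m in pool],
                       dtype=float)
    p = (1.0 / heavies)
    p /= p.sum()
    chosen = [pool[i] for i in rng.choice(len(pool), size=nmol, p=p)]

    placed_coords = []
    for mol in chosen:
        com = mol.coords.mean(axis=0)
        base = mol.coords - com
        ok = False
        for _ in range(max_attempts):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = rng.uniform(0, 2 * np.pi)
            cand = _rotate_about_axis(base, np.zeros(3), axis, ang)
            cand = cand + rng.uniform(0, 1, size=3) * cell
            good = True
            for other in placed_coords:
                d = cand[:, None, :] - other[None, :, :]
                d -= cell * np.round(d / cell)
                if np.linalg.norm(d, axis=-1).min() < clearance:
                    good = False
                    break
            if good:
                ok = True
                break
        if not ok:
            raise PackingError("could not place molecule without clashes")
        placed_coords.append(cand)

    coords = np.concatenate(placed_coords)
    z = np.concatenate([m.atomic_numbers for m in chosen])
    bonds, off = [], 0
    for m in chosen:
        bonds.append(m.bonds + off)
        off += m.n_atoms
    return MolecularSystem(coords=coords, atomic_numbers=z,
                           charge=sum(m.charge for m in chosen),
                           cell=cell, pbc=np.ones(3, dtype=bool),
                           bonds=np.concatenate(bonds))


def _molecules_of(cluster):
    """Connected components of the bond graph -> list of atom-index lists."""
    n = cluster.n_atoms
    adj = [[] for _ in range(n)]
    for i, j in cluster.bonds:
        adj[i].append(j)
        adj[j].append(i)
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        comp, stack = [], [start]
        seen[start] = True
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for nb in adj[cur]:
                if not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(sorted(comp))
    return comps


def extract_nmers(cluster: MolecularSystem, cutoff: float = 6.0,
                  max_order: int = 5):
    """All dimer-to-N-mer subsystems in which every monomer has at least
    one atom within ``cutoff`` of some other monomer of the group.

    Each N-mer is returned unwrapped as an isolated system (monomers are
    shifted by whole-cell images to sit next to their contacts).
    """
    from itertools import combinations
    comps = _molecules_of(cluster)
    m = len(comps)
    cell = cluster.cell
    # min interatomic distance and best image shift per monomer pair
    mind = np.full((m, m), np.inf)
    shift = np.zeros((m, m, 3))
    for a in range(m):
        for b in range(a + 1, m):
            ca, cb = cluster.coords[comps[a]], cluster.coords[comps[b]]
            d = cb[None, :, :] - ca[:, None, :]
            img = np.zeros(3)
            if cluster.pbc is not None and cluster.pbc.any():
                dd = d - cell * np.round(d / cell)
                k = np.unravel_index(
                    np.argmin(np.linalg.norm(dd, axis=-1)), dd.shape[:2])
                img = -cell * np.round(d[k] / cell)
                d = dd
            mind[a, b] = mind[b, a] = np.linalg.norm(d, axis=-1).min()
            shift[a, b] = img       # add to monomer b to sit next to a
            shift[b, a] = -img
    out = []
    for order in range(2, min(max_order, m) + 1):
        for group in combinations(range(m), order):
            ok = all(any(mind[a, b] < cutoff for b in group if b != a)
                     for a in group)
            if not ok:
                continue
            # unwrap: BFS from the first monomer along closest contacts
            pos = {group[0]: np.zeros(3)}
            frontier = [group[0]]
            while frontier:
                a = frontier.pop()
                for b in group:
                    if b not in pos and mind[a, b] < cutoff:
                        pos[b] = pos[a] + shift[a, b]
                        frontier.append(b)
            if len(pos) < order:      # contact graph disconnected; anchor rest
                for b in group:
                    pos.setdefault(b, shift[group[0], b])
            idx, coords = [], []
            for a in group:
                idx.extend(comps[a])
                coords.append(cluster.coords[comps[a]] + pos[a])
            coords = np.concatenate(coords)
            remap = {old: k for k, old in enumerate(idx)}
            bsel = [(remap[int(i)], remap[int(j)]) for i, j in cluster.bonds
                    if int(i) in remap and int(j) in remap]
            q = 0
            out.append(MolecularSystem(
                coords=coords, atomic_numbers=cluster.atomic_numbers[idx],
                charge=q, bonds=np.array(bsel)))
    return out


def make_dataset(n_molecules: int, conformers_per_molecule: int,
                 seed: int = 0, n_backbone=(2, 5), charge_probs=None,
                 scale: float = 0.08, element_weights=None,
                 spec: ToyPotentialSpec | None = None) -> Dataset:
    """Labeled toy dataset: random molecules × near-equilibrium conformers."""
    rng = np.random.default_rng(seed)
    spec = spec or ToyPotentialSpec()
    pot = ToyPotential(spec)
    if charge_probs is None:
        charge_probs = {-1: 0.15, 0: 0.70, 1: 0.15}
    qs = np.array(list(charge_probs.keys()))
    qp = np.array(list(charge_probs.values()), dtype=float)
    qp /= qp.sum()
    samples = []
    for k in range(n_molecules):
        nb = int(rng.integers(n_backbone[0], n_backbone[1] + 1))
        q = int(rng.choice(qs, p=qp))
        mol = None
        for _ in range(50):   # redraw when the valence draw cannot grow
            try:
                mol = generate_molecule(nb, element_weights=element_weights,
                                        charge=q,
                                        seed=int(rng.integers(2 ** 31)),
                                        spec=spec)
                break
            except GenerationError:
                continue
        if mol is None:
            raise GenerationError("could not draw a feasible molecule")
        confs = sample_conformers(mol, conformers_per_molecule, scale=scale,
                                  seed=int(rng.integers(2 ** 31)))
        for c in confs:
            samples.append(pot.label(c, molecule_id=str(k)))
    return Dataset(samples, metadata={"seed": seed, "kind": "toy-conformers"})
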