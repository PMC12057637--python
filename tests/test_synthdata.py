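"""Toy potential self-consistency and structure generators."""

import numpy as np
import pytest

from aimpot.synthdata import (GenerationError, ToyPotential, ToyPotentialSpec,
                              build_cluster, extract_nmers, generate_molecule,
                              label_with_toy, sample_conformers)
from aimpot.system import MolecularSystem


class TestToyPotential:
    def test_homodiatomic_minimum_is_morse_minimum(self, toypot):
        d_e, a, re = toypot.spec.morse(8, 8)
        s = MolecularSystem(np.array([[0., 0, 0], [0, 0, re]]),
                            np.array([8, 8]), bonds=[[0, 1]])
        e, f = toypot.energy_forces(s)
        assert e == pytest.approx(-d_e, abs=1e-12)   # no charges, no 1-3
        assert np.abs(f).max() < 1e-10

    def test_forces_match_finite_differences(self, toypot, rng):
        for seed in (3, 17):
            mol = generate_molecule(4, seed=seed, charge=-1)
            e0, f = toypot.energy_forces(mol)
            h = 1e-5
            for i in range(min(mol.n_atoms, 5)):
                for ax in range(3):
                    cp, cm = mol.copy(), mol.copy()
                    cp.coords[i, ax] += h
                    cm.coords[i, ax] -= h
                    fd = -(toypot.energy_forces(cp)[0]
                           - toypot.energy_forces(cm)[0]) / (2 * h)
                    assert abs(fd - f[i, ax]) < 1e-7

    def test_periodic_forces_match_finite_differences(self, toypot):
        pool = [generate_molecule(2, seed=s) for s in (1, 2)]
        cluster = build_cluster(pool, seed=5)
        _, f = toypot.energy_forces(cluster)
        h = 1e-5
        for i in (0, cluster.n_atoms - 1):
            for ax in range(3):
                cp, cm = cluster.copy(), cluster.copy()
                cp.coords[i, ax] += h
                cm.coords[i, ax] -= h
                fd = -(toypot.energy_forces(cp)[0]
                       - toypot.energy_forces(cm)[0]) / (2 * h)
                assert abs(fd - f[i, ax]) < 1e-6

    def test_charges_sum_to_total_charge(self, toypot, rng):
        for k in range(100):
            q = int(rng.integers(-3, 4))
            mol = generate_molecule(int(rng.integers(1, 5)), charge=q,
                                    seed=int(rng.integers(2 ** 31)))
            charges = toypot.charges(mol)
            assert abs(charges.sum() - q) < 1e-10

    def test_labels_are_internally_consistent(self, toypot):
        mol = generate_molecule(3, seed=9, charge=1)
        sample = toypot.label(mol)
        assert abs(sample.charges.sum() - 1) < 1e-8
        assert abs(np.trace(sample.quadrupole)) < 1e-10
        e, f = toypot.energy_forces(mol)
        assert sample.energy == e
        assert np.array_equal(sample.forces, f)


class TestGenerateMolecule:
    def test_single_hydrogen_atom(self):
        m = generate_molecule(1, element_weights={"H": 1.0}, seed=0,
                              saturate=False)
        assert m.n_atoms == 1 and m.atomic_numbers[0] == 1
        assert np.allclose(m.coords, 0.0)

    def test_deterministic_under_seed(self):
        a = generate_molecule(4, seed=77)
        b = generate_molecule(4, seed=77)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.atomic_numbers, b.atomic_numbers)
        assert np.array_equal(a.bonds, b.bonds)

    def test_no_clashes_across_many_molecules(self):
        worst = np.inf
        for seed in range(200):
            m = generate_molecule(3 + seed % 3, seed=seed)
            d = np.linalg.norm(m.coords[None] - m.coords[:, None], axis=-1)
            np.fill_diagonal(d, np.inf)
            worst = min(worst, d.min())
        assert worst >= 0.7

    def test_valences_respected(self):
        from aimpot.units import VALENCE
        for seed in range(30):
            m = generate_molecule(4, seed=seed)
            deg = np.zeros(m.n_atoms, dtype=int)
            for i, j in m.bonds:
                deg[i] += 1
                deg[j] += 1
            for k in range(m.n_atoms):
                assert deg[k] <= VALENCE[int(m.atomic_numbers[k])]

    def test_infeasible_weights_raise(self):
        with pytest.raises(GenerationError):
            generate_molecule(4, element_weights={"H": 1.0}, seed=0)


class TestConformers:
    def test_zero_scale_zero_twist_identity(self):
        m = generate_molecule(3, seed=5)
        confs = sample_conformers(m, 3, scale=0.0, twist=0.0, seed=1)
        for c in confs:
            assert np.abs(c.coords - m.coords).max() < 1e-12

    def test_count_and_determinism(self):
        m = generate_molecule(4, seed=6)
        a = sample_conformers(m, 100, seed=9)
        b = sample_conformers(m, 100, seed=9)
        assert len(a) == 100
        assert all(np.array_equal(x.coords, y.coords) for x, y in zip(a, b))
        # frames are distinct
        assert np.abs(a[0].coords - a[1].coords).max() > 1e-6

    def test_rmsd_grows_with_scale(self):
        m = generate_molecule(4, seed=8)
        means = []
        for scale in (0.05, 0.1, 0.2):
            rmsds = []
            for seed in range(5):
                confs = sample_conformers(m, 20, scale=scale, twist=0.0,
                                          seed=seed)
                rmsds += [np.sqrt(((c.coords - m.coords) ** 2).mean())
                          for c in confs]
            means.append(np.mean(rmsds))
        assert means[0] < means[1] < means[2]


class TestClusters:
    @pytest.fixture(scope="class")
    def pool(self):
        return [generate_molecule(n, seed=s) for s, n in
                enumerate((2, 2, 3, 3))]

    def test_clearance_enforced(self, pool):
        for seed in range(30):
            cl = build_cluster(pool, seed=seed)
            comps = _components(cl)
            for a in range(len(comps)):
                for b in range(a + 1, len(comps)):
                    d = cl.coords[comps[a]][:, None] - cl.coords[comps[b]]
                    d -= cl.cell * np.round(d / cl.cell)
                    assert np.linalg.norm(d, axis=-1).min() >= 1.5

    def test_cell_and_count_bounds(self, pool):
        for seed in range(50):
            cl = build_cluster(pool, seed=seed)
            assert np.all(cl.cell >= 20.0) and np.all(cl.cell <= 30.0)
            n_mol = len(_components(cl))
            assert 2 <= n_mol <= 5

    def test_empty_pool_rejected(self):
        from aimpot.synthdata import PackingError
        with pytest.raises(PackingError):
            build_cluster([], seed=0)


class TestExtractNmers:
    def _dimer_cluster(self, separation):
        m = generate_molecule(2, seed=3)
        coords = np.concatenate([m.coords,
                                 m.coords + [separation, 0, 0]])
        return MolecularSystem(
            coords, np.tile(m.atomic_numbers, 2),
            cell=[60., 60, 60], pbc=[True] * 3,
            bonds=np.concatenate([m.bonds, m.bonds + m.n_atoms]))

    def test_distant_pair_gives_no_dimer(self):
        assert extract_nmers(self._dimer_cluster(25.0)) == []

    def test_close_pair_gives_exactly_one_dimer(self):
        out = extract_nmers(self._dimer_cluster(5.0))
        assert len(out) == 1
        assert out[0].pbc is None or not out[0].pbc.any()

    def test_chain_matches_powerset_oracle(self):
        """A–B–C chain with A–C distant: each group must satisfy the
        every-monomer-in-contact rule, checked against brute force."""
        m = generate_molecule(2, seed=4)
        gap = 5.0
        coords = np.concatenate([m.coords,
                                 m.coords + [gap + 3.0, 0, 0],
                                 m.coords + [2 * (gap + 3.0), 0, 0]])
        cl = MolecularSystem(coords, np.tile(m.atomic_numbers, 3),
                             cell=[80.] * 3, pbc=[True] * 3,
                             bonds=np.concatenate(
                                 [m.bonds, m.bonds + m.n_atoms,
                                  m.bonds + 2 * m.n_atoms]))
        out = extract_nmers(cl, cutoff=6.0)
        comps = _components(cl)
        from itertools import combinations
        want = 0
        for order in (2, 3):
            for group in combinations(range(3), order):
                ok = True
                for a in group:
                    touches = False
                    for b in group:
                        if a == b:
                            continue
                        d = cl.coords[comps[a]][:, None] - cl.coords[comps[b]]
                        d -= cl.cell * np.round(d / cl.cell)
                        if np.linalg.norm(d, axis=-1).min() < 6.0:
                            touches = True
                    ok = ok and touches
                want += ok
        assert len(out) == want


def _components(system):
    n = system.n_atoms
    adj = [[] for _ in range(n)]
    for i, j in system.bonds:
        adj[i].append(j)
        adj[j].append(i)
    seen = np.zeros(n, dtype=bool)
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            c = stack.pop()
            comp.append(c)
            for nb in adj[c]:
                if not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(sorted(comp))
    return comps
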