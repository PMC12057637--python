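"""Message-passing core: convolution oracles, NQE, invariances, locality,
checkpoint persistence."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from aimpot import autodiff as ad
from aimpot.core import (EquilibrationDegenerateError, ModelConfig,
                         charge_conv, forward_system, init_params,
                         load_checkpoint, nqe, save_checkpoint, scalar_conv,
                         vector_conv, wrap_params, _NORM_EPS)
from aimpot.featurize import RadialBasisSpec, dense_geometry_graph
from aimpot.system import MolecularSystem
from conftest import random_system


def _features(coords, spec=None):
    spec = spec or RadialBasisSpec()
    c = ad.tensor(coords[None], requires_grad=False)
    return dense_geometry_graph(c, spec)


class TestScalarConv:
    def test_isolated_atom_gives_zeros(self):
        g, u, r, od = _features(np.array([[0., 0, 0], [0, 0, 50.0]]))
        a = ad.tensor(np.random.default_rng(0).normal(size=(1, 2, 4, 16)))
        v = scalar_conv(g, a)
        assert np.abs(v.data).max() == 0.0

    def test_matches_naive_loop(self, rng):
        coords = random_system(rng, 5).coords
        g, u, r, od = _features(coords)
        a = ad.tensor(rng.normal(size=(1, 5, 4, 16)))
        v = scalar_conv(g, a).data[0]
        naive = np.zeros_like(v)
        for i in range(5):
            for j in range(5):
                for s in range(16):
                    naive[i, :, s] += g.data[0, i, j, s] * a.data[0, j, :, s]
        assert np.abs(v - naive).max() < 1e-12


class TestVectorConv:
    def test_opposite_equidistant_neighbors_cancel(self, rng):
        coords = np.array([[0., 0, 0], [0, 0, 2.0], [0, 0, -2.0]])
        g, u, r, od = _features(coords)
        a_np = rng.normal(size=(1, 3, 4, 16))
        a_np[0, 2] = a_np[0, 1]        # identical neighbor features
        w = ad.tensor(rng.normal(size=(4, 16, 2)))
        v = vector_conv(g, u, ad.tensor(a_np), w)
        assert np.abs(v.data[0, 0]).max() < np.sqrt(_NORM_EPS) * 1.01

    def test_single_neighbor_direction_independent(self, rng):
        w = ad.tensor(rng.normal(size=(4, 16, 2)))
        outs = []
        for direction in ([0, 0, 2.0], [1.2, -0.7, 0.9]):
            d = np.array(direction)
            coords = np.stack([np.zeros(3), 2.0 * d / np.linalg.norm(d)])
            g, u, r, od = _features(coords)
            a = ad.tensor(np.ones((1, 2, 4, 16)))
            outs.append(vector_conv(g, u, a, w).data[0, 0])
        assert np.abs(outs[0] - outs[1]).max() < 1e-10

    def test_rotation_invariance(self, rng):
        coords = random_system(rng, 6).coords
        R = Rotation.random(random_state=7).as_matrix()
        a = ad.tensor(rng.normal(size=(1, 6, 4, 16)))
        w = ad.tensor(rng.normal(size=(4, 16, 3)))
        g1, u1, *_ = _features(coords)
        g2, u2, *_ = _features(coords @ R.T)
        v1 = vector_conv(g1, u1, a, w)
        v2 = vector_conv(g2, u2, a, w)
        assert np.abs(v1.data - v2.data).max() < 1e-8

    def test_matches_naive_loop(self, rng):
        coords = random_system(rng, 5).coords
        g, u, r, od = _features(coords)
        a = ad.tensor(rng.normal(size=(1, 5, 3, 16)))
        w = ad.tensor(rng.normal(size=(3, 16, 2)))
        v = vector_conv(g, u, a, w).data[0]
        m = np.zeros((5, 3, 3, 2))          # (i, x, d, h)
        for i in range(5):
            for j in range(5):
                t = np.einsum("s,ds,dsh->dh", g.data[0, i, j],
                              a.data[0, j], w.data)
                m[i] += u.data[0, i, j][:, None, None] * t
        naive = np.sqrt((m ** 2).sum(axis=1) + _NORM_EPS)
        assert np.abs(v - naive).max() < 1e-12


class TestChargeConv:
    def test_zero_charges_zero_features(self, rng):
        coords = random_system(rng, 4).coords
        g, u, r, od = _features(coords)
        q = ad.tensor(np.zeros((1, 4)))
        wq = ad.tensor(rng.normal(size=(4, 16, 2)))
        vs, vv = charge_conv(g, u, q, wq)
        assert np.abs(vs.data).max() == 0.0
        assert np.abs(vv.data - np.sqrt(_NORM_EPS)).max() < 1e-12

    def test_symmetric_opposite_charges(self, rng):
        coords = np.array([[0., 0, 0], [0, 0, 2.0], [0, 0, -2.0]])
        g, u, r, od = _features(coords)
        q = ad.tensor(np.array([[0.0, 0.5, -0.5]]))
        wq = ad.tensor(rng.normal(size=(2, 16, 2)))
        vs, vv = charge_conv(g, u, q, wq)
        # scalar channel cancels at the center; vector channel does not
        assert np.abs(vs.data[0, 0]).max() < 1e-12
        assert np.abs(vv.data[0, 0]).max() > 1e-3

    def test_matches_naive_loop(self, rng):
        coords = random_system(rng, 6).coords
        g, u, r, od = _features(coords)
        qv = rng.normal(size=(1, 6))
        wq_v = rng.normal(size=(3, 16, 2))
        vs, vv = charge_conv(g, u, ad.tensor(qv), ad.tensor(wq_v))
        naive_s = np.einsum("ijs,j->is", g.data[0], qv[0])
        assert np.abs(vs.data[0] - naive_s).max() < 1e-12
        m = np.zeros((6, 3, 3, 2))
        for i in range(6):
            for j in range(6):
                t = np.einsum("s,dsh->dh", g.data[0, i, j],
                              wq_v) * qv[0, j]
                m[i] += u.data[0, i, j][:, None, None] * t
        naive_v = np.sqrt((m ** 2).sum(axis=1) + _NORM_EPS)
        assert np.abs(vv.data[0] - naive_v).max() < 1e-12


class TestNQE:
    def test_balanced_charges_untouched(self):
        q = nqe(ad.tensor([0.3, -0.3]), ad.tensor([2.0, 7.0]), 0.0)
        assert np.allclose(q.data, [0.3, -0.3], atol=1e-14)

    def test_hand_computed_redistribution(self):
        q = nqe(ad.tensor([0.0, 0.0]), ad.tensor([1.0, 3.0]), -1.0)
        assert np.allclose(q.data, [-0.25, -0.75], atol=1e-14)

    def test_conservation_for_random_inputs(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 12))
            q_t = rng.normal(size=n)
            f = rng.uniform(0.01, 2.0, size=n)
            Q = float(rng.integers(-9, 10))
            q = nqe(ad.tensor(q_t), ad.tensor(f), Q)
            assert abs(q.data.sum() - Q) < 1e-10

    def test_zero_weights_rejected(self):
        with pytest.raises(EquilibrationDegenerateError):
            nqe(ad.tensor([0.1, 0.2]), ad.tensor([0.0, 0.0]), 0.0)


class TestForward:
    CFG = ModelConfig(hidden=(32, 16), n_passes=2, seed=5)

    def test_isolated_charged_atom_carries_full_charge(self):
        s = MolecularSystem(np.zeros((1, 3)), np.array([8]), charge=-1)
        pt = wrap_params(init_params(self.CFG))
        out = forward_system(pt, s, self.CFG)
        assert np.allclose(out["charges"].data, [[-1.0]], atol=1e-12)

    def test_permutation_equivariance(self, rng):
        s = random_system(rng, 7, charge=1)
        perm = rng.permutation(7)
        s2 = MolecularSystem(s.coords[perm], s.atomic_numbers[perm],
                             charge=1)
        pt = wrap_params(init_params(self.CFG))
        o1 = forward_system(pt, s, self.CFG)
        o2 = forward_system(pt, s2, self.CFG)
        assert np.abs(o2["charges"].data[0]
                      - o1["charges"].data[0][perm]).max() < 1e-10
        assert abs(o2["energy_local"].data[0]
                   - o1["energy_local"].data[0]) < 1e-10

    def test_unrolled_two_pass_sequence_reproduced(self, rng):
        """The forward matches an explicit conv→update→NQE unroll."""
        from aimpot.core import _gelu, _mlp, forward_batch
        cfg = ModelConfig(hidden=(16, 8), n_passes=2, seed=9)
        params = init_params(cfg)
        pt = wrap_params(params)
        s = random_system(rng, 4, charge=-1)
        from aimpot.units import species_index
        zidx = species_index(s.atomic_numbers)[None]
        coords = ad.tensor(s.coords[None])
        out = forward_batch(pt, zidx, coords, np.array([-1.0]), cfg)

        g, u, r, od = dense_geometry_graph(coords, cfg.basis)
        a = pt["embed"][zidx]
        Q = np.array([[-1.0]])
        q = None
        for p in (1, 2):
            feats = [ad.reshape(scalar_conv(g, a), (1, 4, cfg.d * cfg.s)),
                     ad.reshape(vector_conv(g, u, a, pt[f"w_dsh_{p}"]),
                                (1, 4, cfg.d * cfg.h))]
            if p == 2:
                vqs, vqv = charge_conv(g, u, q, pt[f"wq_dsh_{p}"])
                feats += [vqs, ad.reshape(vqv, (1, 4, cfg.d * cfg.h))]
            x = ad.concatenate(feats, axis=2)
            o = _mlp(pt, f"pass{p}_", x, 3)
            qf = _mlp(pt, f"charge{p}_", x, 2)
            a = a + ad.reshape(o, (1, 4, cfg.d, cfg.s))
            q_t = qf[:, :, 0] if p == 1 else q + qf[:, :, 0]
            f = ad.softplus(qf[:, :, 1]) + 1e-6
            q = nqe(q_t, f, Q)
        assert np.abs(out["charges"].data - q.data).max() < 1e-12

    def test_locality_beyond_message_range(self, rng):
        """Perturbing an atom > n_passes×cutoff away leaves AIM unchanged."""
        cfg = self.CFG
        pt = wrap_params(init_params(cfg))
        near = random_system(rng, 4, box=3.0)
        far1 = np.array([[0.0, 0.0, 25.0]])
        far2 = np.array([[0.0, 1.0, 25.0]])
        for far in (far1, far2):
            coords = np.concatenate([near.coords, far])
            z = np.concatenate([near.atomic_numbers, [8]])
            s = MolecularSystem(coords, z)
            out = forward_system(pt, s, cfg)
            aim = out["aim"].data[0, :4]
            if far is far1:
                ref = aim
            else:
                assert np.abs(aim - ref).max() < 1e-12

    def test_charge_conservation_strongly_charged(self, rng):
        pt = wrap_params(init_params(self.CFG))
        for Q in (-9, -3, 5, 9):
            s = random_system(rng, 6, charge=Q)
            out = forward_system(pt, s, self.CFG)
            assert abs(out["charges"].data.sum() - Q) < 1e-10


class TestCheckpoint:
    def test_bit_exact_roundtrip(self, tmp_path, rng):
        cfg = ModelConfig(hidden=(24, 12), seed=2)
        params = init_params(cfg)
        path = tmp_path / "model.npz"
        save_checkpoint(path, params, cfg, extra={"note": "test"})
        back, cfg2, extra = load_checkpoint(path)
        assert cfg2.to_dict() == cfg.to_dict()
        assert extra["note"] == "test"
        assert set(back) == set(params)
        for k in params:
            assert np.array_equal(back[k], params[k])
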