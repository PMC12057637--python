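"""Multipoles, the weighted loss, and the training loop mechanics."""

import numpy as np
import pytest

from aimpot import autodiff as ad
from aimpot.core import ModelConfig, wrap_params
from aimpot.multipoles import dipole_from_charges, quadrupole_from_charges
from aimpot.potential import NeuralPotential
from aimpot.synthdata import make_dataset
from aimpot.system import Dataset, group_by_size
from aimpot.training import (LossWeights, TrainConfig, _Batch,
                             _batch_predictions, _cached_predictions,
                             evaluate, loss, train)


class TestMultipoles:
    def test_two_charge_dipole_hand_value(self):
        coords = np.array([[0., 0, 1], [0, 0, -1]])
        mu = dipole_from_charges(coords, [0.5, -0.5], np.zeros(3))
        assert np.allclose(mu, [0, 0, 1.0])

    def test_neutral_dipole_translation_invariant(self, rng):
        coords = rng.normal(size=(5, 3))
        q = rng.normal(size=5)
        q -= q.mean()          # neutral
        mu1 = dipole_from_charges(coords, q, np.zeros(3))
        mu2 = dipole_from_charges(coords + 10.0, q, np.zeros(3))
        assert np.allclose(mu1, mu2, atol=1e-12)

    def test_zero_charges_zero_moments(self, rng):
        coords = rng.normal(size=(4, 3))
        assert np.allclose(dipole_from_charges(coords, np.zeros(4),
                                               np.zeros(3)), 0.0)
        assert np.allclose(quadrupole_from_charges(coords, np.zeros(4),
                                                   np.zeros(3)), 0.0)

    def test_linear_pair_quadrupole_closed_form(self):
        d = 1.3
        q = 0.4
        coords = np.array([[0., 0, d], [0, 0, -d]])
        theta = quadrupole_from_charges(coords, [q, q], np.zeros(3))
        # Θ_zz = Σ q(3z² - r²)/2 = 2·q·d²; Θ_xx = Θ_yy = -q·d²
        assert theta[2, 2] == pytest.approx(2 * q * d * d)
        assert theta[0, 0] == pytest.approx(-q * d * d)
        assert theta[2, 2] == pytest.approx(-2 * theta[0, 0])

    def test_traceless_for_random_inputs(self, rng):
        theta = quadrupole_from_charges(rng.normal(size=(6, 3)),
                                        rng.normal(size=6), np.zeros(3))
        assert abs(np.trace(theta)) < 1e-10
        assert np.allclose(theta, theta.T)


def _tiny_batch(n_mol=4, seed=0):
    ds = make_dataset(2, n_mol // 2 + 1, seed=seed)
    idx = group_by_size(ds, 64)[0]
    return ds, _Batch([ds.samples[i] for i in idx], None, idx)


class TestLoss:
    def test_perfect_predictions_give_zero(self):
        _, batch = _tiny_batch()
        preds = {"energy": ad.tensor(batch.energy),
                 "forces": ad.tensor(batch.forces),
                 "charges": ad.tensor(batch.charges),
                 "dipole": ad.tensor(batch.dipole),
                 "quadrupole": ad.tensor(batch.quad)}
        total, report = loss(preds, batch, LossWeights())
        assert float(total.data) == 0.0
        assert all(v == 0.0 for v in report.values())

    def test_single_molecule_energy_scaling_hand_value(self):
        """ΔE = 0.1 eV on a diatomic with w_E only -> (0.1/√2)² = 0.005."""
        from aimpot.synthdata import generate_molecule, label_with_toy
        mol = generate_molecule(1, element_weights={"O": 1.0}, seed=1,
                                saturate=False)
        two = mol.copy()
        two.coords = np.array([[0., 0, 0], [0, 0, 1.2]])
        import aimpot.system as sysm
        sample = label_with_toy(
            sysm.MolecularSystem(two.coords, np.array([8, 8]),
                                 bonds=[[0, 1]]))
        batch = _Batch([sample])
        preds = {"energy": ad.tensor(batch.energy + 0.1),
                 "forces": ad.tensor(batch.forces),
                 "charges": ad.tensor(batch.charges),
                 "dipole": ad.tensor(batch.dipole),
                 "quadrupole": ad.tensor(batch.quad)}
        w = LossWeights(w_e=1.0, w_f=0.0, w_d=0.0, w_t=0.0, w_q=0.0)
        total, report = loss(preds, batch, w)
        assert report["energy"] == pytest.approx(0.005, rel=1e-10)
        assert float(total.data) == pytest.approx(0.005, rel=1e-10)

    def test_weighted_terms_resum_to_scalar(self, rng):
        _, batch = _tiny_batch(seed=3)
        rngl = np.random.default_rng(0)
        preds = {"energy": ad.tensor(batch.energy + rngl.normal(
            size=batch.energy.shape)),
            "forces": ad.tensor(batch.forces + rngl.normal(
                size=batch.forces.shape)),
            "charges": ad.tensor(batch.charges + 0.1),
            "dipole": ad.tensor(batch.dipole + 0.2),
            "quadrupole": ad.tensor(batch.quad + 0.05)}
        w = LossWeights(w_q=0.2).normalized()
        total, rep = loss(preds, batch, w)
        resum = (w.w_e * rep["energy"] + w.w_f * rep["forces"]
                 + w.w_q * rep["charges"] + w.w_d * rep["dipole"]
                 + w.w_t * rep["quadrupole"])
        assert float(total.data) == pytest.approx(resum, abs=1e-10)

    def test_normalization_keeps_ratios(self):
        w = LossWeights(1.0, 0.2, 0.05, 0.02, 0.0).normalized()
        assert w.w_e + w.w_f + w.w_d + w.w_t + w.w_q == pytest.approx(1.0)
        assert w.w_e / w.w_f == pytest.approx(5.0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(0, 0, 0, 0, 0)


class TestCachedPathEquivalence:
    def test_cached_features_match_direct_graph(self):
        """Fast-path predictions/gradients equal the coordinate-graph path."""
        ds, batch = _tiny_batch(seed=7)
        pot = NeuralPotential(config=ModelConfig(hidden=(24, 12),
                                                 n_passes=3, seed=5))
        w = LossWeights(w_q=0.2)
        pt1 = wrap_params(pot.params)
        p1 = _batch_predictions(pot, batch, params_t=pt1, need_forces=True)
        l1, _ = loss(p1, batch, w)
        g1 = [t.data for t in ad.grad(l1, list(pt1.values()))]
        pt2 = wrap_params(pot.params)
        p2 = _cached_predictions(pot, batch, pt2, need_forces=True)
        l2, _ = loss(p2, batch, w)
        g2 = [t.data for t in ad.grad(l2, list(pt2.values()))]
        assert np.abs(p1["forces"].data - p2["forces"].data).max() < 1e-12
        assert float(l1.data) == pytest.approx(float(l2.data), rel=1e-12)
        for a, b in zip(g1, g2):
            assert np.abs(a - b).max() < 1e-12


class TestTrainLoop:
    CFG = ModelConfig(hidden=(24, 12), n_passes=2, seed=3)

    def test_overfits_small_set_and_is_deterministic(self):
        ds = make_dataset(2, 8, seed=11)
        tc = TrainConfig(batch_size=8, lr=3e-3, max_epochs=12, seed=4,
                         val_fraction=0.2)
        pot1, log1 = train(ds, NeuralPotential(config=self.CFG, d3=None), tc)
        first, last = log1[0]["train_loss"], log1[-1]["train_loss"]
        assert last < first * 0.5          # clear descent on a toy fit
        pot2, log2 = train(ds, NeuralPotential(config=self.CFG, d3=None), tc)
        assert log1[0]["train_loss"] == log2[0]["train_loss"]
        assert log1[-1]["val_loss"] == log2[-1]["val_loss"]

    def test_learning_rate_schedule_non_increasing(self):
        ds = make_dataset(2, 6, seed=12)
        tc = TrainConfig(batch_size=8, lr=1e-3, max_epochs=8, seed=1,
                         plateau_patience=1, plateau_factor=0.5)
        _, log = train(ds, NeuralPotential(config=self.CFG, d3=None), tc)
        lrs = [e["lr"] for e in log]
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))

    def test_divergence_aborts_with_context(self):
        ds = make_dataset(2, 6, seed=13)
        tc = TrainConfig(batch_size=8, lr=1e6, max_epochs=5, seed=1)
        with pytest.raises(FloatingPointError):
            train(ds, NeuralPotential(config=self.CFG, d3=None), tc)


class TestEvaluate:
    def test_zero_error_against_own_predictions(self):
        from aimpot.system import LabeledSample
        ds = make_dataset(2, 4, seed=21)
        pot = NeuralPotential(config=ModelConfig(hidden=(16, 8),
                                                 n_passes=2, seed=8))
        relabeled = []
        for s in ds.samples:
            b = pot.predict(s.system)
            relabeled.append(LabeledSample(
                system=s.system, energy=b.u_total, forces=b.forces,
                charges=b.charges - (b.charges.sum() - s.system.charge)
                / len(b.charges)))
        table, agg = evaluate(pot, Dataset(relabeled))
        assert agg["energy_mae"] < 1e-9
        assert agg["force_mae"] < 1e-9
        assert len(table) == len(ds)

    def test_aggregates_match_table(self):
        ds = make_dataset(3, 4, seed=22)
        pot = NeuralPotential(config=ModelConfig(hidden=(16, 8),
                                                 n_passes=2, seed=9))
        table, agg = evaluate(pot, ds)
        assert agg["energy_mae"] == pytest.approx(table["abs_de"].mean())
        assert agg["force_mae"] == pytest.approx(table["force_mae"].mean())
        assert len(table) == len(ds)
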