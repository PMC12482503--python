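import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from synthprice import (
    TrainConfig,
    class_latent_stats,
    contrastive_loss,
    finetune_contrastive,
    freeze_readout,
    hellinger_affinity,
)
from synthprice.contrastive import SIGMA_FLOOR, _contrastive_step
from synthprice.errors import ConfigError, DegenerateBatchError
from synthprice.price_model import PriceModel, mse_batch_grads


class TestHellingerAffinity:
    def test_identical_distributions_have_affinity_one(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            mu, sigma = rng.normal(0, 10), rng.uniform(1e-3, 10)
            assert hellinger_affinity(mu, sigma, mu, sigma) == pytest.approx(1.0, abs=1e-12)

    def test_vanishes_as_means_separate(self):
        assert hellinger_affinity(0.0, 1.0, 100.0, 1.0) < 1e-6
        vals = [hellinger_affinity(0, 1, d, 1) for d in (0, 1, 2, 5, 10)]
        assert vals == sorted(vals, reverse=True)

    def test_symmetric_in_the_two_distributions(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            m1, m2 = rng.normal(0, 3, 2)
            s1, s2 = rng.uniform(0.1, 3, 2)
            assert hellinger_affinity(m1, s1, m2, s2) == pytest.approx(
                hellinger_affinity(m2, s2, m1, s1), abs=1e-15
            )

    def test_matches_bhattacharyya_quadrature_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            m1, m2 = rng.normal(0, 3, 2)
            s1, s2 = rng.uniform(0.2, 3, 2)
            closed = hellinger_affinity(m1, s1, m2, s2)
            numeric, _ = quad(
                lambda x: np.sqrt(norm.pdf(x, m1, s1) * norm.pdf(x, m2, s2)),
                -60, 60, limit=200,
            )
            assert closed == pytest.approx(numeric, abs=1e-6)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        m = rng.normal(0, 5, 200)
        s = rng.uniform(0.01, 5, 200)
        h = hellinger_affinity(m[:100], s[:100], m[100:], s[100:])
        assert np.all(h > 0) and np.all(h <= 1)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            hellinger_affinity(0, 0.0, 0, 1.0)
        with pytest.raises(ValueError):
            hellinger_affinity(0, 1.0, 0, -2.0)


class TestClassLatentStats:
    def test_hand_computed_four_by_two(self):
        Z = np.array([[0.0, 2.0], [2.0, 4.0], [10.0, 0.0], [14.0, 2.0]])
        labels = np.array(["ES", "ES", "HS", "HS"])
        st = class_latent_stats(Z, labels)
        np.testing.assert_allclose(st.mu_es, [1.0, 3.0])
        np.testing.assert_allclose(st.mu_hs, [12.0, 1.0])
        np.testing.assert_allclose(st.sigma_es, [1.0, 1.0])  # population SD
        np.testing.assert_allclose(st.sigma_hs, [2.0, 1.0])
        assert (st.n_es, st.n_hs) == (2, 2)

    def test_identical_rows_floor_sigma(self):
        Z = np.array([[1.0, 1.0], [1.0, 1.0], [3.0, 3.0], [3.0, 3.0]])
        st = class_latent_stats(Z, np.array([False, False, True, True]))
        np.testing.assert_array_equal(st.sigma_es, SIGMA_FLOOR)
        np.testing.assert_array_equal(st.sigma_hs, SIGMA_FLOOR)

    def test_permutation_within_class_is_invariant(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(20, 4))
        labels = np.array([False] * 10 + [True] * 10)
        st1 = class_latent_stats(Z, labels)
        perm = np.concatenate([rng.permutation(10), 10 + rng.permutation(10)])
        st2 = class_latent_stats(Z[perm], labels)
        np.testing.assert_allclose(st1.mu_es, st2.mu_es)
        np.testing.assert_allclose(st1.sigma_hs, st2.sigma_hs)

    def test_single_class_batch_rejected(self):
        with pytest.raises(DegenerateBatchError):
            class_latent_stats(np.zeros((4, 2)), np.array([True] * 4))


class TestContrastiveLoss:
    def _stats(self, identical=True):
        Z = np.random.default_rng(0).normal(size=(40, 5))
        if identical:
            latents = np.vstack([Z, Z])
            labels = np.array([False] * 40 + [True] * 40)
        else:
            latents = np.vstack([Z, Z + 50.0])
            labels = np.array([False] * 40 + [True] * 40)
        return class_latent_stats(latents, labels)

    def test_lambda_zero_reduces_exactly_to_batch_mse(self):
        rng = np.random.default_rng(1)
        pred, target = rng.normal(size=30), rng.normal(size=30)
        comps = contrastive_loss(pred, target, self._stats(), lam=0.0)
        assert comps.total == float(np.mean((pred - target) ** 2))

    def test_perfect_fit_and_identical_stats_leave_pure_hellinger(self):
        y = np.random.default_rng(2).normal(size=20)
        comps = contrastive_loss(y, y, self._stats(identical=True), lam=0.05)
        assert comps.mse_es == 0.0
        assert comps.hellinger_mean == pytest.approx(1.0, abs=1e-12)
        assert comps.total == pytest.approx(0.05, abs=1e-12)

    def test_penalty_inactive_below_default_bound(self):
        y = np.zeros(10)
        comps = contrastive_loss(
            y, y, self._stats(), lam=0.05,
            penalty_cfg={"X": 20.0, "hs_pred": np.full(8, 15.0)},
        )
        assert comps.hs_penalty == 0.0

    def test_penalty_active_above_bound(self):
        y = np.zeros(10)
        comps = contrastive_loss(
            y, y, self._stats(), lam=0.0,
            penalty_cfg={"X": 20.0, "hs_pred": np.array([25.0, 15.0])},
        )
        assert comps.hs_penalty == pytest.approx(2.5)  # mean(max(0, y - 20))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            contrastive_loss(np.zeros(3), np.zeros(4), self._stats(), 0.05)


class TestContrastiveGradients:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        m = PriceModel(12, hidden=(8,), latent_dim=4, seed=3)
        Xe, ye = rng.normal(size=(9, 12)), rng.normal(size=9)
        Xh = rng.normal(size=(7, 12))
        comps, grads = _contrastive_step(m, Xe, ye, Xh, lam=0.7, penalty_x=0.1)
        assert 0 < comps.hellinger_mean <= 1
        eps = 1e-6
        for k in m.params:
            flat = m.params[k].ravel()
            for idx in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                flat[idx] += eps
                lp, _ = _contrastive_step(m, Xe, ye, Xh, lam=0.7, penalty_x=0.1)
                flat[idx] -= 2 * eps
                lm, _ = _contrastive_step(m, Xe, ye, Xh, lam=0.7, penalty_x=0.1)
                flat[idx] += eps
                fd = (lp.total - lm.total) / (2 * eps)
                assert grads[k].ravel()[idx] == pytest.approx(fd, abs=1e-6, rel=1e-4)

    def test_lambda_zero_step_equals_pure_mse_gradients(self):
        rng = np.random.default_rng(1)
        m = freeze_readout(PriceModel(10, hidden=(6,), latent_dim=3, seed=2))
        Xe, ye = rng.normal(size=(8, 10)), rng.normal(size=8)
        Xh = rng.normal(size=(8, 10))
        _, g_contrastive = _contrastive_step(m, Xe, ye, Xh, lam=0.0, penalty_x=None)
        _, g_mse = mse_batch_grads(m, Xe, ye)
        for k in g_mse:
            np.testing.assert_allclose(g_contrastive[k], g_mse[k], atol=1e-12)


class TestFinetune:
    def test_requires_frozen_readout(self):
        m = PriceModel(8, hidden=(4,), latent_dim=2, seed=0)
        with pytest.raises(ConfigError):
            finetune_contrastive(
                m, (np.zeros((4, 8)), np.zeros(4)), (np.zeros((4, 8)), np.zeros(4)),
                np.zeros((4, 8)), np.zeros((4, 8)),
            )

    def test_readout_bit_identical_and_encoder_updated(self):
        rng = np.random.default_rng(2)
        m = freeze_readout(PriceModel(10, hidden=(6,), latent_dim=3, seed=1))
        w0, b0 = m.params["w_out"].copy(), m.params["b_out"].copy()
        enc0 = m.params["W0"].copy()
        Xe, ye = rng.normal(size=(64, 10)), rng.normal(size=64)
        Xh = rng.normal(size=(64, 10)) + 1.0
        cfg = TrainConfig(hidden=(6,), latent_dim=3, epochs=2, patience=5, seed=0)
        m, _ = finetune_contrastive(m, (Xe, ye), (Xe, ye), Xh, Xh, lam=0.5, config=cfg)
        assert np.array_equal(m.params["w_out"], w0)
        assert np.array_equal(m.params["b_out"], b0)
        assert not np.array_equal(m.params["W0"], enc0)
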