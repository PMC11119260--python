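"""Translation stage: loss arithmetic, oracle equivalence, synthesis."""

import dataclasses

import numpy as np
import pytest

from dttl import (CMTConfig, CMTWeights, cmt_objective, dt_loss, gan_losses,
                  identity_loss, mcc_loss, synthesize_minority, train_cmt)
from dttl.cda import PartitionedTarget
from dttl.cmt import init_state
from dttl.data import LabeledImages

identity = lambda x: x  # noqa: E731


def shift_by(c):
    return lambda x: x + c


class TestDTLoss:
    def test_identity_generator(self, rng):
        assert dt_loss(identity, rng.random((3, 4, 4))) == 0.0

    def test_constant_offset(self):
        batch = np.full((2, 4, 4), 0.5)
        g = lambda x: np.full_like(x, 0.7)  # noqa: E731
        assert dt_loss(g, batch) == pytest.approx(0.2, abs=1e-7)

    def test_batch_order_invariance(self, rng):
        batch = rng.random((5, 4, 4))
        g = shift_by(0.05)
        assert dt_loss(g, batch) == pytest.approx(dt_loss(g, batch[::-1]), abs=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            dt_loss(identity, np.empty((0, 4, 4)))


class TestMCCLoss:
    def test_identity_pair(self, rng):
        b = rng.random((2, 4, 4))
        assert mcc_loss(identity, identity, b, b) == 0.0

    def test_exact_inverse_pair(self):
        b = np.full((2, 4, 4), 0.5)  # interior values, no clipping
        assert mcc_loss(shift_by(0.1), shift_by(-0.1), b, b) == \
            pytest.approx(0.0, abs=1e-7)

    def test_one_sided_offset(self):
        b = np.full((2, 4, 4), 0.5)
        # G adds 0.1, G' identity: each present side contributes 0.1
        assert mcc_loss(shift_by(0.1), identity, b, np.empty((0, 4, 4))) == \
            pytest.approx(0.1, abs=1e-7)
        assert mcc_loss(shift_by(0.1), identity, b, b) == pytest.approx(0.2, abs=1e-7)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            mcc_loss(identity, identity, np.empty((0, 4, 4)), np.empty((0, 4, 4)))


class TestIdentityLoss:
    def test_identity_generators(self, rng):
        b = rng.random((3, 4, 4))
        assert identity_loss(identity, identity, b, b) == 0.0

    def test_zero_output_on_constant(self):
        b = np.full((2, 4, 4), 0.3)
        gp = lambda x: np.zeros_like(x)  # noqa: E731
        assert identity_loss(identity, gp, b, np.empty((0, 4, 4))) == \
            pytest.approx(0.3, abs=1e-7)

    def test_nonnegative(self, rng):
        g = lambda x: np.clip(x + rng.normal(0, 0.2, x.shape), 0, 1)  # noqa: E731
        b = rng.random((3, 4, 4))
        assert identity_loss(g, g, b, b) >= 0.0


class TestGANLosses:
    @pytest.fixture()
    def state(self):
        return init_state(CMTConfig(seed=0))

    def test_uninformative_discriminators(self, state, rng):
        """Zero-initialised final layers give exactly 0.5 everywhere."""
        b = rng.random((2, 16, 16)).astype(np.float32)
        for disc in (state.D_s, state.D_t):
            disc.layers[-2].W.value[...] = 0.0
            disc.layers[-2].b.value[...] = 0.0
        _, disc_obj = gan_losses(state, b, b, b, b)
        assert disc_obj == pytest.approx(4 * np.log(0.5), abs=1e-6)

    def test_single_sample_arithmetic(self, state, monkeypatch):
        b = np.zeros((1, 16, 16), dtype=np.float32)
        vals = {"D_t": [0.8, 0.3], "D_s": [0.9, 0.4]}

        def fake_disc_prob(disc, images):
            key = "D_t" if disc is state.D_t else "D_s"
            return np.array([vals[key].pop(0)])

        monkeypatch.setattr(state, "disc_prob", fake_disc_prob)
        gen_loss, disc_obj = gan_losses(state, b, b, b, b)
        expected = np.log(0.8) + np.log(0.7) + np.log(0.9) + np.log(0.6)
        assert disc_obj == pytest.approx(expected, abs=1e-9)
        assert gen_loss == pytest.approx(np.log(0.7) + np.log(0.6), abs=1e-9)

    def test_empty_batch_rejected(self, state):
        with pytest.raises(ValueError):
            gan_losses(state, np.empty((0, 16, 16)), np.zeros((1, 16, 16)),
                       np.zeros((1, 16, 16)), np.zeros((1, 16, 16)))


class TestCMTObjective:
    def test_zero_weights_return_gan(self):
        w = CMTWeights(lambda_dt=0, lambda_mcc=0, lambda_ide=0)
        assert cmt_objective(-1.5, 9, 9, 9, w) == -1.5

    def test_weighted_sum(self):
        w = CMTWeights(lambda_dt=1, lambda_mcc=10, lambda_ide=5)
        assert cmt_objective(-1.0, 0.2, 0.4, 0.1, w) == pytest.approx(3.7)

    def test_linearity(self):
        w = CMTWeights(lambda_dt=2, lambda_mcc=3, lambda_ide=4)
        base = cmt_objective(0, 0, 0, 0, w)
        assert cmt_objective(1, 1, 1, 1, w) - base == pytest.approx(1 + 2 + 3 + 4)


class TestLoopOracles:
    """Vectorised losses agree with scalar-loop re-implementations."""

    def _loop_l1(self, a, b):
        total, n = 0.0, 0
        for x, y in zip(a.ravel(), b.ravel()):
            total += abs(x - y)
            n += 1
        return total / n

    def test_losses_match_scalar_loops(self, rng):
        bs = rng.random((3, 4, 4))
        bt = rng.random((2, 4, 4))
        g, gp = shift_by(0.07), shift_by(-0.02)
        assert dt_loss(g, bt) == pytest.approx(self._loop_l1(g(bt), bt), abs=1e-6)
        expected = (self._loop_l1(gp(g(bs)), bs) + self._loop_l1(g(gp(bt)), bt))
        assert mcc_loss(g, gp, bs, bt) == pytest.approx(expected, abs=1e-6)
        expected = self._loop_l1(gp(bs), bs) + self._loop_l1(g(bt), bt)
        assert identity_loss(g, gp, bs, bt) == pytest.approx(expected, abs=1e-6)


def _partition_from_hidden(cohort):
    return PartitionedTarget(cohort.target_images,
                             cohort.target_hidden_labels.copy())


class TestTrainCMT:
    def test_zero_epochs_returns_initial_state(self, small_cohort):
        cfg = CMTConfig(max_epochs=0, seed=2)
        st = train_cmt(small_cohort.source, _partition_from_hidden(small_cohort), cfg)
        assert len(st.training_log) == 0

    def test_empty_subset_named_in_error(self, small_cohort):
        part = _partition_from_hidden(small_cohort)
        part.pseudo_labels[:] = 0  # no pseudo-minority left
        with pytest.raises(ValueError, match="pseudo-minority"):
            train_cmt(small_cohort.source, part, CMTConfig(max_epochs=1))

    def test_fixed_seed_reproduces_training_log(self, small_cohort):
        cfg = CMTConfig(max_epochs=1, seed=8)
        part = _partition_from_hidden(small_cohort)
        a = train_cmt(small_cohort.source, part, cfg)
        b = train_cmt(small_cohort.source, part, cfg)
        assert a.training_log.equals(b.training_log)

    def test_loss_components_logged_and_finite(self, small_cohort):
        cfg = CMTConfig(max_epochs=1, seed=8)
        st = train_cmt(small_cohort.source, _partition_from_hidden(small_cohort), cfg)
        for col in ("l_gan", "l_dt", "l_mcc", "l_ide", "l_cmt"):
            assert np.isfinite(st.training_log[col]).all()


class TestSynthesize:
    def test_one_to_one_with_identity_provenance(self, small_cohort, rng):
        st = init_state(CMTConfig(seed=1))
        maj = small_cohort.source.images[small_cohort.source.labels == 0]
        pool = synthesize_minority(st, maj)
        assert len(pool) == len(maj)
        assert np.array_equal(pool.provenance, np.arange(len(maj)))
        # untrained generator is the identity
        assert np.array_equal(pool.samples, maj)

    def test_empty_input_gives_empty_pool(self):
        st = init_state(CMTConfig(seed=1))
        pool = synthesize_minority(st, np.empty((0, 16, 16), dtype=np.float32))
        assert len(pool) == 0

    def test_outputs_stay_in_range(self, small_cohort):
        cfg = CMTConfig(max_epochs=1, seed=5)
        st = train_cmt(small_cohort.source, _partition_from_hidden(small_cohort), cfg)
        pool = synthesize_minority(st, small_cohort.source.images[:10])
        assert pool.samples.shape == (10,) + small_cohort.source.images.shape[1:]
        assert pool.samples.min() >= 0.0 and pool.samples.max() <= 1.0
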