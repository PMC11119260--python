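"""Selection, balanced-set assembly and final supervised training."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dttl import (BTLConfig, CDAConfig, SelectionConfig, assemble_balanced_target,
                  balanced_ce_loss, score_minority_prob, select_samples, train_btl)
from dttl.btl import ORIGIN_SYNTH, BalancedTargetSet
from dttl.cda import PartitionedTarget, init_state
from dttl.cmt import GeneratedPool
from dttl.data import MAJ, MIN


def _pool(n, size=8):
    rng = np.random.default_rng(n)
    return GeneratedPool(rng.random((n, size, size), dtype=np.float32),
                         np.arange(n, dtype=np.int64))


def _brute_force_select(scores, p_max, s, n_min, p_min=0.0):
    """Independent enumeration oracle: filter, sort, truncate."""
    eligible = [(sc, i) for i, sc in enumerate(scores) if p_min <= sc <= p_max]
    eligible.sort(key=lambda t: (-t[0], t[1]))
    k = int(np.floor(s * n_min))
    return [i for _, i in eligible[:k]]


class TestSelectSamples:
    def test_worked_example(self):
        scores = np.array([0.99, 0.8, 0.7, 0.6, 0.3])
        sel = select_samples(_pool(5), scores, SelectionConfig(p_max=0.9, s=1.0),
                             n_min=2)
        assert sel.tolist() == [1, 2]  # the 0.8 and 0.7 entries

    def test_all_above_threshold(self):
        sel = select_samples(_pool(3), np.array([0.99, 0.98, 0.97]),
                             SelectionConfig(p_max=0.9, s=1.0), n_min=5)
        assert sel.size == 0

    def test_capped_at_availability(self):
        sel = select_samples(_pool(4), np.array([0.5, 0.99, 0.4, 0.3]),
                             SelectionConfig(p_max=0.9, p_min=0.0, s=1.0),
                             n_min=5)
        assert sorted(sel.tolist()) == [0, 2, 3]

    def test_negative_n_min_rejected(self):
        with pytest.raises(ValueError):
            select_samples(_pool(2), np.array([0.1, 0.2]), SelectionConfig(), -1)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=1000, deadline=None)
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 21))
        scores = np.round(rng.random(n), 3)  # coarse grid exercises ties
        p_max = float(rng.uniform(0.05, 1.0))
        p_min = float(rng.choice([0.0, rng.uniform(0.0, p_max / 2)]))
        s = float(rng.uniform(0.1, 3.0))
        n_min = int(rng.integers(0, 15))
        cfg = SelectionConfig(p_max=p_max, p_min=p_min, s=s)
        sel = select_samples(_pool(n), scores, cfg, n_min=n_min)
        assert sel.tolist() == _brute_force_select(scores, p_max, s, n_min, p_min)

    def test_confidence_floor_excludes_majority_like_candidates(self):
        """Candidates the classifier argmax-labels majority are dropped
        even when the retention quota is unfilled."""
        scores = np.array([0.9, 0.5, 0.01, 0.002])
        sel = select_samples(_pool(4), scores,
                             SelectionConfig(p_max=0.95, p_min=0.5, s=2.0),
                             n_min=3)
        assert sel.tolist() == [0, 1]
        # floor disabled reproduces the pure upper-threshold rule
        sel0 = select_samples(_pool(4), scores,
                              SelectionConfig(p_max=0.95, p_min=0.0, s=2.0),
                              n_min=3)
        assert sel0.tolist() == [0, 1, 2, 3]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None)
    def test_selected_scores_dominate(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(int(rng.integers(1, 21)))
        p_max = float(rng.uniform(0.1, 1.0))
        cfg = SelectionConfig(p_max=p_max,
                              p_min=float(rng.uniform(0.0, p_max)),
                              s=float(rng.uniform(0.1, 2.0)))
        n_min = int(rng.integers(0, 10))
        sel = select_samples(_pool(len(scores)), scores, cfg, n_min)
        chosen = set(sel.tolist())
        assert all(cfg.p_min <= scores[i] <= cfg.p_max for i in chosen)
        unchosen = [scores[i] for i in range(len(scores))
                    if i not in chosen and cfg.p_min <= scores[i] <= cfg.p_max]
        if chosen and unchosen:
            assert min(scores[i] for i in chosen) >= max(unchosen) - 1e-12


class TestAssemble:
    def _part(self, n_maj, n_min, size=8):
        imgs = np.random.default_rng(0).random((n_maj + n_min, size, size),
                                               dtype=np.float32)
        labels = np.array([MAJ] * n_maj + [MIN] * n_min)
        return PartitionedTarget(imgs, labels)

    def test_balancing_counts(self):
        part = self._part(100, 20)
        pool = _pool(200)
        sel = np.arange(80)
        t_prime = assemble_balanced_target(part, pool, sel)
        assert t_prime.counts() == {"maj": 100, "min": 100}

    def test_empty_selection_preserves_partition_counts(self):
        part = self._part(30, 10)
        t_prime = assemble_balanced_target(part, _pool(5), np.array([], dtype=int))
        assert t_prime.counts() == {"maj": 30, "min": 10}

    def test_synthetic_samples_carry_minority_label(self):
        part = self._part(10, 5)
        t_prime = assemble_balanced_target(part, _pool(8), np.array([1, 3]))
        synth = t_prime.origin == ORIGIN_SYNTH
        assert synth.sum() == 2
        assert (t_prime.labels[synth] == MIN).all()

    def test_minority_bound(self):
        """Minority count in T' is |X_min^t| + |selected| and cannot
        exceed |X_min^t| + floor(s*|X_min^t|)."""
        part = self._part(50, 12)
        pool = _pool(100)
        cfg = SelectionConfig(p_max=1.0, s=1.5)
        scores = np.random.default_rng(1).random(100)
        sel = select_samples(pool, scores, cfg, n_min=12)
        t_prime = assemble_balanced_target(part, pool, sel)
        assert t_prime.counts()["min"] == 12 + len(sel)
        assert t_prime.counts()["min"] <= 12 + int(np.floor(cfg.s * 12))


class TestBalancedCELoss:
    def test_perfect_predictions(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert balanced_ce_loss(p, [MAJ, MIN]) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_predictions(self):
        p = np.full((4, 2), 0.5)
        assert balanced_ce_loss(p, [MAJ, MIN, MAJ, MIN]) == \
            pytest.approx(np.log(2), abs=1e-9)

    def test_mixed_confidence(self):
        p = np.array([[0.5, 0.5], [0.0, 1.0]])
        assert balanced_ce_loss(p, [MAJ, MIN]) == pytest.approx(0.3466, abs=2e-4)


class TestScoreMinorityProb:
    def test_scores_are_probabilities_and_batch_consistent(self, small_cohort):
        state = init_state(CDAConfig(seed=0))
        pool = GeneratedPool(small_cohort.target_images[:6],
                             np.arange(6, dtype=np.int64))
        scores = score_minority_prob(state, pool)
        assert scores.shape == (6,)
        assert np.all((scores >= 0) & (scores <= 1))
        # one-at-a-time evaluation agrees with the batch
        singles = [score_minority_prob(
            state, GeneratedPool(pool.samples[i:i + 1], np.zeros(1, np.int64)))[0]
            for i in range(6)]
        assert np.allclose(scores, singles, atol=1e-6)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            score_minority_prob(init_state(CDAConfig()), _pool(0))


class TestTrainBTL:
    def _t_prime(self, cohort):
        n = len(cohort.target_images)
        return BalancedTargetSet(cohort.target_images,
                                 cohort.target_hidden_labels.copy(),
                                 np.full(n, "target-pseudo-maj", dtype=object))

    def test_zero_epochs_leaves_model_unchanged(self, small_cohort):
        state = init_state(CDAConfig(seed=0))
        before = state.F.params()[0].value.copy()
        train_btl(state, self._t_prime(small_cohort), BTLConfig(max_epochs=0))
        assert np.array_equal(state.F.params()[0].value, before)

    def test_single_class_rejected(self, small_cohort):
        state = init_state(CDAConfig(seed=0))
        t = self._t_prime(small_cohort)
        t.labels[:] = MAJ
        with pytest.raises(ValueError):
            train_btl(state, t, BTLConfig(max_epochs=1))

    def test_loss_descends_on_fixed_set(self, small_cohort):
        """Epoch-mean entropy loss is non-increasing early in training
        at a small learning rate."""
        state = init_state(CDAConfig(seed=0))
        cfg = BTLConfig(max_epochs=5, learning_rate=1e-4, seed=1)
        state = train_btl(state, self._t_prime(small_cohort), cfg)
        losses = state.training_log["l_ent"].to_numpy()
        assert np.all(np.diff(losses) <= 1e-6)
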