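import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import uqtriage as uq
from uqtriage.exceptions import DegenerateGroupError, DomainError


def pair_counting_auc(scores, labels):
    """Exhaustive all-pairs oracle: P(pos > neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


small_instances = st.lists(
    st.tuples(st.floats(0, 1, allow_nan=False, width=32), st.integers(0, 1)),
    min_size=2,
    max_size=12,
).filter(lambda rows: 0 < sum(y for _, y in rows) < len(rows))


class TestAuc:
    def test_fixed_example(self):
        assert uq.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert uq.auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert uq.auc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateGroupError):
            uq.auc([0.1, 0.2], [1, 1])

    @given(small_instances)
    @settings(derandomize=True, max_examples=150)
    def test_equals_exhaustive_pair_counting(self, rows):
        scores = [s for s, _ in rows]
        labels = [y for _, y in rows]
        assert uq.auc(scores, labels) == pytest.approx(
            pair_counting_auc(scores, labels), abs=1e-12
        )

    @given(small_instances)
    @settings(derandomize=True, max_examples=60)
    def test_monotone_transform_invariance_and_label_flip(self, rows):
        scores = np.array([s for s, _ in rows])
        labels = np.array([y for _, y in rows])
        value = uq.auc(scores, labels)
        # power-of-two scaling is exact, hence strictly monotone on floats
        assert uq.auc(4.0 * scores, labels) == pytest.approx(value, abs=1e-12)
        assert uq.auc(scores, 1 - labels) == pytest.approx(1.0 - value, abs=1e-12)

    def test_cross_check_against_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 300)
        labels[:2] = [0, 1]
        scores = rng.normal(0, 1, 300) + labels
        assert uq.auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestBootstrapCi:
    def test_deterministic_given_seed(self, dev_scores):
        r = dev_scores["ensemble_risk"].to_numpy()
        y = dev_scores["label"].to_numpy()
        a = uq.bootstrap_auc_ci(r, y, reps=200, seed=3)
        b = uq.bootstrap_auc_ci(r, y, reps=200, seed=3)
        assert a == b

    def test_perfect_separation_collapses_interval(self):
        scores = np.concatenate([np.linspace(0, 0.4, 200), np.linspace(0.6, 1.0, 200)])
        labels = np.concatenate([np.zeros(200, int), np.ones(200, int)])
        low, high = uq.bootstrap_auc_ci(scores, labels, reps=200, seed=0)
        assert low == high == 1.0

    def test_invalid_reps(self):
        with pytest.raises(DomainError):
            uq.bootstrap_auc_ci([0.1, 0.9], [0, 1], reps=0)

    def test_interval_width_at_screening_scale(self):
        # Interval width over screening-scale cohorts (n=883, ~65
        # malignant, full AUC ~0.93) should be a few hundredths.
        widths = []
        for k in range(20):
            scores = uq.score_records(
                uq.generate_cohort(uq.development_config(seed=300 + k))
            )
            low, high = uq.bootstrap_auc_ci(
                scores["ensemble_risk"].to_numpy(),
                scores["label"].to_numpy(),
                reps=1000,
                seed=k,
            )
            widths.append(high - low)
        assert 0.03 <= np.mean(widths) <= 0.09


class TestSensitivityAtSpecificity:
    def test_perfect_separation(self):
        assert (
            uq.sensitivity_at_specificity([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        )

    def test_constant_scores(self):
        assert uq.sensitivity_at_specificity([0.4] * 10, [0] * 5 + [1] * 5) == 0.0

    def test_brute_force_sweep_oracle(self):
        benign = np.round(np.arange(0.01, 0.201, 0.01), 2)
        malignant = np.array([0.15, 0.18, 0.25, 0.3, 0.9])
        scores = np.concatenate([benign, malignant])
        labels = np.concatenate([np.zeros(20, int), np.ones(5, int)])
        best = 0.0
        for t in np.concatenate(([-np.inf], np.unique(scores), [np.inf])):
            if np.mean(benign <= t) >= 0.95:
                best = max(best, float(np.mean(malignant > t)))
        assert uq.sensitivity_at_specificity(scores, labels) == pytest.approx(best)

    def test_non_increasing_in_target(self, dev_scores):
        r = dev_scores["ensemble_risk"].to_numpy()
        y = dev_scores["label"].to_numpy()
        values = [
            uq.sensitivity_at_specificity(r, y, target_spec=t)
            for t in (0.5, 0.8, 0.9, 0.95, 0.99)
        ]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestDelong:
    def test_perfect_separation_has_zero_variance(self):
        assert uq.delong_variance([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 0.0

    def test_hand_enumerated_structural_components(self):
        # pos {0.8, 0.6, 0.3} vs neg {0.1, 0.4, 0.7}:
        # V10 = (1, 2/3, 1/3), V01 = (1, 2/3, 1/3), AUC = 2/3,
        # var = var(V10)/3 + var(V01)/3 = (1/9)/3 + (1/9)/3 = 2/27.
        scores = [0.8, 0.6, 0.3, 0.1, 0.4, 0.7]
        labels = [1, 1, 1, 0, 0, 0]
        assert uq.auc(scores, labels) == pytest.approx(2 / 3)
        assert uq.delong_variance(scores, labels) == pytest.approx(2 / 27, abs=1e-12)

    def test_requires_two_per_class(self):
        with pytest.raises(DomainError):
            uq.delong_variance([0.1, 0.5, 0.9], [0, 1, 1])

    def test_matches_bootstrap_variance_at_large_n(self):
        scores = uq.score_records(
            uq.generate_cohort(uq.development_config(n_nodules=2000, seed=21))
        )
        r = scores["ensemble_risk"].to_numpy()
        y = scores["label"].to_numpy()
        vd = uq.delong_variance(r, y)
        rng = np.random.default_rng(99)
        values = []
        for _ in range(2000):
            while True:
                idx = rng.integers(0, len(r), len(r))
                if 0 < y[idx].sum() < len(r):
                    break
            values.append(uq.auc(r[idx], y[idx]))
        vb = float(np.var(values, ddof=1))
        assert abs(vd - vb) / vb < 0.15

    def test_variance_shrinks_with_sample_size(self):
        small = uq.score_records(
            uq.generate_cohort(uq.development_config(n_nodules=400, seed=8))
        )
        large = uq.score_records(
            uq.generate_cohort(uq.development_config(n_nodules=3200, seed=8))
        )
        v_small = uq.delong_variance(
            small["ensemble_risk"].to_numpy(), small["label"].to_numpy()
        )
        v_large = uq.delong_variance(
            large["ensemble_risk"].to_numpy(), large["label"].to_numpy()
        )
        assert v_large < v_small


class TestCompareAuc:
    def test_identical_groups_give_null_result(self, dev_scores):
        r = dev_scores["ensemble_risk"].to_numpy()
        y = dev_scores["label"].to_numpy()
        result = uq.compare_auc(r, y, r, y)
        assert result.z_statistic == 0.0
        assert result.p_value == 1.0

    def test_overlapping_comparison_is_flagged(self, dev_scores):
        r = dev_scores["ensemble_risk"].to_numpy()
        y = dev_scores["label"].to_numpy()
        result = uq.compare_auc(r, y, r[:500], y[:500], overlapping=True)
        assert result.overlapping is True
        assert result.paired is False

    def test_degenerate_group_propagates(self):
        with pytest.raises(DegenerateGroupError):
            uq.compare_auc([0.1, 0.9], [0, 1], [0.2, 0.3], [0, 0])
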