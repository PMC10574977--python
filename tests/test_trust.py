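import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trustauc import (
    TrustParams,
    TrustScorer,
    normalize_confidence,
    positive_trust_score,
    qa_trust,
    select_threshold,
)
from trustauc.trust import make_prediction_records


def _brute_force_threshold(scores, labels):
    """Exhaustive candidate search; returns (best_t, best_f1)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    uniq = np.unique(s)
    cands = [0.5 * uniq[0]] + list((uniq[:-1] + uniq[1:]) / 2) + [0.5 * (1 + uniq[-1])]
    best_t, best_f1 = None, -1.0
    for t in sorted(cands):
        pred = s >= t
        tp = np.sum(pred & (y == 1))
        fp = np.sum(pred & (y == 0))
        fn = np.sum(~pred & (y == 1))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1:
            best_t, best_f1 = t, f1
    return best_t, best_f1


def _f1_at(scores, labels, t):
    pred = np.asarray(scores) >= t
    y = np.asarray(labels)
    tp = np.sum(pred & (y == 1))
    fp = np.sum(pred & (y == 0))
    fn = np.sum(~pred & (y == 1))
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


class TestSelectThreshold:
    def test_separable_example(self):
        t = select_threshold([0.1, 0.2, 0.6, 0.9], [0, 0, 1, 1])
        assert t == pytest.approx(0.4)
        assert _f1_at([0.1, 0.2, 0.6, 0.9], [0, 0, 1, 1], t) == 1.0

    def test_inverted_scorer_still_maximizes(self):
        scores, labels = [0.9, 0.1], [0, 1]
        t = select_threshold(scores, labels)
        _, best = _brute_force_threshold(scores, labels)
        assert best < 1.0
        assert _f1_at(scores, labels, t) == pytest.approx(best)

    def test_separable_reaches_perfect_f1(self, rng):
        s = np.concatenate([rng.uniform(0.6, 0.95, 7), rng.uniform(0.05, 0.4, 13)])
        y = np.array([1] * 7 + [0] * 13)
        assert _f1_at(s, y, select_threshold(s, y)) == 1.0

    @pytest.mark.parametrize("trial", range(200))
    def test_matches_exhaustive_search(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 51))
        s = rng.uniform(0.01, 0.99, size=n)
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if y.all():
            y[0] = 0
        t = select_threshold(s, y)
        bt, bf1 = _brute_force_threshold(s, y)
        assert _f1_at(s, y, t) == pytest.approx(bf1, abs=1e-12)
        assert t == pytest.approx(bt)  # smallest maximiser wins ties

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([0.2, 0.8], [1, 1])


class TestNormalizeConfidence:
    def test_threshold_maps_to_half(self):
        for t in (0.1, 0.3, 0.5, 0.9):
            assert normalize_confidence(t, t) == pytest.approx(0.5)

    def test_endpoints_anchor_at_zero_and_one(self):
        assert normalize_confidence(0.0, 0.3) == 0.0
        assert normalize_confidence(1.0, 0.3) == 1.0

    def test_worked_example(self):
        assert normalize_confidence(0.15, 0.3) == pytest.approx(0.25)

    def test_strictly_increasing_on_dense_grid(self):
        s = np.linspace(0.0, 1.0, 10_000)
        p = normalize_confidence(s, 0.37)
        assert np.all(np.diff(p) > 0)
        assert p.min() >= 0.0 and p.max() <= 1.0

    @pytest.mark.parametrize("t", [0.0, 1.0, -0.2, 1.3])
    def test_invalid_threshold_rejected(self, t):
        with pytest.raises(ValueError):
            normalize_confidence(0.5, t)


class TestQATrust:
    def test_deserved_full_confidence(self):
        assert qa_trust(1.0, True, 1, 1) == 1.0

    def test_undeserved_full_confidence(self):
        assert qa_trust(1.0, False, 1, 1) == 0.0

    def test_power_coefficients(self):
        assert qa_trust(0.9, True, alpha=2, beta=1) == pytest.approx(0.81)

    def test_degenerate_coefficients_give_unit_trust(self, rng):
        C = rng.uniform(size=50)
        correct = rng.integers(0, 2, size=50).astype(bool)
        assert np.all(qa_trust(C, correct, alpha=0, beta=0) == 1.0)

    @given(
        alpha=st.floats(0, 5),
        beta=st.floats(0, 5),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_monotonicity_in_confidence(self, alpha, beta):
        C = np.linspace(0, 1, 101)
        q_correct = qa_trust(C, np.ones(101, dtype=bool), alpha, beta)
        q_wrong = qa_trust(C, np.zeros(101, dtype=bool), alpha, beta)
        assert np.all(np.diff(q_correct) >= -1e-12)
        assert np.all(np.diff(q_wrong) <= 1e-12)
        assert q_correct.min() >= 0 and q_correct.max() <= 1
        assert q_wrong.min() >= 0 and q_wrong.max() <= 1

    def test_out_of_range_confidence_rejected(self):
        with pytest.raises(ValueError):
            qa_trust(1.2, True, 1, 1)


class TestPositiveTrustScore:
    def _records(self, scores, labels, t=0.5):
        params = TrustParams(threshold=t)
        ids = [str(i) for i in range(len(scores))]
        return make_prediction_records(ids, scores, labels, params), params

    def test_confident_correct_model_has_unit_trust(self):
        recs, params = self._records([0.999999, 0.999999, 0.2], [1, 1, 0])
        # force exact unit confidence for the two positives
        import dataclasses as dc

        recs = [
            dc.replace(r, confidence=1.0) if r.true_label == 1 else r for r in recs
        ]
        report = positive_trust_score(recs, params)
        assert report.positive_trust == 1.0
        assert report.n_positive == 2

    def test_confidently_wrong_model_has_zero_trust(self):
        import dataclasses as dc

        recs, params = self._records([0.0001, 0.0001, 0.2], [1, 1, 0])
        recs = [
            dc.replace(r, confidence=1.0) if r.true_label == 1 else r for r in recs
        ]
        report = positive_trust_score(recs, params)
        assert report.positive_trust == 0.0

    def test_vectorized_equals_scalar_loop(self, rng):
        n = 1000
        s = rng.uniform(0.001, 0.999, size=n)
        z = rng.integers(0, 2, size=n)
        z[0] = 1
        params = TrustParams(alpha=1.3, beta=0.7, threshold=0.42)
        recs = make_prediction_records([str(i) for i in range(n)], s, z, params)
        report = positive_trust_score(recs, params)
        total, count = 0.0, 0
        for r in recs:
            if r.true_label != 1:
                continue
            q = (
                r.confidence**params.alpha
                if r.predicted_label == r.true_label
                else (1 - r.confidence) ** params.beta
            )
            total += q
            count += 1
        assert report.positive_trust == pytest.approx(total / count, abs=1e-12)
        assert report.n_positive == count

    def test_no_true_positives_rejected(self):
        recs, params = self._records([0.3, 0.4], [0, 0])
        with pytest.raises(ValueError, match="positive"):
            positive_trust_score(recs, params)

    def test_trust_bounded_in_unit_interval(self, rng):
        s = rng.uniform(0.001, 0.999, size=200)
        z = rng.integers(0, 2, size=200)
        z[:5] = 1
        recs, params = self._records(s, z, t=0.3)
        report = positive_trust_score(recs, params)
        assert 0.0 <= report.positive_trust <= 1.0
        assert all(0.0 <= q <= 1.0 for _, q in report.per_sample_Q)


class TestTrustScorer:
    def test_end_to_end_calibration_sensitivity(self):
        """Equal accuracy, different confidence placement: the model whose
        correct answers sit far from the threshold earns more trust."""
        y_val = np.array([0] * 10 + [1] * 10)
        s_val = np.concatenate([np.linspace(0.05, 0.3, 10), np.linspace(0.7, 0.95, 10)])
        y_test = np.array([0] * 6 + [1] * 6)
        confident = np.array([0.02] * 6 + [0.98] * 6)
        hesitant_t = TrustScorer().fit(s_val, y_val).threshold_
        hesitant = np.array([hesitant_t - 0.02] * 6 + [hesitant_t + 0.02] * 6)

        scorer = TrustScorer().fit(s_val, y_val)
        ids = [str(i) for i in range(12)]
        trust_confident = scorer.report(ids, confident, y_test).positive_trust
        trust_hesitant = scorer.report(ids, hesitant, y_test).positive_trust
        # identical accuracy (both perfect at threshold) but different trust
        assert trust_confident > trust_hesitant

    def test_report_artifacts(self, tmp_path, rng):
        s_val = np.array([0.2, 0.3, 0.7, 0.8])
        y_val = np.array([0, 0, 1, 1])
        scorer = TrustScorer().fit(s_val, y_val)
        report = scorer.report(["a", "b"], np.array([0.9, 0.1]), np.array([1, 0]))
        j = report.to_json(tmp_path / "trust.json")
        c = report.per_sample_csv(tmp_path / "q.csv")
        assert j.exists() and c.exists()
        import json

        payload = json.loads(j.read_text())
        assert 0 <= payload["positive_trust"] <= 1
        assert payload["n_positive"] == 1
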