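"""ROC analysis: AUC equivalences, Youden cutoff, bands, interval methods."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fallrisk import (
    auc_band,
    auc_ci,
    auc_mann_whitney,
    confusion_at,
    roc_curve,
    youden_cutoff,
)


def brute_force_auc(scores, labels):
    """Pairwise oracle: P(pos > neg) + half ties, over all pairs."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def exhaustive_youden(scores, labels):
    """Scan every candidate threshold for max J; ties -> lowest threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best = (-np.inf, None)
    for t in np.concatenate([[-np.inf], np.unique(scores), [np.inf]]):
        j = (pos >= t).mean() + (neg < t).mean() - 1.0
        if j > best[0] + 1e-15:
            best = (j, t)
    return best[1], best[0]


class TestAUC:
    def test_perfect_separation(self):
        res = roc_curve([1, 2, 3, 4], [0, 0, 1, 1], ci=False)
        assert res.auc == pytest.approx(1.0)
        cutoff, sens, spec = youden_cutoff(res)
        assert (cutoff, sens, spec) == (3.0, 1.0, 1.0)

    def test_all_tied_scores_chance(self):
        res = roc_curve([5.0] * 8, [0, 1, 0, 1, 0, 1, 0, 0], ci=False)
        assert res.auc == pytest.approx(0.5)
        assert res.youden_index == pytest.approx(0.0)
        assert res.youden_cutoff == -np.inf  # lowest-threshold tie policy

    def test_four_point_pairwise_value(self):
        assert auc_mann_whitney([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) \
            == pytest.approx(0.75)

    def test_label_swap_complement(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        a = auc_mann_whitney(scores, labels)
        b = auc_mann_whitney(scores, 1 - labels)
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2, 3], [1, 1, 1])

    @given(st.integers(0, 10**6))
    @settings(max_examples=60, deadline=None)
    def test_trapezoid_equals_mann_whitney(self, seed):
        """The probabilistic AUC interpretation holds on every instance."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = roc_curve(scores, labels, ci=False)
        assert res.auc == pytest.approx(auc_mann_whitney(scores, labels),
                                        abs=1e-12)
        assert res.auc == pytest.approx(brute_force_auc(scores, labels),
                                        abs=1e-12)

    def test_roc_monotonicity(self, rng):
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        res = roc_curve(scores, labels, ci=False)
        assert (np.diff(res.sensitivity) <= 1e-12).all()
        assert (np.diff(res.specificity) >= -1e-12).all()


class TestYouden:
    def test_two_gaussian_instance_matches_exhaustive_scan(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 120), rng.normal(1.3, 1, 80)])
        labels = np.concatenate([np.zeros(120, int), np.ones(80, int)])
        res = roc_curve(scores, labels, ci=False)
        t_oracle, j_oracle = exhaustive_youden(scores, labels)
        assert res.youden_cutoff == pytest.approx(t_oracle)
        assert res.youden_index == pytest.approx(j_oracle)

    @given(st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        """exp() maps the chosen threshold; J is unchanged."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        scores = np.round(rng.normal(size=n), 1)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a = roc_curve(scores, labels, ci=False)
        b = roc_curve(np.exp(scores), labels, ci=False)
        assert b.youden_index == pytest.approx(a.youden_index, abs=1e-12)
        if math.isfinite(a.youden_cutoff):
            assert b.youden_cutoff == pytest.approx(np.exp(a.youden_cutoff))


class TestBand:
    @pytest.mark.parametrize("auc,band", [
        (0.790, "moderately_accurate"),
        (0.5, "noninformative"),
        (0.65, "less_accurate"),
        (0.7, "less_accurate"),
        (0.9, "moderately_accurate"),
        (0.95, "highly_accurate"),
        (1.0, "perfect"),
        (0.3, "noninformative"),
    ])
    def test_partition(self, auc, band):
        assert auc_band(auc) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            auc_band(1.2)


class TestAucCI:
    def test_tight_near_one_for_perfect_separation(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 100), rng.normal(8, 1, 100)])
        labels = np.repeat([0, 1], 100)
        low, high = auc_ci(scores, labels)
        assert low > 0.95
        assert high <= 1.0

    def test_chance_scores_cover_half(self, rng):
        scores = rng.normal(size=500)
        labels = rng.integers(0, 2, 500)
        labels[:2] = [0, 1]
        low, high = auc_ci(scores, labels)
        assert low < 0.5 < high

    def test_bounds_clipped_to_unit_interval(self):
        low, high = auc_ci([1, 2, 3, 4], [0, 0, 1, 1])
        assert 0.0 <= low <= high <= 1.0

    def test_bootstrap_method_agrees_roughly(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 150), rng.normal(1, 1, 80)])
        labels = np.concatenate([np.zeros(150, int), np.ones(80, int)])
        h = auc_ci(scores, labels, method="hanley")
        b = auc_ci(scores, labels, method="bootstrap", n_boot=500, seed=1)
        assert h[0] == pytest.approx(b[0], abs=0.05)
        assert h[1] == pytest.approx(b[1], abs=0.05)


def wilson_interval(successes, n, z=1.959963984540054):
    """Closed-form oracle for the Wilson score interval."""
    phat = successes / n
    denom = 1 + z ** 2 / n
    centre = (phat + z ** 2 / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z ** 2 / (4 * n ** 2)) / denom
    return centre - half, centre + half


class TestConfusion:
    def test_perfect_classifier(self):
        summary = confusion_at([1, 2, 3, 4], [0, 0, 1, 1], cutoff=3,
                               n_boot=50, seed=0)
        assert (summary.tp, summary.fp, summary.tn, summary.fn) == (2, 0, 2, 0)
        assert summary.sensitivity == summary.specificity == 1.0
        assert summary.ppv == summary.npv == 1.0

    def test_wilson_interval_matches_closed_form(self, rng):
        """148 recurrent fallers of whom 98 detected: the published scale."""
        scores = np.concatenate([rng.normal(0, 1, 356), rng.normal(1.4, 1, 148)])
        labels = np.concatenate([np.zeros(356, int), np.ones(148, int)])
        summary = confusion_at(scores, labels, cutoff=1.0, n_boot=10, seed=0)
        lo, hi = wilson_interval(summary.tp, summary.tp + summary.fn)
        assert summary.sensitivity_ci[0] == pytest.approx(lo, abs=1e-9)
        assert summary.sensitivity_ci[1] == pytest.approx(hi, abs=1e-9)
        lo, hi = wilson_interval(summary.tn, summary.tn + summary.fp)
        assert summary.specificity_ci[0] == pytest.approx(lo, abs=1e-9)
        assert summary.specificity_ci[1] == pytest.approx(hi, abs=1e-9)

    def test_single_resample_bootstrap_degenerate(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        summary = confusion_at(scores, labels, cutoff=0.0, n_boot=1, seed=3)
        assert summary.ppv_ci[0] == summary.ppv_ci[1]

    def test_one_sided_cutoff_warns_and_reports_nan(self):
        with pytest.warns(UserWarning):
            summary = confusion_at([1, 2, 3, 4], [0, 1, 0, 1], cutoff=10,
                                   n_boot=5, seed=0)
        assert math.isnan(summary.ppv)

    def test_ci_brackets_point_estimates(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 120), rng.normal(1, 1, 60)])
        labels = np.concatenate([np.zeros(120, int), np.ones(60, int)])
        s = confusion_at(scores, labels, cutoff=0.5, n_boot=400, seed=7)
        assert s.sensitivity_ci[0] <= s.sensitivity <= s.sensitivity_ci[1]
        assert s.specificity_ci[0] <= s.specificity <= s.specificity_ci[1]
        assert s.ppv_ci[0] <= s.ppv <= s.ppv_ci[1]
        assert s.npv_ci[0] <= s.npv <= s.npv_ci[1]
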