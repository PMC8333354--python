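"""ROC construction, AUC identities, Youden cutoffs, severity screening."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import roc_auc_score

from nirspain.screening import (
    ScreeningError,
    YoudenScreener,
    apply_cutoff,
    auc_ci,
    roc_curve,
    severity_screen,
    youden_cutoff,
)


def exhaustive_auc(scores, labels, orientation):
    """Independent oracle: AUC as the normalized count over all
    positive-negative pairs (ties worth one half)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        if p == q:
            total += 0.5
        elif (p < q) == (orientation == "low_positive"):
            total += 1.0
    return total / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([1, 2, 3, 4], [1, 1, 0, 0], orientation="low_positive")
        assert roc.auc == 1.0

    def test_worked_four_point_sets(self):
        roc = roc_curve([1, 2, 3, 4], [0, 0, 1, 1], orientation="high_positive")
        assert roc.auc == 1.0
        roc2 = roc_curve([1, 3, 2, 4], [0, 0, 1, 1],
                         orientation="high_positive")
        assert roc2.auc == pytest.approx(0.75)

    def test_random_labels_give_half_auc_on_average(self, rng):
        scores = rng.normal(0, 1, 30)
        labels = np.array([0] * 15 + [1] * 15)
        aucs = []
        for _ in range(2000):
            rng.shuffle(labels)
            aucs.append(roc_curve(scores, labels, "high_positive").auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.01)

    @given(
        data=st.lists(
            st.tuples(st.integers(-5, 5), st.booleans()),
            min_size=4,
            max_size=12,
        )
    )
    def test_auc_equals_mann_whitney_identity(self, data):
        scores = np.array([d[0] for d in data], dtype=float)
        labels = np.array([int(d[1]) for d in data])
        if labels.min() == labels.max():
            return  # one class only: construction precondition
        for orientation in ("low_positive", "high_positive"):
            roc = roc_curve(scores, labels, orientation)
            assert roc.auc == pytest.approx(
                exhaustive_auc(scores, labels, orientation), abs=1e-12
            )

    def test_orientation_flip_complements_auc(self, rng):
        scores = rng.normal(0, 1, 40)
        labels = (rng.uniform(size=40) < 0.4).astype(int)
        labels[:2] = [0, 1]
        a1 = roc_curve(scores, labels, "low_positive").auc
        a2 = roc_curve(scores, labels, "high_positive").auc
        assert a1 + a2 == pytest.approx(1.0)

    def test_monotone_transform_leaves_curve_unchanged(self, rng):
        scores = rng.normal(0, 1, 25)
        labels = (rng.uniform(size=25) < 0.5).astype(int)
        labels[:2] = [0, 1]
        r1 = roc_curve(scores, labels, "high_positive")
        r2 = roc_curve(np.exp(scores), labels, "high_positive")
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)
        assert np.allclose(
            r1.table[["sensitivity", "one_minus_specificity"]],
            r2.table[["sensitivity", "one_minus_specificity"]],
        )

    def test_agrees_with_sklearn(self, rng):
        scores = rng.normal(0, 1, 60)
        labels = (rng.uniform(size=60) < 0.5).astype(int)
        labels[:2] = [0, 1]
        ours = roc_curve(scores, labels, "high_positive").auc
        assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ScreeningError):
            roc_curve([1.0, 2.0], [1, 1])


class TestAucCi:
    def test_symmetric_about_half_for_null_auc(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 200), rng.normal(0, 1, 200)])
        labels = np.array([0] * 200 + [1] * 200)
        roc = roc_curve(scores, labels, "high_positive")
        lo, hi = auc_ci(roc)
        assert (lo + hi) / 2 == pytest.approx(roc.auc, abs=1e-9)

    def test_bootstrap_reproducible(self, rng):
        scores = rng.normal(0, 1, 30)
        labels = np.array([0] * 15 + [1] * 15)
        roc = roc_curve(scores, labels, "high_positive")
        ci1 = auc_ci(roc, method="bootstrap", seed=3, n_boot=500)
        ci2 = auc_ci(roc, method="bootstrap", seed=3, n_boot=500)
        assert ci1 == ci2

    def test_hanley_mcneil_width_shrinks_with_n(self, rng):
        widths = []
        for n in (10, 40, 160):
            pos = rng.normal(1.0, 1, n)
            neg = rng.normal(0.0, 1, n)
            roc = roc_curve(
                np.concatenate([pos, neg]),
                np.array([1] * n + [0] * n),
                "high_positive",
            )
            # fix the AUC so only n drives the width
            roc.auc = 0.75
            lo, hi = auc_ci(roc)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_degenerate_auc_is_clipped(self):
        roc = roc_curve([1, 2, 3, 4], [1, 1, 0, 0], "low_positive")
        lo, hi = auc_ci(roc)
        assert 0.0 <= lo <= hi <= 1.0


class TestYouden:
    def test_separable_data_picks_higher_sensitivity_tie(self):
        roc = roc_curve([1, 2, 3, 4], [0, 0, 1, 1], "high_positive")
        j = roc.table.sensitivity - roc.table.one_minus_specificity
        assert j.max() == pytest.approx(1.0)
        # attained-value convention: the separating attained score is 3
        assert youden_cutoff(roc) == 3.0

    def test_orientation_symmetric_separation(self, rng):
        # flipping labels and orientation together still separates perfectly;
        # the attained-value convention picks the adjacent order statistics
        # on either side of the true boundary
        scores = rng.normal(0, 1, 30)
        labels = (scores > 0.2).astype(int)
        roc_hi = roc_curve(scores, labels, "high_positive")
        roc_lo = roc_curve(scores, 1 - labels, "low_positive")
        c_hi = youden_cutoff(roc_hi)
        c_lo = youden_cutoff(roc_lo)
        j_hi = (roc_hi.table.sensitivity - roc_hi.table.one_minus_specificity).max()
        j_lo = (roc_lo.table.sensitivity - roc_lo.table.one_minus_specificity).max()
        assert j_hi == pytest.approx(1.0) and j_lo == pytest.approx(1.0)
        assert c_lo <= 0.2 < c_hi


class TestApplyCutoff:
    def test_extreme_cutoffs(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([1, 1, 0, 0])
        assert apply_cutoff(scores, labels, 0.0, "low_positive") == (0.0, 1.0)
        assert apply_cutoff(scores, labels, 9.0, "low_positive") == (1.0, 0.0)

    def test_separating_cutoff(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([1, 1, 0, 0])
        assert apply_cutoff(scores, labels, 2.5, "low_positive") == (1.0, 1.0)

    def test_nonfinite_cutoff_rejected(self):
        with pytest.raises(ScreeningError):
            apply_cutoff([1.0, 2.0], [0, 1], math.nan)


class TestSeverityScreen:
    def test_perfectly_monotone_severity(self):
        feature = np.arange(22, dtype=float)
        severity = feature * 3 + 1
        out = severity_screen(feature, severity)
        assert out["roc"].auc == 1.0

    def test_independent_severity_near_half_over_seeds(self):
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(300):
            feature = rng.normal(0, 1, 22)
            severity = rng.normal(50, 10, 22)
            aucs.append(severity_screen(feature, severity)["roc"].auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_degenerate_split_rejected(self):
        with pytest.raises(ScreeningError):
            severity_screen(np.arange(10.0), np.full(10, 5.0))

    def test_fixed_cutoff_rates_reported(self):
        feature = np.linspace(-0.4, 0.1, 22)
        severity = feature + 1.0
        out = severity_screen(feature, severity, fixed_cutoffs=(-0.175,))
        sens, spec = out["fixed_cutoffs"][-0.175]
        assert 0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0


class TestYoudenScreener:
    def test_fit_predict_roundtrip(self, rng):
        scores = np.concatenate([rng.normal(-0.3, 0.1, 25),
                                 rng.normal(0.3, 0.1, 25)])
        y = np.array([1] * 25 + [0] * 25)  # low scores positive
        clf = YoudenScreener(orientation="low_positive").fit(scores, y)
        assert clf.auc_ > 0.95
        pred = clf.predict(scores)
        assert (pred == y).mean() > 0.95

    def test_sklearn_protocol(self):
        from sklearn.base import clone

        clf = YoudenScreener(orientation="high_positive")
        params = clf.get_params()
        assert params["orientation"] == "high_positive"
        clone(clf)  # must be cloneable for model selection
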