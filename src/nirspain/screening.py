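"""ROC machinery for the dHbO* biomarker screens.

Two screens are implemented: discriminating fibromyalgia from controls by
the PFC dHbO* feature, and -- within fibromyalgia -- discriminating subjects
with above-median severity at fixed published-style cutoffs.

Conventions
-----------
* Orientation ``low_positive`` classifies a score as positive when
  score <= cutoff (fibromyalgia shows *lower* dHbO*, reconciling negative
  cutoffs with positive group means); ``high_positive`` uses
  score >= cutoff.
* Cutoffs are reported at attained score values, one row per distinct
  score plus a degenerate all-positive threshold.
* AUC is the trapezoidal area, identical to the normalized Mann-Whitney U
  statistic (ties count 1/2).
* The default AUC confidence interval is Hanley-McNeil; a seeded bootstrap
  percentile interval is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "ScreeningError",
    "RocResult",
    "roc_curve",
    "auc_ci",
    "youden_cutoff",
    "apply_cutoff",
    "severity_screen",
    "YoudenScreener",
]

ORIENTATIONS = ("low_positive", "high_positive")


class ScreeningError(ValueError):
    pass


@dataclass
class RocResult:
    """Empirical ROC: cutoff table, AUC, CI and the Youden-optimal cutoff."""

    table: pd.DataFrame  # columns: cutoff, sensitivity, one_minus_specificity
    auc: float
    orientation: str
    n_positive: int
    n_negative: int
    ci: tuple[float, float] | None = None
    ci_method: str | None = None
    scores: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    labels: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)

    @property
    def youden(self) -> pd.Series:
        """Row of the cutoff table maximizing J = sens + spec - 1."""
        j = self.table["sensitivity"] - self.table["one_minus_specificity"]
        best = j.max()
        cand = self.table[np.isclose(j, best)]
        cand = cand.sort_values(
            ["sensitivity", "abs_cutoff"], ascending=[False, True]
        )
        return cand.iloc[0]


def _validate(scores, labels, orientation):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ScreeningError("scores and labels must be matching 1-d arrays")
    if orientation not in ORIENTATIONS:
        raise ScreeningError(f"orientation must be one of {ORIENTATIONS}")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ScreeningError("both classes must be present")
    return scores, labels, n_pos, n_neg


def _auc_mann_whitney(scores, labels, orientation) -> float:
    """AUC as the normalized U statistic: P(positive beyond negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if orientation == "low_positive":
        wins = (pos[:, None] < neg[None, :]).sum()
    else:
        wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (len(pos) * len(neg)))


def roc_curve(scores, labels, orientation: str = "low_positive") -> RocResult:
    """Empirical ROC over all attained score thresholds.

    For ``low_positive`` a subject is called positive when
    score <= cutoff, so sensitivity rises with the cutoff; for
    ``high_positive`` the rule is score >= cutoff.
    """
    scores, labels, n_pos, n_neg = _validate(scores, labels, orientation)
    cutoffs = np.unique(scores)
    if orientation == "high_positive":
        cutoffs = cutoffs[::-1]
    rows = []
    for c in cutoffs:
        called = scores <= c if orientation == "low_positive" else scores >= c
        sens = (called & (labels == 1)).sum() / n_pos
        fpr = (called & (labels == 0)).sum() / n_neg
        rows.append(
            {"cutoff": float(c), "sensitivity": sens,
             "one_minus_specificity": fpr, "abs_cutoff": abs(float(c))}
        )
    table = pd.DataFrame(rows)
    # trapezoid over the full curve including the (0,0) endpoint
    fpr = np.concatenate([[0.0], table["one_minus_specificity"].to_numpy(), [1.0]])
    tpr = np.concatenate([[0.0], table["sensitivity"].to_numpy(), [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        table=table, auc=auc, orientation=orientation,
        n_positive=n_pos, n_negative=n_neg,
        scores=scores, labels=labels,
    )


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def auc_ci(
    roc: RocResult,
    method: str = "hanley-mcneil",
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """95 % (by default) confidence interval for the AUC, clipped to [0, 1].

    ``hanley-mcneil`` uses the closed-form binormal-motivated SE;
    ``bootstrap`` is a seeded stratified percentile bootstrap.
    """
    z = sps.norm.isf((1.0 - level) / 2.0)
    if roc.auc in (0.0, 1.0) and min(roc.n_positive, roc.n_negative) < 10:
        warnings.warn(
            "degenerate AUC with few subjects; the clipped interval is "
            "unreliable",
            stacklevel=2,
        )
    if method == "hanley-mcneil":
        se = _hanley_mcneil_se(roc.auc, roc.n_positive, roc.n_negative)
        lo, hi = roc.auc - z * se, roc.auc + z * se
    elif method == "bootstrap":
        if roc.scores.size == 0:
            raise ScreeningError("RocResult carries no data for the bootstrap")
        rng = np.random.default_rng(seed)
        pos = roc.scores[roc.labels == 1]
        neg = roc.scores[roc.labels == 0]
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            ps = rng.choice(pos, size=len(pos), replace=True)
            ns = rng.choice(neg, size=len(neg), replace=True)
            s = np.concatenate([ps, ns])
            l = np.concatenate([np.ones(len(ps), int), np.zeros(len(ns), int)])
            aucs[b] = _auc_mann_whitney(s, l, roc.orientation)
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(aucs, [a, 1.0 - a])
    else:
        raise ScreeningError(f"unknown CI method {method!r}")
    roc.ci = (float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))
    roc.ci_method = method
    return roc.ci


def youden_cutoff(roc: RocResult) -> float:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Ties break toward higher sensitivity, then smaller absolute cutoff.
    """
    if len(roc.table) == 0:
        raise ScreeningError("empty cutoff table")
    return float(roc.youden["cutoff"])


def apply_cutoff(
    scores, labels, cutoff: float, orientation: str = "low_positive"
) -> tuple[float, float]:
    """Empirical (sensitivity, specificity) of a fixed cutoff."""
    if not np.isfinite(cutoff):
        raise ScreeningError("cutoff must be finite")
    scores, labels, n_pos, n_neg = _validate(scores, labels, orientation)
    called = scores <= cutoff if orientation == "low_positive" else scores >= cutoff
    sens = float((called & (labels == 1)).sum() / n_pos)
    spec = float((~called & (labels == 0)).sum() / n_neg)
    return sens, spec


def severity_screen(
    feature: np.ndarray,
    severity: np.ndarray,
    fixed_cutoffs: tuple[float, ...] = (-0.175,),
    quantile: float = 0.5,
    orientation: str = "high_positive",
    ci_method: str = "hanley-mcneil",
) -> dict:
    """Within-patient severity screen of a dHbO* feature.

    ``severity`` is dichotomized at its ``quantile`` (median split by
    default -- a package convention, flagged in the output); the feature is
    then evaluated as a classifier of the high-severity label.  The default
    orientation is ``high_positive`` because the reference rank correlation
    between left-PFC dHbO* and severity is positive.  Sensitivity and
    specificity at the supplied fixed cutoffs are reported alongside the
    full ROC.
    """
    feature = np.asarray(feature, float)
    severity = np.asarray(severity, float)
    thr = np.quantile(severity, quantile)
    labels = (severity > thr).astype(int)
    if labels.min() == labels.max():
        raise ScreeningError(
            "degenerate severity dichotomization: one class is empty"
        )
    roc = roc_curve(feature, labels, orientation=orientation)
    auc_ci(roc, method=ci_method)
    fixed = {
        c: apply_cutoff(feature, labels, c, orientation) for c in fixed_cutoffs
    }
    return {
        "roc": roc,
        "fixed_cutoffs": fixed,
        "severity_threshold": float(thr),
        "dichotomization": f"quantile split at q={quantile} (package convention)",
    }


class YoudenScreener(BaseEstimator, ClassifierMixin):
    """Single-score screening classifier with a Youden-optimal cutoff.

    ``fit`` builds the empirical ROC of the 1-d score against the binary
    label and stores the Youden cutoff; ``predict`` applies it.  Fitted
    attributes: ``roc_``, ``cutoff_``, ``auc_``, ``ci_``.
    """

    def __init__(self, orientation: str = "low_positive",
                 ci_method: str = "hanley-mcneil"):
        self.orientation = orientation
        self.ci_method = ci_method

    def _scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ScreeningError("YoudenScreener expects a single score column")
        return X

    def fit(self, X, y):
        s = self._scores(X)
        self.roc_ = roc_curve(s, np.asarray(y), orientation=self.orientation)
        self.ci_ = auc_ci(self.roc_, method=self.ci_method)
        self.cutoff_ = youden_cutoff(self.roc_)
        self.auc_ = self.roc_.auc
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X):
        s = self._scores(X)
        if self.orientation == "low_positive":
            return (s <= self.cutoff_).astype(int)
        return (s >= self.cutoff_).astype(int)

    def decision_function(self, X):
        s = self._scores(X)
        return self.cutoff_ - s if self.orientation == "low_positive" else s - self.cutoff_
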