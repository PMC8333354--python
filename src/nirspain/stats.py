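"""Group-level statistics for the cold-pressor feature table.

Implements the study's statistical layer:

* cohort characterization (Mann-Whitney U for continuous, Fisher's exact
  for binary categorical variables);
* one GEE per ROI per outcome -- a marginal Gaussian model
  ``outcome ~ group + temperature + group:temperature`` with exchangeable
  working correlation, subject clusters (two observations each) and robust
  sandwich covariance; effects are reported as df=1 Wald chi-square with
  Cramer's V = sqrt(chi2 / (n * df)) computed on the number of subjects;
* Spearman rank-correlation tables with 0.05/0.01 significance flags;
* a Gaussian GLM relating severity scores to left/right PFC dHbO*;
* the a-priori sample-size computation for an omnibus multiple-regression
  F test via the noncentral-F distribution (lambda = f2 * N), with an
  attrition inflation step.

Sum-to-zero (effect) coding is used in the GEE so each df=1 Wald test is a
Type-III-style main effect, matching the structure of the published table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "StatsError",
    "GroupStatResult",
    "GlmTerm",
    "characterize_cohort",
    "gee_wald",
    "cramers_v",
    "spearman_table",
    "glm_severity",
    "regression_power",
    "sample_size_regression",
    "inflate_sample",
]


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GroupStatResult:
    effect: str  # "group" | "temperature" | "interaction"
    wald_chi2: float
    df: int
    p_value: float
    cramers_v: float
    p_bonferroni: float | None = None


@dataclass(frozen=True)
class GlmTerm:
    term: str
    coef: float
    std_err: float
    ci_low: float
    ci_high: float
    wald_chi2: float
    df: int
    p_value: float


def characterize_cohort(
    metadata: pd.DataFrame,
    continuous: list[str],
    categorical: list[str] | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Two-group comparison table.

    Continuous variables get group mean/SD plus a two-sided Mann-Whitney U
    p-value (tie-corrected); binary categorical variables get counts plus
    Fisher's exact p.
    """
    groups = sorted(metadata[group_col].dropna().unique())
    if len(groups) != 2:
        raise StatsError(f"expected exactly two groups, found {groups}")
    g1 = metadata[metadata[group_col] == groups[0]]
    g2 = metadata[metadata[group_col] == groups[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise StatsError("one group is empty")
    rows = []
    for var in continuous:
        x, y = g1[var].dropna(), g2[var].dropna()
        p = sps.mannwhitneyu(x, y, alternative="two-sided").pvalue
        rows.append(
            {
                "variable": var, "kind": "continuous",
                f"{groups[0]}_mean": x.mean(), f"{groups[0]}_sd": x.std(ddof=1),
                f"{groups[1]}_mean": y.mean(), f"{groups[1]}_sd": y.std(ddof=1),
                "test": "mann-whitney", "p_value": float(p),
            }
        )
    for var in categorical or []:
        tab = pd.crosstab(metadata[group_col], metadata[var])
        if tab.shape != (2, 2):
            # pad absent levels so all-one-level variables stay testable
            tab = tab.reindex(columns=[False, True], fill_value=0)
            if tab.shape != (2, 2):
                raise StatsError(f"{var!r} is not binary; Fisher test needs 2x2")
        p = sps.fisher_exact(tab.to_numpy())[1]
        rows.append(
            {
                "variable": var, "kind": "categorical",
                f"{groups[0]}_mean": np.nan, f"{groups[0]}_sd": np.nan,
                f"{groups[1]}_mean": np.nan, f"{groups[1]}_sd": np.nan,
                "test": "fisher-exact", "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


def cramers_v(chi2: float, n: int, df: int = 1) -> float:
    """Effect size V = sqrt(chi2 / (n * df))."""
    if chi2 < 0:
        raise StatsError("chi2 must be >= 0")
    if n <= 0:
        raise StatsError("n must be > 0")
    return math.sqrt(chi2 / (n * df))


def gee_wald(
    features: pd.DataFrame,
    outcome: str,
    roi: str,
    group_col: str = "group",
    subject_col: str = "subject_id",
    bonferroni_family: int | None = None,
) -> list[GroupStatResult]:
    """GEE group x temperature comparison for one ROI and one outcome.

    Fits ``outcome ~ C(group, Sum) * C(temperature, Sum)`` with exchangeable
    working correlation over subject clusters and reports robust Wald
    chi-square (df = 1) for the group, temperature and interaction effects,
    with Cramer's V computed on the subject count.  ``bonferroni_family``
    optionally adds a per-family adjusted p (e.g. 4 for the four ROIs).
    """
    data = features[features["roi"] == roi].dropna(subset=[outcome]).copy()
    counts = data.groupby(subject_col)["temperature"].nunique()
    if (counts < 2).any():
        incomplete = list(counts.index[counts < 2])
        raise StatsError(
            f"subjects missing a temperature row for ROI {roi!r}: {incomplete}"
        )
    n_per_group = data.groupby(group_col)[subject_col].nunique()
    if len(n_per_group) != 2 or (n_per_group < 2).any():
        raise StatsError("need two groups with >= 2 subjects each")
    data = data.sort_values([subject_col, "temperature"])
    model = smf.gee(
        f"{outcome} ~ C({group_col}, Sum) * C(temperature, Sum)",
        groups=subject_col,
        data=data,
        cov_struct=sm.cov_struct.Exchangeable(),
        family=sm.families.Gaussian(),
    )
    try:
        res = model.fit()
    except Exception as exc:  # statsmodels raises various numeric errors
        raise StatsError(f"GEE failed to converge for ROI {roi!r}: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise StatsError(f"singular design for ROI {roi!r}")
    n_subjects = int(data[subject_col].nunique())
    names = list(res.params.index)
    effect_terms = {
        "group": next(t for t in names if t.startswith("C(" + group_col) and ":" not in t),
        "temperature": next(
            t for t in names if t.startswith("C(temperature") and ":" not in t
        ),
        "interaction": next(t for t in names if ":" in t),
    }
    out = []
    for effect, term in effect_terms.items():
        z = res.params[term] / res.bse[term]
        chi2 = float(z**2)
        p = float(sps.chi2.sf(chi2, 1))
        p_adj = (
            min(1.0, p * bonferroni_family) if bonferroni_family else None
        )
        out.append(
            GroupStatResult(
                effect=effect, wald_chi2=chi2, df=1, p_value=p,
                cramers_v=cramers_v(chi2, n_subjects, 1),
                p_bonferroni=p_adj,
            )
        )
    return out


def spearman_table(
    data: pd.DataFrame,
    columns: list[str],
) -> pd.DataFrame:
    """Pairwise Spearman rho with two-tailed p and significance flags.

    Ties are mid-ranked; a constant column yields NaN cells flagged as
    undefined.  Returns a tidy frame (var_x, var_y, rho, p_value, flag).
    """
    rows = []
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            pair = data[[a, b]].dropna()
            if len(pair) < 4:
                raise StatsError(f"need >= 4 paired observations for ({a}, {b})")
            if pair[a].nunique() == 1 or pair[b].nunique() == 1:
                rows.append(
                    {"var_x": a, "var_y": b, "rho": np.nan, "p_value": np.nan,
                     "flag": "undefined (constant input)"}
                )
                continue
            rho, p = sps.spearmanr(pair[a], pair[b])
            flag = "**" if p < 0.01 else "*" if p < 0.05 else ""
            rows.append(
                {"var_x": a, "var_y": b, "rho": float(rho),
                 "p_value": float(p), "flag": flag}
            )
    return pd.DataFrame(rows)


def glm_severity(
    data: pd.DataFrame,
    outcome: str,
    predictors: tuple[str, str] = ("dhbostar_left_PFC", "dhbostar_right_PFC"),
) -> list[GlmTerm]:
    """Gaussian GLM of a severity score on the two PFC dHbO* predictors.

    Reports per term the coefficient B, its standard error, 95 % CI and the
    df=1 Wald chi-square, mirroring the published model layout.
    """
    cols = [outcome, *predictors]
    d = data[cols].dropna()
    if len(d) < 10:
        raise StatsError("need >= 10 complete cases")
    if len(predictors) == 2:
        r = np.corrcoef(d[predictors[0]], d[predictors[1]])[0, 1]
        if abs(r) > 0.999:
            raise StatsError(f"collinear predictors (|r| = {abs(r):.4f})")
    X = sm.add_constant(d[list(predictors)])
    res = sm.GLM(d[outcome], X, family=sm.families.Gaussian()).fit()
    ci = res.conf_int(alpha=0.05)
    out = []
    for term in X.columns:
        z = res.params[term] / res.bse[term]
        chi2 = float(z**2)
        out.append(
            GlmTerm(
                term="(Intercept)" if term == "const" else term,
                coef=float(res.params[term]),
                std_err=float(res.bse[term]),
                ci_low=float(ci.loc[term, 0]),
                ci_high=float(ci.loc[term, 1]),
                wald_chi2=chi2,
                df=1,
                p_value=float(sps.chi2.sf(chi2, 1)),
            )
        )
    return out


def regression_power(
    n: int, f2: float, n_predictors: int, alpha: float = 0.05
) -> float:
    """Power of the omnibus F test of a multiple regression.

    Noncentral F with lambda = f2 * N and df = (u, N - u - 1).
    """
    df2 = n - n_predictors - 1
    if df2 < 1:
        return 0.0
    crit = sps.f.isf(alpha, n_predictors, df2)
    return float(sps.ncf.sf(crit, n_predictors, df2, f2 * n))


def inflate_sample(n: int, inflation: float) -> int:
    """Attrition-inflated sample size, rounded up."""
    return int(math.ceil(n * (1.0 + inflation)))


def sample_size_regression(
    effect_size: float = 0.6,
    alpha: float = 0.05,
    power: float = 0.80,
    n_predictors: int = 2,
    inflation: float = 0.10,
    effect_type: str = "f2",
    n_max: int = 10_000,
) -> tuple[int, int]:
    """Smallest N whose omnibus-regression power reaches the target.

    ``effect_size`` is Cohen's f2 by default (``effect_type='f'`` squares it
    first).  Returns ``(base_n, inflated_n)`` with the attrition inflation
    applied to the base.
    """
    if effect_size <= 0:
        raise StatsError("effect size must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise StatsError("alpha and power must lie in (0, 1)")
    f2 = effect_size if effect_type == "f2" else effect_size**2
    for n in range(n_predictors + 2, n_max + 1):
        if regression_power(n, f2, n_predictors, alpha) >= power:
            return n, inflate_sample(n, inflation)
    raise StatsError(f"target power not reached by N = {n_max}")
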