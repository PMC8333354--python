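"""Cohort characterization, GEE, Cramer's V, Spearman, GLM, sample size."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from nirspain.stats import (
    StatsError,
    characterize_cohort,
    cramers_v,
    gee_wald,
    glm_severity,
    inflate_sample,
    regression_power,
    sample_size_regression,
    spearman_table,
)


class TestCharacterize:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 20)
        meta = pd.DataFrame(
            {"group": ["a"] * 20 + ["b"] * 20, "v": np.concatenate([x, x])}
        )
        out = characterize_cohort(meta, continuous=["v"])
        assert out.loc[0, "p_value"] > 0.9

    def test_fisher_exact_on_perfect_split(self):
        meta = pd.DataFrame(
            {
                "group": ["a"] * 10 + ["b"] * 10,
                "flag": [True] * 10 + [False] * 10,
            }
        )
        out = characterize_cohort(meta, continuous=[], categorical=["flag"])
        # hypergeometric: 2 / C(20,10) = 2/184756
        assert out.loc[0, "p_value"] == pytest.approx(2 / 184756, rel=1e-6)

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(2)
        meta = pd.DataFrame(
            {
                "group": ["a"] * 20 + ["b"] * 20,
                "v": np.concatenate(
                    [rng.normal(0, 1, 20), rng.normal(3, 1, 20)]
                ),
            }
        )
        out = characterize_cohort(meta, continuous=["v"])
        assert out.loc[0, "p_value"] < 0.001

    def test_single_group_rejected(self):
        meta = pd.DataFrame({"group": ["a"] * 5, "v": range(5)})
        with pytest.raises(StatsError):
            characterize_cohort(meta, continuous=["v"])


class TestCramersV:
    @pytest.mark.parametrize(
        "chi2, n, expected",
        [(5.33, 41, 0.36), (13.15, 41, 0.57), (0.0, 41, 0.0)],
    )
    def test_published_effect_sizes(self, chi2, n, expected):
        assert round(cramers_v(chi2, n), 2) == expected

    def test_invalid_inputs(self):
        with pytest.raises(StatsError):
            cramers_v(-1.0, 41)
        with pytest.raises(StatsError):
            cramers_v(1.0, 0)

    @given(
        chi2=st.floats(0.01, 100, allow_nan=False),
        n=st.integers(2, 500),
        c=st.integers(2, 9),
    )
    def test_scale_consistency(self, chi2, n, c):
        assert cramers_v(c * chi2, c * n) == pytest.approx(cramers_v(chi2, n))


def _paired_features(rng, n_per_group, temp_effect=0.0, group_effect=0.0,
                     subject_sd=0.0, noise_sd=1.0, roi="left_PFC"):
    rows = []
    for g, gname in enumerate(("fibromyalgia", "control")):
        for k in range(n_per_group):
            sid = f"{gname[:2]}{k}"
            u = rng.normal(0, subject_sd)
            for t, temp in enumerate(("25C", "5C")):
                rows.append(
                    {
                        "subject_id": sid,
                        "group": gname,
                        "roi": roi,
                        "temperature": temp,
                        "y": group_effect * g + temp_effect * t + u
                        + rng.normal(0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)


class TestGee:
    def test_null_data_gives_null_inference(self, rng):
        feats = _paired_features(rng, 30, noise_sd=0.01)
        # add a tiny constant so the outcome is not literally degenerate
        feats["y"] += 1.0
        results = gee_wald(feats, "y", "left_PFC")
        for r in results:
            assert r.wald_chi2 < 4.0
            assert r.p_value > 0.04

    def test_incomplete_subject_rejected(self, rng):
        feats = _paired_features(rng, 5)
        feats = feats.drop(index=feats.index[1])  # drop one temperature row
        with pytest.raises(StatsError):
            gee_wald(feats, "y", "left_PFC")

    def test_matches_hand_sandwich_on_mirrored_clusters(self):
        """On balanced data built so the within-cluster cross-moments vanish,
        exchangeable GEE inference equals heteroskedasticity-robust OLS."""
        rng = np.random.default_rng(3)
        n = 24
        base = _paired_features(rng, n, temp_effect=0.4, group_effect=0.6)
        # mirror residual pairs: duplicate each subject with the second
        # temperature observation reflected about the cell mean
        cell_mean = base.groupby(["group", "temperature"])["y"].transform(
            "mean"
        )
        resid = base["y"] - cell_mean
        mirrored = base.copy()
        mirrored["subject_id"] = mirrored["subject_id"] + "_m"
        flip = np.where(mirrored["temperature"] == "5C", -1.0, 1.0)
        mirrored["y"] = cell_mean + flip * resid
        data = pd.concat([base, mirrored], ignore_index=True)

        results = gee_wald(data, "y", "left_PFC")

        # independent oracle: sum-coded OLS with the HC0 sandwich, by hand
        g = np.where(data["group"] == "control", 1.0, -1.0)
        t = np.where(data["temperature"] == "5C", 1.0, -1.0)
        X = np.column_stack([np.ones(len(data)), g, t, g * t])
        y = data["y"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        bread = np.linalg.inv(X.T @ X)
        meat = X.T @ (X * (r**2)[:, None])
        cov = bread @ meat @ bread
        wald_ols = beta**2 / np.diag(cov)
        by_effect = dict(zip(("group", "temperature", "interaction"),
                             wald_ols[1:]))
        for res in results:
            assert res.wald_chi2 == pytest.approx(
                by_effect[res.effect], abs=1e-6
            )

    def test_power_for_one_sd_temperature_effect(self):
        """A 1-SD within-subject temperature shift at n = 50/group is
        detected in the vast majority of replicates."""
        rng = np.random.default_rng(4)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            feats = _paired_features(rng, 50, temp_effect=1.0, noise_sd=1.0)
            res = gee_wald(feats, "y", "left_PFC")
            p = next(r.p_value for r in res if r.effect == "temperature")
            hits += p < 0.05
        assert hits / n_rep >= 0.80

    def test_bonferroni_flag(self, rng):
        feats = _paired_features(rng, 10, temp_effect=1.0)
        res = gee_wald(feats, "y", "left_PFC", bonferroni_family=4)
        for r in res:
            assert r.p_bonferroni == pytest.approx(min(1.0, 4 * r.p_value))


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self, rng):
        x = rng.normal(0, 1, 30)
        df = pd.DataFrame({"x": x, "y": np.exp(x), "z": -x})
        out = spearman_table(df, ["x", "y", "z"])
        lookup = {(r.var_x, r.var_y): r.rho for r in out.itertuples()}
        assert lookup[("x", "y")] == pytest.approx(1.0)
        assert lookup[("x", "z")] == pytest.approx(-1.0)

    def test_hand_rank_case(self):
        # sum of squared rank differences = 4 -> rho = 1 - 6*4/(5*24) = 0.8
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [1, 3, 2, 5, 4]})
        out = spearman_table(df, ["x", "y"])
        assert out.loc[0, "rho"] == pytest.approx(0.8)

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [2, 2, 2, 2]})
        out = spearman_table(df, ["x", "y"])
        assert np.isnan(out.loc[0, "rho"])
        assert "undefined" in out.loc[0, "flag"]

    @given(
        seed=st.integers(0, 1000),
        power=st.floats(0.2, 3.0),
    )
    def test_invariance_under_random_monotone_maps(self, seed, power):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 15)
        y = rng.normal(0, 1, 15)
        rho0 = sps.spearmanr(x, y).statistic
        rho1 = sps.spearmanr(np.sign(x) * np.abs(x) ** power, y).statistic
        assert rho0 == pytest.approx(rho1, abs=1e-12)


class TestGlm:
    def _frame(self, rng, n=22, b0=70.0, bl=49.0, br=-22.0, sigma=1.0):
        xl = rng.normal(0.3, 0.2, n)
        xr = 0.6 * xl + rng.normal(0, 0.15, n)
        y = b0 + bl * xl + br * xr + rng.normal(0, sigma, n)
        return pd.DataFrame(
            {"score": y, "dhbostar_left_PFC": xl, "dhbostar_right_PFC": xr}
        )

    def test_constant_outcome_gives_null_slopes(self, rng):
        df = self._frame(rng, bl=0.0, br=0.0, sigma=1e-9)
        df["score"] = 70.0 + rng.normal(0, 1e-6, len(df))
        res = glm_severity(df, "score")
        for term in res:
            if term.term != "(Intercept)":
                assert abs(term.coef) < 1e-3
                assert term.ci_low <= 0.0 <= term.ci_high

    def test_parameter_recovery_coverage(self):
        """True coefficients fall inside the 95% CI in ~95% of replicates."""
        rng = np.random.default_rng(5)
        hits_l = hits_r = 0
        n_rep = 200
        for _ in range(n_rep):
            df = self._frame(rng, sigma=1.0)
            res = {t.term: t for t in glm_severity(df, "score")}
            tl = res["dhbostar_left_PFC"]
            tr = res["dhbostar_right_PFC"]
            hits_l += tl.ci_low <= 49.0 <= tl.ci_high
            hits_r += tr.ci_low <= -22.0 <= tr.ci_high
        assert hits_l / n_rep >= 0.90
        assert hits_r / n_rep >= 0.90

    def test_single_predictor_equals_closed_form_ols(self, rng):
        df = self._frame(rng)
        res = glm_severity(df, "score", predictors=("dhbostar_left_PFC",))
        x = df["dhbostar_left_PFC"].to_numpy()
        y = df["score"].to_numpy()
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        term = next(t for t in res if t.term == "dhbostar_left_PFC")
        assert term.coef == pytest.approx(slope, rel=1e-10)

    def test_collinear_predictors_rejected(self, rng):
        df = self._frame(rng)
        df["dhbostar_right_PFC"] = 2.0 * df["dhbostar_left_PFC"]
        with pytest.raises(StatsError):
            glm_severity(df, "score")

    def test_too_few_cases_rejected(self, rng):
        df = self._frame(rng, n=5)
        with pytest.raises(StatsError):
            glm_severity(df, "score")


class TestSampleSize:
    def test_power_monotone_in_n(self):
        powers = [regression_power(n, 0.6, 2) for n in range(5, 101)]
        assert all(b >= a - 1e-12 for a, b in zip(powers, powers[1:]))

    def test_inflation_rounds_up(self):
        assert inflate_sample(20, 0.10) == 22
        assert inflate_sample(19, 0.10) == 21  # ceil(20.9)

    def test_matches_monte_carlo_within_one_subject(self):
        """Analytic noncentral-F power agrees with direct simulation of the
        omnibus regression F test."""
        f2 = 0.6
        base_n, _ = sample_size_regression(f2, effect_type="f2")
        rng = np.random.default_rng(6)
        u = 2
        b = math.sqrt(f2)  # slope giving population R2 = f2/(1+f2)

        def mc_power(n, reps=50_000):
            X = rng.normal(size=(reps, n, u))
            # standardize columns (fixed-design convention: lambda = f2 * N)
            X = (X - X.mean(axis=1, keepdims=True)) / X.std(
                axis=1, keepdims=True
            )
            y = b * X[:, :, 0] + rng.normal(size=(reps, n))
            Xd = np.concatenate([np.ones((reps, n, 1)), X], axis=2)
            # batched least squares via normal equations
            xtx = np.einsum("rni,rnj->rij", Xd, Xd)
            xty = np.einsum("rni,rn->ri", Xd, y)
            beta = np.linalg.solve(xtx, xty[..., None])[..., 0]
            fit = np.einsum("rni,ri->rn", Xd, beta)
            ssr = ((fit - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            sse = ((y - fit) ** 2).sum(axis=1)
            fstat = (ssr / u) / (sse / (n - u - 1))
            crit = sps.f.isf(0.05, u, n - u - 1)
            return (fstat > crit).mean()

        # the smallest N reaching 80% by simulation is within +-1 of analytic
        p_at = mc_power(base_n)
        p_below = mc_power(base_n - 2)
        assert p_at >= 0.80 - 0.02
        assert p_below < 0.80 + 0.02

    def test_invalid_inputs(self):
        with pytest.raises(StatsError):
            sample_size_regression(0.0)
        with pytest.raises(StatsError):
            sample_size_regression(0.5, alpha=1.5)
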