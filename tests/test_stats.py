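"""Cohort statistics: regressions, correlations, change slopes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from longnet import (
    brain_cognition_correlation,
    change_slopes,
    metric_age_regression,
    metric_correlations,
    partial_correlation,
    pearson_with_ci,
)
from longnet.nulls import compare_to_null


def _cohort(n=80, seed=0, beta_age=0.004, noise=0.05):
    rng = np.random.default_rng(seed)
    age = rng.uniform(64, 83, n)
    gender = rng.integers(0, 2, n)
    education = rng.integers(1, 4, n)
    fd = rng.lognormal(np.log(0.2), 0.3, n)
    metric = 0.4 + beta_age * (age - age.mean()) + rng.normal(0, noise, n)
    return pd.DataFrame(
        {
            "subject": [f"s{i}" for i in range(n)],
            "age": age,
            "gender": gender,
            "education": education,
            "fd": fd,
            "flexibility": metric,
        }
    )


class TestMetricAgeRegression:
    def test_recovers_planted_age_effect(self):
        hits = 0
        for seed in range(30):
            df = _cohort(n=150, seed=seed)
            rep = metric_age_regression(df, "flexibility")
            est = rep.table.loc["age", "estimate"]
            se = rep.table.loc["age", "se"]
            if est > 0 and abs(est - 0.004) < 2 * se:
                hits += 1
        assert hits >= 27  # >= 90% of replicates

    def test_constant_outcome_gives_zero_slopes(self):
        df = _cohort(n=40, seed=1)
        df["flexibility"] = 0.7
        rep = metric_age_regression(df, "flexibility")
        assert rep.table.loc["age", "estimate"] == pytest.approx(0.0, abs=1e-12)
        assert rep.r_squared == pytest.approx(0.0, abs=1e-10)

    def test_exact_linear_relation_gives_partial_eta_one(self):
        df = _cohort(n=40, seed=2)
        df["flexibility"] = 2.0 * (df["age"] - df["age"].mean())
        rep = metric_age_regression(df, "flexibility", covariates=())
        assert rep.table.loc["age", "estimate"] == pytest.approx(2.0)
        assert rep.table.loc["age", "partial_eta_sq"] == pytest.approx(1.0)

    def test_collinear_design_names_offender(self):
        df = _cohort(n=40, seed=3)
        df["fd"] = df["age"] * 2.0  # exact collinearity with centered age
        with pytest.raises(ValueError, match="fd"):
            metric_age_regression(df, "flexibility")

    def test_partial_eta_sq_equals_squared_partial_correlation(self):
        df = _cohort(n=60, seed=4)
        rep = metric_age_regression(df, "flexibility")
        controls = df[["gender", "education", "fd"]].to_numpy().astype(float)
        prec = partial_correlation(
            df["flexibility"].to_numpy(),
            (df["age"] - df["age"].mean()).to_numpy(),
            controls,
        )
        assert rep.table.loc["age", "partial_eta_sq"] == pytest.approx(
            prec["r"] ** 2, abs=1e-10
        )

    def test_welch_t_agrees_with_ols_dummy_under_equal_variance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 1, 40)
        c = compare_to_null(x, y)
        df = pd.DataFrame(
            {
                "age": np.concatenate([np.ones(40), np.zeros(40)]),
                "flexibility": np.concatenate([x, y]),
            }
        )
        rep = metric_age_regression(df, "flexibility", covariates=())
        # Welch df differs, but t statistics agree when group sizes match
        assert abs(abs(c.t) - abs(rep.table.loc["age", "estimate"] / rep.table.loc["age", "se"])) < 1e-6


class TestCorrelations:
    def test_perfect_negative_correlation(self):
        df = pd.DataFrame({"Q_mean": np.arange(10.0), "recruitment": -np.arange(10.0),
                           "flexibility": np.arange(10.0) ** 2, "age": np.random.default_rng(0).normal(70, 4, 10)})
        out = metric_correlations(df, columns=("Q_mean", "recruitment"), control=None)
        assert out.loc[0, "r"] == pytest.approx(-1.0)

    def test_r_matches_brute_force_covariance_formula(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
        y = np.array([0.5, 1.1, 1.9, 2.6, 3.1])
        rec = pearson_with_ci(x, y)
        r_hand = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert rec["r"] == pytest.approx(r_hand, abs=1e-12)

    def test_partial_correlation_with_degenerate_control_flagged(self):
        x = np.random.default_rng(1).normal(size=30)
        y = np.random.default_rng(2).normal(size=30)
        with pytest.raises(ValueError, match="control"):
            partial_correlation(x, y, x)

    def test_pvalues_match_permutation_null(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(size=25)
        rec = pearson_with_ci(x, y)
        # permutation oracle
        robs = abs(np.corrcoef(x, y)[0, 1])
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            count += abs(np.corrcoef(x, rng.permutation(y))[0, 1]) >= robs
        p_perm = (count + 1) / (n_perm + 1)
        mc_err = 3 * np.sqrt(max(p_perm, rec["p"]) / n_perm) + 1e-3
        assert abs(rec["p"] - p_perm) < max(0.01, mc_err)

    def test_partial_correlation_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {"x": rng.normal(size=40), "y": rng.normal(size=40), "z": rng.normal(size=40)}
        )
        df["y"] += 0.5 * df["z"]
        df["x"] += 0.5 * df["z"]
        ours = partial_correlation(df["x"].to_numpy(), df["y"].to_numpy(), df["z"].to_numpy())
        ref = pg.partial_corr(df, x="x", y="y", covar="z")
        p_col = "p_val" if "p_val" in ref.columns else "p-val"
        assert ours["r"] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert ours["p"] == pytest.approx(float(ref[p_col].iloc[0]), abs=1e-10)

    def test_partial_removes_a_common_driver(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=200)
        x = z + 0.3 * rng.normal(size=200)
        y = z + 0.3 * rng.normal(size=200)
        raw = pearson_with_ci(x, y)["r"]
        part = partial_correlation(x, y, z)["r"]
        assert raw > 0.8 and abs(part) < 0.3


class TestChangeSlopes:
    def _cog(self, rows):
        return pd.DataFrame(rows, columns=["subject", "occasion", "speed_T"])

    def test_closed_form_slope_on_printed_scores(self):
        cog = self._cog([("a", o, s) for o, s in zip(range(4), (50, 49, 48, 46))])
        out = change_slopes(cog, "speed_T", adjust_retest=False)
        assert out["a"] == pytest.approx(-1.0, abs=1e-12)

    def test_constant_scores_give_zero_slope(self):
        cog = self._cog([("a", o, 50.0) for o in range(4)])
        out = change_slopes(cog, "speed_T", adjust_retest=False)
        assert out["a"] == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_three_occasions_flagged_missing(self):
        cog = self._cog([("a", 0, 50.0), ("a", 1, 49.0), ("b", 0, 50.0),
                         ("b", 1, 49.0), ("b", 2, 48.0)])
        out = change_slopes(cog, "speed_T", adjust_retest=False)
        assert np.isnan(out["a"]) and np.isfinite(out["b"])

    def test_retest_adjustment_removes_followup_bump(self):
        # pure retest jump, no true slope: adjusted slopes should be ~0
        rng = np.random.default_rng(3)
        rows = []
        for s in range(60):
            for o, t in zip(range(4), (0, 1, 2, 4)):
                rows.append((f"s{s}", o, 50 + 2.0 * (o > 0) + rng.normal(0, 0.3)))
        cog = self._cog(rows)
        adj = change_slopes(cog, "speed_T", adjust_retest=True)
        raw = change_slopes(cog, "speed_T", adjust_retest=False)
        assert abs(adj.mean()) < abs(raw.mean())
        assert abs(adj.mean()) < 0.1

    def test_cohort_mean_slope_recovered(self):
        rng = np.random.default_rng(4)
        rows = []
        for s in range(150):
            slope = -0.5 + rng.normal(0, 0.3)
            for o, t in zip(range(4), (0, 1, 2, 4)):
                rows.append((f"s{s:03d}", o, 50 + slope * t + rng.normal(0, 1)))
        out = change_slopes(self._cog(rows), "speed_T", adjust_retest=False)
        assert abs(out.mean() - (-0.5)) < 0.1

    def test_shrinkage_pulls_toward_cohort_mean(self):
        rng = np.random.default_rng(5)
        rows = []
        for s in range(40):
            slope = -0.5 + rng.normal(0, 0.2)
            for o, t in zip(range(4), (0, 1, 2, 4)):
                rows.append((f"s{s:02d}", o, 50 + slope * t + rng.normal(0, 2)))
        cog = self._cog(rows)
        raw = change_slopes(cog, "speed_T", adjust_retest=False)
        shrunk = change_slopes(cog, "speed_T", adjust_retest=False, shrink=True)
        assert shrunk.var() < raw.var()
        assert abs(shrunk.mean() - raw.mean()) < 0.05


class TestBrainCognition:
    def test_null_association_stays_small(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {
                "flexibility": rng.normal(0.4, 0.05, 150),
                "speed_slope": rng.normal(-0.5, 0.3, 150),
                "age": rng.uniform(64, 83, 150),
            }
        )
        out = brain_cognition_correlation(df, ["flexibility"], ["speed_slope"])
        assert abs(out.loc[0, "r"]) < 0.2

    def test_planted_association_sign_recovered(self):
        rng = np.random.default_rng(7)
        flex = rng.normal(0.4, 0.05, 150)
        df = pd.DataFrame(
            {
                "flexibility": flex,
                "speed_slope": 3.0 * flex + rng.normal(0, 0.1, 150),
                "age": rng.uniform(64, 83, 150),
            }
        )
        out = brain_cognition_correlation(df, ["flexibility"], ["speed_slope"])
        assert out.loc[0, "r"] > 0.5
        assert out.loc[0, "partial_r"] > 0.5

    def test_tiny_sample_gives_wide_interval(self):
        df = pd.DataFrame(
            {"flexibility": [0.1, 0.5, 0.9, 0.2], "speed_slope": [0.0, -1.0, 0.5, 0.2],
             "age": [65.0, 70.0, 75.0, 80.0]}
        )
        out = brain_cognition_correlation(df, ["flexibility"], ["speed_slope"], control=None)
        assert out.loc[0, "ci_high"] - out.loc[0, "ci_low"] > 1.0
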