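"""Group-level statistics: age regressions, metric correlations, change slopes.

The cohort-level questions addressed here are (a) whether each multilayer
metric varies with age at baseline, controlling for gender, education and
head motion; (b) how modularity, recruitment and flexibility inter-relate,
with and without age partialled out; and (c) whether per-subject rates of
cognitive change track the network metrics ("change-change" association).

Per-subject cognitive change is summarized by the OLS slope of score on
time in years, after an optional cohort-level adjustment for the retest
(practice) effect between baseline and the first follow-up; an optional
empirical-shrinkage mode pulls noisy subject slopes toward the cohort
mean.  This deliberately replaces full random-slope mixed-model machinery
with a transparent two-stage estimate, since the slopes are used only as
inputs to correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _sps

#: Default occasion -> time-in-years mapping for a 4-occasion design.
DEFAULT_TIMES = {0: 0.0, 1: 1.0, 2: 2.0, 3: 4.0}

#: Retest indicator: 0 at baseline, 1 at every follow-up.
def retest_indicator(occasion: np.ndarray) -> np.ndarray:
    return (np.asarray(occasion) > 0).astype(float)


@dataclass
class RegressionReport:
    """OLS fit of one metric on age plus nuisance covariates."""

    outcome: str
    table: pd.DataFrame  # index: predictors; estimate, se, ci_low, ci_high, p, partial_eta_sq
    n: int
    r_squared: float

    def coefficient(self, predictor: str) -> float:
        return float(self.table.loc[predictor, "estimate"])


def _check_design(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns that do not raise the rank
        cols, bad = [], []
        mat = np.empty((X.shape[0], 0))
        for c in X.columns:
            trial = np.column_stack([mat, X[c].to_numpy()])
            if np.linalg.matrix_rank(trial) > mat.shape[1]:
                mat = trial
                cols.append(c)
            else:
                bad.append(c)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def metric_age_regression(
    cohort: pd.DataFrame,
    metric: str,
    covariates: tuple[str, ...] = ("gender", "education", "fd"),
    age_col: str = "age",
    n_models: int = 1,
    alpha: float = 0.05,
) -> RegressionReport:
    """OLS of a metric on grand-mean-centered age plus nuisance covariates.

    Partial eta-squared per predictor is SS_effect / (SS_effect + SS_resid)
    from the type-III decomposition, computed as t^2 / (t^2 + df_resid) for
    these single-degree-of-freedom terms.  Significance is judged at
    ``alpha / n_models`` (Bonferroni over the family of models run).
    """
    df = cohort.dropna(subset=[metric, age_col, *covariates])
    n = len(df)
    if n <= len(covariates) + 2:
        raise ValueError(f"need more subjects ({n}) than predictors")
    X = pd.DataFrame({"age": df[age_col] - df[age_col].mean()})
    for c in covariates:
        X[c] = df[c].astype(float)
    X = sm.add_constant(X)
    _check_design(X)
    fit = sm.OLS(df[metric].astype(float), X).fit()
    tvals = fit.tvalues
    # guard the all-constant-outcome case where t is 0/0
    tvals = tvals.where(np.isfinite(tvals), 0.0)
    partial_eta = tvals**2 / (tvals**2 + fit.df_resid)
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": fit.pvalues.where(np.isfinite(fit.pvalues), 1.0),
            "partial_eta_sq": partial_eta,
        }
    )
    table["significant"] = table["p"] < alpha / n_models
    table.index = ["intercept"] + list(X.columns[1:])
    return RegressionReport(
        outcome=metric,
        table=table,
        n=n,
        r_squared=float(fit.rsquared) if np.isfinite(fit.rsquared) else 0.0,
    )


def pearson_with_ci(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> dict:
    """Pearson r with the Fisher-z confidence interval and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in correlation input")
    r, p = _sps.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = _sps.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return {
        "r": float(r),
        "ci_low": float(np.tanh(z - half)),
        "ci_high": float(np.tanh(z + half)),
        "p": float(p),
        "n": n,
    }


def _residualize(y: np.ndarray, controls: np.ndarray) -> np.ndarray:
    X = sm.add_constant(controls)
    return np.asarray(sm.OLS(y, X).fit().resid)


def partial_correlation(
    x: np.ndarray, y: np.ndarray, controls: np.ndarray, alpha: float = 0.05
) -> dict:
    """Partial Pearson correlation via residual-on-residual correlation."""
    controls = np.atleast_2d(np.asarray(controls, dtype=float))
    if controls.shape[0] == 1:
        controls = controls.T
    k = controls.shape[1]
    for j in range(k):
        c = controls[:, j]
        if np.std(c) == 0:
            raise ValueError("constant control variable")
        if np.std(x - c) < 1e-12 * max(1.0, np.std(x)) or np.std(y - c) < 1e-12 * max(
            1.0, np.std(y)
        ):
            raise ValueError("control variable equals one of the correlated variables")
    rx = _residualize(np.asarray(x, float), controls)
    ry = _residualize(np.asarray(y, float), controls)
    n = len(rx)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / max(1e-300, 1 - r**2))
    p = 2 * _sps.t.sf(abs(t), df)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = _sps.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3 - k)
    return {
        "r": r,
        "ci_low": float(np.tanh(z - half)),
        "ci_high": float(np.tanh(z + half)),
        "p": float(p),
        "n": n,
    }


def metric_correlations(
    cohort: pd.DataFrame,
    columns: tuple[str, ...] = ("Q_mean", "recruitment", "flexibility"),
    control: str | None = "age",
) -> pd.DataFrame:
    """Pairwise Pearson (and age-partialled) correlations among metrics."""
    rows = []
    for i, a in enumerate(columns):
        for b in columns[i + 1 :]:
            rec = pearson_with_ci(cohort[a].to_numpy(), cohort[b].to_numpy())
            row = {"x": a, "y": b, **rec}
            if control is not None:
                prec = partial_correlation(
                    cohort[a].to_numpy(), cohort[b].to_numpy(), cohort[control].to_numpy()
                )
                row.update(
                    {
                        "partial_r": prec["r"],
                        "partial_p": prec["p"],
                        "partial_ci_low": prec["ci_low"],
                        "partial_ci_high": prec["ci_high"],
                    }
                )
            rows.append(row)
    return pd.DataFrame(rows)


def change_slopes(
    cognition: pd.DataFrame,
    domain: str,
    times: dict[int, float] | None = None,
    adjust_retest: bool = True,
    shrink: bool = False,
) -> pd.Series:
    """Per-subject OLS slope of a cognitive score on time in years.

    ``cognition`` is long-format with columns ``subject``, ``occasion`` and
    the domain score.  With ``adjust_retest`` the cohort-level retest
    effect (a jump common to all follow-ups relative to baseline) is
    estimated by pooled OLS on time + retest and removed from the scores
    before the per-subject fits.  With ``shrink`` the raw slopes are pulled
    toward the cohort mean with empirical-Bayes weights (slopes measured
    with more within-subject noise shrink more).  Subjects with fewer than
    3 occasions get NaN.
    """
    times = times or DEFAULT_TIMES
    df = cognition.dropna(subset=[domain]).copy()
    df["time"] = df["occasion"].map(times)
    if df["time"].isna().any():
        bad = sorted(df.loc[df["time"].isna(), "occasion"].unique())
        raise ValueError(f"no time mapping for occasions {bad}")
    score = df[domain].astype(float).to_numpy()
    if adjust_retest:
        X = sm.add_constant(
            np.column_stack([df["time"].to_numpy(), retest_indicator(df["occasion"].to_numpy())])
        )
        fit = sm.OLS(score, X).fit()
        score = score - fit.params[2] * retest_indicator(df["occasion"].to_numpy())
    df = df.assign(_score=score)

    slopes, se2 = {}, {}
    for subject, sub in df.groupby("subject", sort=True):
        if len(sub) < 3:
            slopes[subject] = np.nan
            continue
        t = sub["time"].to_numpy()
        y = sub["_score"].to_numpy()
        X = sm.add_constant(t)
        fit = sm.OLS(y, X).fit()
        slopes[subject] = float(fit.params[1])
        se2[subject] = float(fit.bse[1] ** 2) if len(sub) > 2 else np.nan
    out = pd.Series(slopes, name=f"{domain}_slope")
    if shrink:
        valid = out.dropna()
        mean_slope = valid.mean()
        sampling = pd.Series(se2).reindex(valid.index)
        tau2 = max(0.0, valid.var(ddof=1) - sampling.mean())
        w = tau2 / (tau2 + sampling)
        out.loc[valid.index] = mean_slope + w * (valid - mean_slope)
    return out


def brain_cognition_correlation(
    cohort: pd.DataFrame,
    flexibility_cols: list[str],
    slope_cols: list[str],
    control: str | None = "age",
) -> pd.DataFrame:
    """Change-change association: cognitive slopes vs. flexibility measures."""
    rows = []
    for f in flexibility_cols:
        for s in slope_cols:
            sub = cohort.dropna(subset=[f, s] + ([control] if control else []))
            rec = pearson_with_ci(sub[f].to_numpy(), sub[s].to_numpy())
            row = {"flexibility": f, "slope": s, **rec}
            if control is not None:
                prec = partial_correlation(
                    sub[f].to_numpy(), sub[s].to_numpy(), sub[control].to_numpy()
                )
                row.update({"partial_r": prec["r"], "partial_p": prec["p"]})
            rows.append(row)
    return pd.DataFrame(rows)
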