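"""Statistical models linking energetic metrics to intrinsic traits.

Covers the analysis layer that sits on merged per-individual-season
records: seasonal allometric scaling of DEE/ODBA with body weight
(log-log ordinary least squares with season-specific exponents and
intercepts), intrinsic-driver regressions with bidirectional stepwise AIC
selection, the ODBA-DEE covariation test, the OD = ODBA/DEE activity
ratio, group contrasts (t-test for means, F-ratio test for variances) and
the regressions of next-season condition residuals on the energetic
metrics.

Weight and age are alternative covariate sets, never co-fitted, because
they are collinear within season.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ScalingFit",
    "fit_seasonal_allometry",
    "fit_driver_models",
    "stepwise_aic",
    "covariation_test",
    "od_ratio",
    "attach_od",
    "group_contrasts",
    "regress_od_on_next_bci",
]

Metric = Literal["dee", "odba"]

#: OD values are ~1e-4 g per kJ/day; reported x1e4 for readability
OD_REPORT_SCALE = 1e4


@dataclass
class ScalingFit:
    """Season-specific allometric exponents from the log-log fit."""

    metric: str
    exponents: pd.DataFrame      # index season: beta, se, p, intercept
    pooled_exponent: float
    pooled_se: float
    pooled_p: float
    pooled_intercept: float
    r2_pooled: float
    n: int
    seasonal_result: object = None
    pooled_result: object = None


def _validate_positive(records: pd.DataFrame, cols: Sequence[str]) -> None:
    for col in cols:
        bad = records.index[records[col] <= 0].tolist()
        if bad:
            raise ValueError(f"non-positive {col} in records {bad}")


def fit_seasonal_allometry(records: pd.DataFrame, metric: str) -> ScalingFit:
    """Log-log OLS of a metric on body weight with per-season slopes.

    Fits ``ln(metric) ~ ln(W) * season`` (free intercepts and exponents per
    season) plus the pooled single-exponent fit ``ln(metric) ~ ln(W)``.
    Requires >= 3 records per season with positive metric and weight.
    """
    df = records.dropna(subset=[metric, "weight_kg"]).copy()
    _validate_positive(df, [metric, "weight_kg"])
    counts = df.groupby("season").size()
    if (counts < 3).any():
        raise ValueError(f"need >=3 records per season; got {dict(counts)}")
    df["ln_metric"] = np.log(df[metric])
    df["ln_w"] = np.log(df["weight_kg"])

    seasonal = smf.ols("ln_metric ~ ln_w * C(season)", data=df).fit()
    pooled = smf.ols("ln_metric ~ ln_w", data=df).fit()

    seasons = sorted(df["season"].unique())
    base = seasons[0]
    rows = []
    for s in seasons:
        if s == base:
            beta = seasonal.params["ln_w"]
            # SE of the baseline slope itself
            se = seasonal.bse["ln_w"]
            p = seasonal.pvalues["ln_w"]
            intercept = seasonal.params["Intercept"]
        else:
            term = f"ln_w:C(season)[T.{s}]"
            contrast = np.zeros(len(seasonal.params))
            names = list(seasonal.params.index)
            contrast[names.index("ln_w")] = 1.0
            contrast[names.index(term)] = 1.0
            tt = seasonal.t_test(contrast)
            beta = float(np.atleast_1d(tt.effect)[0])
            se = float(np.atleast_1d(tt.sd).ravel()[0])
            p = float(np.atleast_1d(tt.pvalue).ravel()[0])
            intercept = (
                seasonal.params["Intercept"]
                + seasonal.params[f"C(season)[T.{s}]"]
            )
        rows.append(
            {"season": s, "beta": beta, "se": se, "p": p, "intercept": intercept}
        )
    exponents = pd.DataFrame(rows).set_index("season")
    return ScalingFit(
        metric=metric,
        exponents=exponents,
        pooled_exponent=float(pooled.params["ln_w"]),
        pooled_se=float(pooled.bse["ln_w"]),
        pooled_p=float(pooled.pvalues["ln_w"]),
        pooled_intercept=float(pooled.params["Intercept"]),
        r2_pooled=float(pooled.rsquared),
        n=len(df),
        seasonal_result=seasonal,
        pooled_result=pooled,
    )


def _hierarchical_candidates(terms: Sequence[str]) -> list[frozenset]:
    """All term subsets respecting marginality (interaction => both mains)."""
    interactions = [t for t in terms if ":" in t]
    candidates = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            s = frozenset(combo)
            ok = all(
                set(t.split(":")).issubset({m for c in s for m in c.split(":")})
                and all(m in s for m in t.split(":"))
                for t in s
                if ":" in t
            )
            if ok:
                candidates.append(s)
    del interactions
    return candidates


def stepwise_aic(
    data: pd.DataFrame,
    response: str,
    full_terms: Sequence[str],
    trace: bool = False,
) -> object:
    """Bidirectional stepwise AIC selection from the full OLS model.

    Starts at the full model and, at each step, tries dropping any current
    term and adding back any absent term (respecting marginality: an
    interaction is only present with both main effects, and a main effect
    is only dropped after its interactions).  Stops when no single move
    lowers AIC.  Returns the fitted selected model with ``selected_terms``
    attached.
    """

    def formula(terms):
        rhs = " + ".join(sorted(terms)) if terms else "1"
        return f"{response} ~ {rhs}"

    def admissible(terms: frozenset) -> bool:
        for t in terms:
            if ":" in t and not all(m in terms for m in t.split(":")):
                return False
        return True

    def fit(terms):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.ols(formula(terms), data=data).fit()
        if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
            raise ValueError("perfect collinearity in design matrix")
        return res

    current = frozenset(full_terms)
    if not admissible(current):
        raise ValueError("full model violates marginality")
    best = fit(current)
    best_aic = best.aic
    improved = True
    while improved:
        improved = False
        moves = []
        for t in current:
            cand = current - {t}
            if admissible(cand):
                moves.append(cand)
        for t in set(full_terms) - current:
            cand = current | {t}
            if admissible(cand):
                moves.append(cand)
        for cand in moves:
            res = fit(cand)
            if res.aic < best_aic - 1e-9:
                best, best_aic, current = res, res.aic, cand
                improved = True
        if trace:
            print(f"AIC {best_aic:.2f}: {sorted(current)}")
    # post-hoc audit: no retained term's removal may lower AIC
    for t in current:
        cand = current - {t}
        if admissible(cand) and fit(cand).aic < best_aic - 1e-9:
            raise AssertionError(
                f"stepwise audit failed: dropping {t} lowers AIC"
            )
    best.selected_terms = sorted(current)
    return best


def fit_driver_models(
    records: pd.DataFrame,
    metric: str,
    covariate_set: Literal["weight", "age"] = "weight",
) -> object:
    """Intrinsic-driver model for a metric with stepwise AIC selection.

    Full model: ``metric ~ covariate * season + sex`` where covariate is
    body weight or age (never both, they are collinear within season).
    """
    covariate = {"weight": "weight_kg", "age": "age"}[covariate_set]
    df = records.dropna(subset=[metric, covariate, "season", "sex"]).copy()
    full = [covariate, "C(season)", f"{covariate}:C(season)", "C(sex)"]
    return stepwise_aic(df, metric, full)


@dataclass
class CovariationResult:
    """DEE-on-ODBA regressions, raw and weight-adjusted, plus per-season."""

    overall: object
    weight_adjusted: object
    by_season: dict = field(default_factory=dict)

    def summary(self) -> dict:
        def row(res):
            return {
                "slope": float(res.params.get("odba", np.nan)),
                "p": float(res.pvalues.get("odba", np.nan)),
                "r2": float(res.rsquared),
                "n": int(res.nobs),
            }

        out = {
            "overall": row(self.overall),
            "weight_adjusted": row(self.weight_adjusted),
        }
        out["by_season"] = {s: row(r) for s, r in self.by_season.items()}
        return out


def covariation_test(records: pd.DataFrame) -> CovariationResult:
    """Regress DEE_i on ODBA_i, with and without weight, and per season."""
    df = records.dropna(subset=["dee", "odba"]).copy()
    if len(df) < 3:
        raise ValueError("need >=3 overlapping records")
    overall = smf.ols("dee ~ odba", data=df).fit()
    adjusted = smf.ols("dee ~ odba + weight_kg", data=df).fit()
    by_season = {}
    for s, sub in df.groupby("season"):
        if len(sub) >= 3:
            by_season[s] = smf.ols("dee ~ odba", data=sub).fit()
    return CovariationResult(overall, adjusted, by_season)


def od_ratio(odba_i: float, dee_i: float) -> float:
    """OD = ODBA_i / DEE_i, the fraction of throughput spent on movement."""
    if dee_i <= 0:
        raise ValueError("DEE must be > 0")
    if odba_i is None or np.isnan(odba_i):
        raise ValueError("ODBA missing; OD undefined")
    return odba_i / dee_i


def attach_od(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``od`` where both metrics are present; NaN elsewhere."""
    out = records.copy()
    both = out["odba"].notna() & out["dee"].notna() & (out["dee"] > 0)
    out["od"] = np.where(both, out["odba"] / out["dee"], np.nan)
    return out


@dataclass
class GroupContrast:
    grouping: str
    groups: dict
    t_stat: float
    t_p: float
    f_stat: float
    f_p: float
    warnings: list = field(default_factory=list)


def group_contrasts(
    records: pd.DataFrame, value: str, grouping: str
) -> GroupContrast:
    """Two-group contrast: Student's t for means, F-ratio for variances.

    Also reports per-group mean, SD and the fold-range (max/min) used to
    describe inter-individual spread.
    """
    df = records.dropna(subset=[value, grouping])
    levels = sorted(df[grouping].unique())
    if len(levels) != 2:
        raise ValueError(f"grouping {grouping!r} must have 2 levels; got {levels}")
    a = df.loc[df[grouping] == levels[0], value].to_numpy(float)
    b = df.loc[df[grouping] == levels[1], value].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 records per group")
    notes = []
    if np.var(a, ddof=1) == 0 or np.var(b, ddof=1) == 0:
        raise ValueError("zero variance in a group: F-test undefined")

    t_stat, t_p = scipy.stats.ttest_ind(a, b, equal_var=True)
    f_stat = np.var(a, ddof=1) / np.var(b, ddof=1)
    dfn, dfd = len(a) - 1, len(b) - 1
    # two-sided variance-ratio test
    cdf = scipy.stats.f.cdf(f_stat, dfn, dfd)
    f_p = 2 * min(cdf, 1 - cdf)

    def describe(x):
        return {
            "n": len(x),
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)),
            "fold_range": float(np.max(x) / np.min(x)) if np.min(x) > 0 else np.inf,
        }

    return GroupContrast(
        grouping=grouping,
        groups={levels[0]: describe(a), levels[1]: describe(b)},
        t_stat=float(t_stat),
        t_p=float(t_p),
        f_stat=float(f_stat),
        f_p=float(f_p),
        warnings=notes,
    )


@dataclass
class NextBciResult:
    """Next-season condition residual regressed on each energetic metric."""

    fits: dict                       # predictor -> OLS results
    autocorrelation: Optional[object]

    def summary(self) -> dict:
        out = {}
        for name, res in self.fits.items():
            out[name] = {
                "slope": float(np.asarray(res.params)[1]),
                "se": float(np.asarray(res.bse)[1]),
                "p": float(np.asarray(res.pvalues)[1]),
                "r2": float(res.rsquared),
                "n": int(res.nobs),
            }
        if self.autocorrelation is not None:
            res = self.autocorrelation
            out["bci_res_lag"] = {
                "slope": float(np.asarray(res.params)[1]),
                "p": float(np.asarray(res.pvalues)[1]),
                "r2": float(res.rsquared),
                "n": int(res.nobs),
            }
        return out


def regress_od_on_next_bci(records: pd.DataFrame) -> NextBciResult:
    """Linear fits of next-season BCI_res on ODBA_i, DEE_i and OD_i.

    Also fits the season-to-season BCI_res autocorrelation (this-season
    residual predicting next-season residual) when ``bci_res`` is present.
    """
    fits = {}
    for predictor in ("odba", "dee", "od"):
        sub = records.dropna(subset=[predictor, "next_bci_res"])
        if len(sub) >= 3:
            y = sub["next_bci_res"].to_numpy(float)
            x = sm.add_constant(sub[predictor].to_numpy(float))
            fits[predictor] = sm.OLS(y, x).fit()
    if not fits:
        raise ValueError("need >=3 linked records for at least one predictor")
    auto = None
    if "bci_res" in records:
        sub = records.dropna(subset=["bci_res", "next_bci_res"])
        if len(sub) >= 3:
            y = sub["next_bci_res"].to_numpy(float)
            x = sm.add_constant(sub["bci_res"].to_numpy(float))
            auto = sm.OLS(y, x).fit()
    return NextBciResult(fits=fits, autocorrelation=auto)
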