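"""Body condition index (BCI) and its long-term additive-smooth adjustment.

BCI is the log ratio ln(W)/ln(BL): body weight W in kg over body length BL
in the configured length unit (millimetres by default, matching the 5-mm
recording precision).  Because badger weight cycles strongly with season
and changes with age and sex, raw BCI is adjusted against the long-term
capture archive with an additive smooth model

    BCI ~ s(age) + s(day_of_year) + sex,

and the residual (BCI_res) is the condition currency carried into the
survival analyses.  "Next-season" links follow the trapping calendar:
spring (May) -> summer (September) -> autumn (November) -> next-year
spring; there is no winter trapping.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.gam.api import BSplines, GLMGam

__all__ = [
    "SEASONS",
    "SEASON_MONTH",
    "bci",
    "season_from_date",
    "next_season",
    "BciAdjustment",
    "fit_bci_adjustment",
    "attach_bci",
    "next_season_residuals",
]

SEASONS = ("spring", "summer", "autumn")

#: trapping months: May, September, November
SEASON_MONTH = {"spring": 5, "summer": 9, "autumn": 11}
_MONTH_SEASON = {5: "spring", 9: "summer", 11: "autumn"}


def bci(weight_kg: float, body_length: float) -> float:
    """Body condition index ln(W)/ln(BL).

    ``body_length`` must exceed one length unit so the denominator is a
    positive log; the absolute BCI value depends on the length unit used
    (mm here), which is why downstream analyses work on residuals.
    """
    if weight_kg <= 0:
        raise ValueError("weight must be > 0")
    if body_length <= 1:
        raise ValueError("body length must exceed 1 unit (log ratio undefined)")
    return math.log(weight_kg) / math.log(body_length)


def season_from_date(date) -> str:
    """Map a capture date to its trapping season (pure, idempotent).

    Captures in the trapping months map directly; captures in other months
    map to the nearest trapping month (with a warning), since the study
    design only trains seasons at the three trapping sessions.
    """
    month = pd.Timestamp(date).month
    if month in _MONTH_SEASON:
        return _MONTH_SEASON[month]
    warnings.warn(
        f"month {month} is not a trapping month; mapping to nearest season",
        stacklevel=2,
    )
    # distance on the circular month scale to the three trapping months
    best = min(
        SEASON_MONTH,
        key=lambda s: min(
            abs(month - SEASON_MONTH[s]), 12 - abs(month - SEASON_MONTH[s])
        ),
    )
    return best


def next_season(season: str, year: int) -> tuple[str, int]:
    """Following trapping season; autumn wraps to next-year spring."""
    idx = SEASONS.index(season)
    if idx == len(SEASONS) - 1:
        return SEASONS[0], year + 1
    return SEASONS[idx + 1], year


@dataclass
class BciAdjustment:
    """Fitted additive-smooth BCI adjustment with a residual predictor."""

    result: object             # statsmodels GAM results
    smoother: BSplines
    sex_levels: tuple
    df: int
    alpha: tuple

    def predict(self, captures: pd.DataFrame) -> np.ndarray:
        """Expected BCI given age, day-of-year and sex."""
        exog = _sex_design(captures["sex"], self.sex_levels)
        x_spline = np.column_stack(
            [captures["age"].to_numpy(float), _day_of_year(captures)]
        )
        # transform=True rebuilds the spline basis for the new covariates
        return np.asarray(
            self.result.predict(exog, x_spline, transform=True)
        )

    def residuals(self, captures: pd.DataFrame) -> np.ndarray:
        """BCI_res = observed BCI - model expectation."""
        return captures["bci"].to_numpy(float) - self.predict(captures)


def _day_of_year(captures: pd.DataFrame) -> np.ndarray:
    return pd.DatetimeIndex(captures["date"]).dayofyear.to_numpy(float)


def _sex_design(sex: pd.Series, levels: tuple) -> np.ndarray:
    # intercept + treatment-coded sex
    cols = [np.ones(len(sex))]
    for level in levels[1:]:
        cols.append((sex.to_numpy() == level).astype(float))
    return np.column_stack(cols)


def fit_bci_adjustment(
    captures: pd.DataFrame,
    df: int = 10,
    alpha: Optional[float] = None,
    select_alpha: bool = True,
    min_per_group: int = 5,
) -> BciAdjustment:
    """Fit the long-term additive-smooth BCI adjustment.

    Parameters
    ----------
    captures : DataFrame
        Needs columns ``bci``, ``age``, ``date``, ``sex``.
    df : int
        Basis size of each penalized cubic spline.
    alpha : float, optional
        Fixed smoothing penalty for both smooths; when None and
        ``select_alpha`` is true, chosen by generalized cross-validation.
    """
    required = {"bci", "age", "date", "sex"}
    if not required.issubset(captures.columns):
        raise ValueError(f"captures must have columns {sorted(required)}")
    counts = captures.groupby("sex").size()
    if (counts < min_per_group).any():
        raise ValueError(
            f"need at least {min_per_group} records per sex; got {dict(counts)}"
        )

    age = captures["age"].to_numpy(float)
    doy = _day_of_year(captures)
    x_spline = np.column_stack([age, doy])
    smoother = BSplines(x_spline, df=[df, df], degree=[3, 3])

    sex_levels = tuple(sorted(captures["sex"].unique()))
    exog = _sex_design(captures["sex"], sex_levels)
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("rank-deficient parametric design (sex column)")

    y = captures["bci"].to_numpy(float)
    model = GLMGam(y, exog=exog, smoother=smoother)
    if alpha is None and select_alpha:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit()          # seeds the scale used by the GCV search
            alphas = model.select_penweight()[0]
        model = GLMGam(y, exog=exog, smoother=smoother, alpha=alphas)
    elif alpha is not None:
        alphas = np.full(2, float(alpha))
        model = GLMGam(y, exog=exog, smoother=smoother, alpha=alphas)
    else:
        alphas = np.zeros(2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit()
    return BciAdjustment(
        result=result,
        smoother=smoother,
        sex_levels=sex_levels,
        df=df,
        alpha=tuple(np.atleast_1d(alphas)),
    )


def attach_bci(captures: pd.DataFrame, length_unit: str = "mm") -> pd.DataFrame:
    """Add ``bci`` (and record the length unit) to a capture table."""
    out = captures.copy()
    out["bci"] = [
        bci(w, bl) for w, bl in zip(out["weight_kg"], out["body_length_mm"])
    ]
    out.attrs["bci_length_unit"] = length_unit
    return out


def next_season_residuals(
    captures: pd.DataFrame, model: BciAdjustment
) -> pd.DataFrame:
    """Per capture, the individual's BCI_res at the *following* season.

    Returns the input with columns ``bci_res`` (this capture) and
    ``next_bci_res`` (NaN when the individual was not recaptured the
    following season — missingness is a data outcome, not an error).
    """
    out = captures.copy()
    out["bci_res"] = model.residuals(out)
    key = {
        (row.individual_id, row.season, row.year): row.bci_res
        for row in out.itertuples()
    }
    nxt = []
    for row in out.itertuples():
        s, y = next_season(row.season, row.year)
        nxt.append(key.get((row.individual_id, s, y), np.nan))
    out["next_bci_res"] = nxt
    return out
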