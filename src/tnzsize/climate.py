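"""Annual minimum-temperature aggregation and site-level linear models.

AnnMinTemp is the arithmetic mean of a site's daily minimum temperatures
within a calendar year, guarded by a completeness threshold.  The linear
trend models regress AnnMinTemp on geography or year; the effect models
regress the TNZ parameters (ULT, LLT, TNZ breadth) on AnnMinTemp, reported
on both the natural (per degC) and standardised predictor scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError, FitError

__all__ = [
    "LinearFit",
    "annual_min_temp",
    "spatial_ann_min_temp",
    "site_climate_table",
    "fit_lm",
    "tnz_effect_models",
]


@dataclass
class LinearFit:
    intercept: float
    slope: float
    slope_se: float
    t_statistic: float
    p_value: float
    r_squared: float
    n: int


def _year_values(series: pd.DataFrame, site: str, year: int) -> np.ndarray:
    df = series[series["site"] == site]
    years = pd.to_datetime(df["date"]).dt.year
    return df.loc[years == year, "tmin_C"].to_numpy(dtype=float)


def annual_min_temp(
    series: pd.DataFrame, site: str, year: int, min_days: int = 300
) -> float:
    """Mean daily minimum temperature of ``site`` within calendar ``year``.

    Requires at least ``min_days`` daily values so that a patchy year cannot
    silently bias the mean.
    """
    vals = _year_values(series, site, year)
    if len(vals) < min_days:
        raise DataError(
            f"site {site}, year {year}: only {len(vals)} daily values "
            f"(completeness guard requires >= {min_days})"
        )
    return float(vals.mean())


def spatial_ann_min_temp(
    series: pd.DataFrame, site: str, years: tuple[int, int] = (2022, 2023),
    min_days: int = 300,
) -> float:
    """Site-level AnnMinTemp for the spatial analysis: mean of two annual values."""
    annual = []
    for y in years:
        try:
            annual.append(annual_min_temp(series, site, y, min_days=min_days))
        except DataError as exc:
            raise DataError(f"spatial AnnMinTemp for site {site}: {exc}") from exc
    return float(np.mean(annual))


def site_climate_table(
    series: pd.DataFrame, min_days: int = 300
) -> pd.DataFrame:
    """One AnnMinTemp row per site-year present in the daily series."""
    df = series.copy()
    df["year"] = pd.to_datetime(df["date"]).dt.year
    rows = []
    for (site, year), grp in df.groupby(["site", "year"], sort=True):
        if len(grp) < min_days:
            continue
        rows.append({"site": site, "year": int(year),
                     "ann_min_temp": float(grp["tmin_C"].mean())})
    return pd.DataFrame(rows)


def fit_lm(x, y) -> LinearFit:
    """Simple-linear-regression fit with a two-sided t test on the slope."""
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise FitError(f"need n >= 3 observations, got {len(x)}")
    if np.ptp(x) == 0:
        raise FitError("predictor is constant (rank-deficient design)")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return LinearFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        t_statistic=float(res.tvalues[1]),
        p_value=float(res.pvalues[1]),
        r_squared=float(res.rsquared),
        n=int(res.nobs),
    )


def tnz_effect_models(
    tnz_estimates: pd.DataFrame, site_climate: pd.DataFrame
) -> dict[str, dict[str, LinearFit]]:
    """ULT, LLT and TNZ breadth each regressed on site-level AnnMinTemp.

    ``tnz_estimates`` needs columns site, llt_C, ult_C, tnz_b_C;
    ``site_climate`` needs site and ann_min_temp (one row per site).
    Returns ``{response: {"natural": fit, "standardized": fit}}`` — natural
    slopes are in degC per degC of AnnMinTemp.
    """
    merged = tnz_estimates.merge(site_climate[["site", "ann_min_temp"]], on="site")
    if len(merged) < 3:
        raise DataError(
            f"join of TNZ estimates and climate leaves {len(merged)} sites; need >= 3"
        )
    x = merged["ann_min_temp"].to_numpy(dtype=float)
    if np.std(x, ddof=1) == 0:
        raise FitError("AnnMinTemp is constant across sites")
    xs = (x - x.mean()) / x.std(ddof=1)
    out: dict[str, dict[str, LinearFit]] = {}
    for label, col in (("ult", "ult_C"), ("llt", "llt_C"), ("tnz_b", "tnz_b_C")):
        y = merged[col].to_numpy(dtype=float)
        out[label] = {
            "natural": fit_lm(x, y),
            "standardized": fit_lm(xs, y),
        }
    return out
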