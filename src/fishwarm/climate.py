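"""Air-to-water temperature transfer and annual aggregation.

Stream water temperature is estimated from monthly maximum air temperature
with a logistic transfer curve bounded above by 32 °C,

    T_water = 32 / (1 + exp(-0.13 * T_air + 1.94)),

then summarised per site-year as ``t_avg`` (mean of the converted monthly
values) and ``t_max`` (their maximum).  The conversion is applied month-wise
*before* aggregation: the transfer is nonlinear, so converting an annual mean
would give a different (wrong) answer.

The warming trend across sites is measured with a linear mixed model,
``water temperature ~ year + (1 | site)``, reported per year; multiply by 10
for the conventional per-decade figure.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .mixedmodels import MixedModelFit, ModelSpec, fit_lmm

logger = logging.getLogger(__name__)

#: Upper bound of the logistic air->water transfer (°C). Water temperature
#: approaches, but never reaches, this value as air temperature grows.
TRANSFER_CEILING = 32.0
TRANSFER_SLOPE = 0.13
TRANSFER_OFFSET = 1.94


def air_to_water(tmax_air):
    """Convert maximum air temperature (°C) to water temperature (°C).

    Accepts a scalar or array; output is strictly inside (0, 32) and
    strictly increasing in the input.

    Raises
    ------
    ValueError
        If any input is NaN or infinite.
    """
    arr = np.asarray(tmax_air, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("air temperature must be finite")
    out = TRANSFER_CEILING / (1.0 + np.exp(-TRANSFER_SLOPE * arr + TRANSFER_OFFSET))
    if np.isscalar(tmax_air) or arr.ndim == 0:
        return float(out)
    return out


def water_to_air(t_water):
    """Analytic inverse of :func:`air_to_water`.

    Defined for water temperatures strictly inside (0, 32).
    """
    arr = np.asarray(t_water, dtype=float)
    if not np.all((arr > 0.0) & (arr < TRANSFER_CEILING)):
        raise ValueError("water temperature must lie strictly in (0, 32)")
    out = (TRANSFER_OFFSET + np.log(arr / (TRANSFER_CEILING - arr))) / TRANSFER_SLOPE
    if np.isscalar(t_water) or arr.ndim == 0:
        return float(out)
    return out


def aggregate_annual(climate: pd.DataFrame, min_months: int = 12) -> pd.DataFrame:
    """Aggregate monthly maximum air temperatures to annual water variables.

    Parameters
    ----------
    climate
        Columns ``site_id, year, month, tmax_air_c`` (one row per
        site-year-month).
    min_months
        Minimum number of months required for a site-year to be reported
        (default 12, i.e. complete coverage; relax for gappy records).

    Returns
    -------
    DataFrame with columns ``site_id, year, t_avg, t_max, n_months``.
    """
    required = {"site_id", "year", "month", "tmax_air_c"}
    missing = required - set(climate.columns)
    if missing:
        raise ValueError(f"climate table missing columns: {sorted(missing)}")
    if len(climate) == 0:
        logger.warning("aggregate_annual: empty climate table")
        return pd.DataFrame(columns=["site_id", "year", "t_avg", "t_max", "n_months"])

    df = climate[["site_id", "year", "month"]].copy()
    df["t_water"] = air_to_water(climate["tmax_air_c"].to_numpy())
    grouped = df.groupby(["site_id", "year"], sort=True)["t_water"].agg(
        t_avg="mean", t_max="max", n_months="count"
    )
    out = grouped.reset_index()
    incomplete = out["n_months"] < min_months
    if incomplete.any():
        logger.info(
            "aggregate_annual: dropping %d site-years with < %d months",
            int(incomplete.sum()),
            min_months,
        )
        out = out[~incomplete].reset_index(drop=True)
    return out


def warming_trend(
    annual: pd.DataFrame,
    variable: str = "t_avg",
    reml: bool = False,
) -> MixedModelFit:
    """Fit the warming trend ``variable ~ year + (1 | site_id)``.

    The ``year`` coefficient is in °C per year; multiply estimate and SE by
    10 to report °C per decade.  With a single site there is no
    between-site variance to estimate and the fit falls back to ordinary
    least squares (noted in the fit's warnings).
    """
    if variable not in ("t_avg", "t_max"):
        raise ValueError("variable must be 't_avg' or 't_max'")
    data = annual[["site_id", "year", variable]].dropna()
    if data["year"].nunique() < 2:
        raise ValueError("warming trend needs at least 2 distinct years")
    spec = ModelSpec(
        response=variable,
        fixed_terms=["year"],
        grouping="site_id",
        family="gaussian",
    )
    return fit_lmm(data, spec, reml=reml)


def decadal_trend(fit: MixedModelFit) -> tuple[float, float]:
    """Return (estimate, SE) of the year coefficient scaled to °C per decade."""
    row = fit.coefficients.set_index("term").loc["year"]
    return 10.0 * float(row["estimate"]), 10.0 * float(row["se"])
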