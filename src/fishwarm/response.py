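"""Per-population temperature responses.

Each population (one species within one community time series) is reduced to
a single response: the slope of the least-squares regression of z-scored
abundance on same-year water temperature over the survey years, and its sign
as a binary outcome (1 = abundance increases with warming, 0 = decreases).
Abundance is standardized within each population (mean 0, SD 1, ddof = 1) so
that heterogeneous units (counts, CPUE, densities) are comparable; a slope
of exactly zero — possible only through degenerate numerics — is classified
as 0 and counted.

`assemble_response_table` joins the classified responses with range
positions, site elevation, species traits and series duration into the
modeling table consumed by the mixed models.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """Raised when a constant series cannot be standardized."""


def standardize_abundance(values) -> np.ndarray:
    """z-score a population's abundance series (mean 0, SD 1, ddof=1)."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        raise ValueError("standardization needs at least 2 years")
    sd = arr.std(ddof=1)
    if sd == 0.0:
        raise ZeroVarianceError("constant abundance series cannot be standardized")
    return (arr - arr.mean()) / sd


def classify_response(standardized, temperature) -> tuple[float, int]:
    """Least-squares slope of z-scored abundance on temperature, and its sign.

    Returns ``(slope, binary)`` with ``binary = 1`` iff ``slope > 0``.
    The regression runs over survey years only (the paired values given).
    """
    z = np.asarray(standardized, dtype=float)
    t = np.asarray(temperature, dtype=float)
    if len(z) != len(t) or len(z) < 2:
        raise ValueError("need >= 2 paired years")
    tc = t - t.mean()
    stt = float(tc @ tc)
    if stt == 0.0:
        raise ValueError("constant temperature across surveys")
    slope = float(tc @ (z - z.mean())) / stt
    return slope, int(slope > 0)


def assemble_response_table(
    surveys: pd.DataFrame,
    annual_water: pd.DataFrame,
    positions: pd.DataFrame,
    sites: pd.DataFrame,
    traits: pd.DataFrame,
    variable: str = "t_avg",
    min_duration: int = 10,
) -> pd.DataFrame:
    """Build the modeling table: one row per population surviving all joins.

    Parameters
    ----------
    surveys
        Filtered, zero-filled survey records.
    annual_water
        Output of :func:`fishwarm.climate.aggregate_annual`.
    positions
        Output of :func:`fishwarm.ranges.assign_positions`.
    sites
        ``site_id, elevation_m``.
    traits
        ``species, max_length, trophic_level, migratory, native_hemisphere``.
    variable
        ``"t_avg"`` or ``"t_max"`` — the temperature regressor.
    min_duration
        Minimum inclusive series span (years).

    Returns
    -------
    DataFrame with one row per (time_series_id, species):
    ``response_binary, slope, temperature_variable, duration, position,
    clamped, hemisphere, elevation, max_length, trophic_level, migratory,
    range_size_km``.  Exclusion tallies are attached as
    ``df.attrs["exclusions"]`` and logged.
    """
    if variable not in ("t_avg", "t_max"):
        raise ValueError("variable must be 't_avg' or 't_max'")
    excl: dict[str, int] = {}

    spans = surveys.groupby("time_series_id")["year"].agg(lambda y: y.max() - y.min() + 1)
    keep_series = spans.index[spans >= min_duration]
    df = surveys[surveys["time_series_id"].isin(keep_series)].copy()
    excl["below_min_duration"] = int(
        surveys[["time_series_id", "species"]].drop_duplicates().shape[0]
        - df[["time_series_id", "species"]].drop_duplicates().shape[0]
    )

    n_pop = lambda d: d[["time_series_id", "species"]].drop_duplicates().shape[0]
    before = n_pop(df)
    df = df.merge(
        annual_water[["site_id", "year", variable]], on=["site_id", "year"], how="inner"
    )
    excl["missing_temperature"] = before - n_pop(df)

    # per-population sufficient statistics for the slope of z(A) on T
    df["_a2"] = df["abundance"] ** 2
    df["_t2"] = df[variable] ** 2
    df["_at"] = df["abundance"] * df[variable]
    agg = df.groupby(["time_series_id", "species"], sort=True).agg(
        n=("abundance", "size"),
        sum_a=("abundance", "sum"),
        sum_a2=("_a2", "sum"),
        sum_t=(variable, "sum"),
        sum_t2=("_t2", "sum"),
        sum_at=("_at", "sum"),
    )
    n = agg["n"].to_numpy(dtype=float)
    s_tt = agg["sum_t2"] - agg["sum_t"] ** 2 / n
    s_aa = agg["sum_a2"] - agg["sum_a"] ** 2 / n
    s_at = agg["sum_at"] - agg["sum_a"] * agg["sum_t"] / n
    sd_a = np.sqrt(np.maximum(s_aa, 0.0) / (n - 1))

    ok = (agg["n"] >= 2).to_numpy()
    excl["single_year"] = int((~ok).sum())
    const_t = ok & np.isclose(s_tt.to_numpy(), 0.0)
    excl["constant_temperature"] = int(const_t.sum())
    const_a = ok & ~const_t & np.isclose(sd_a, 0.0)
    excl["zero_variance_abundance"] = int(const_a.sum())
    keep = ok & ~const_t & ~const_a

    result = agg.loc[keep, ["n"]].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        result["slope"] = (s_at / s_tt / sd_a)[keep]
    result["response_binary"] = (result["slope"] > 0).astype(int)
    n_zero = int((result["slope"] == 0).sum())
    if n_zero:
        logger.info("classify: %d exact-zero slopes classified as 0", n_zero)
    result = result.reset_index()

    meta = df[["time_series_id", "site_id", "latitude"]].drop_duplicates("time_series_id")
    result = result.merge(meta, on="time_series_id", how="left")
    result = result.merge(spans.rename("duration"), left_on="time_series_id", right_index=True)

    before = len(result)
    result = result.merge(
        positions[["time_series_id", "species", "position", "clamped", "hemisphere",
                   "range_size_km"]],
        on=["time_series_id", "species"],
        how="inner",
    )
    excl["missing_range_position"] = before - len(result)

    before = len(result)
    result = result.merge(sites[["site_id", "elevation_m"]], on="site_id", how="inner")
    result = result.merge(
        traits[["species", "max_length", "trophic_level", "migratory"]].dropna(
            subset=["max_length", "trophic_level"]
        ),
        on="species",
        how="inner",
    )
    excl["missing_elevation_or_traits"] = before - len(result)

    out = result.rename(columns={"elevation_m": "elevation"})[
        [
            "time_series_id",
            "species",
            "response_binary",
            "slope",
            "duration",
            "position",
            "clamped",
            "hemisphere",
            "elevation",
            "max_length",
            "trophic_level",
            "migratory",
            "range_size_km",
        ]
    ].copy()
    out["temperature_variable"] = variable
    out.attrs["exclusions"] = excl
    logger.info("assemble_response_table(%s): %d populations, exclusions %s",
                variable, len(out), excl)
    return out
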