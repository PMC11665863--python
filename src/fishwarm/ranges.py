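"""Species latitudinal range limits and within-range position.

Range limits per species come from occurrence latitudes after trimming the
most extreme 1% at each tail (guarding against misidentified or mis-entered
points).  Limits are expressed on absolute latitude, so "poleward" is always
the larger value in either hemisphere.  A population's position in its
species' range is

    position = (|observed latitude| - equatorward limit)
               / (poleward limit - equatorward limit)

so 0 sits at the equatorward (trailing, warm) edge and 1 at the poleward
(leading, cool) edge.

Species whose occurrences span the equator are split into northern and
southern components, the equator acting as the equatorward limit of each;
species annotated as native to one hemisphere keep only occurrences from
that hemisphere (introduced-range records are ignored).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Kilometres per degree of latitude (meridian arc, spherical mean).
KM_PER_DEGREE_LATITUDE = 111.32


def _component_limits(abs_lat: np.ndarray, tail: float, method: str) -> tuple[float, float]:
    """Trimmed (equatorward, poleward) limits of one hemisphere component."""
    if method == "quantile":
        lo = float(np.quantile(abs_lat, tail))
        hi = float(np.quantile(abs_lat, 1.0 - tail))
    elif method == "drop":
        k = int(np.floor(tail * len(abs_lat)))
        srt = np.sort(abs_lat)
        kept = srt[k : len(srt) - k] if k > 0 else srt
        lo, hi = float(kept[0]), float(kept[-1])
    else:
        raise ValueError("method must be 'quantile' or 'drop'")
    return lo, hi


def trim_and_limit(
    occurrences: pd.DataFrame,
    native_hemisphere: pd.Series | dict | None = None,
    min_occurrences: int = 10,
    tail: float = 0.01,
    method: str = "quantile",
    min_width_deg: float = 1e-6,
) -> pd.DataFrame:
    """Derive per-species (per-hemisphere-component) range limits.

    Parameters
    ----------
    occurrences
        Columns ``species, latitude`` (``longitude`` ignored if present).
    native_hemisphere
        Optional per-species annotation ``{"north", "south", "both"}``;
        occurrences outside a species' native hemisphere are discarded
        before trimming.
    min_occurrences
        Species (components) with fewer points are excluded and logged.
    tail
        Fraction trimmed at each latitudinal tail (default 1%).
    method
        ``"quantile"``: limits are the interpolated ``tail`` and
        ``1 - tail`` percentiles.  ``"drop"``: remove ``floor(tail*n)``
        points from each tail, then take the min/max.
    min_width_deg
        Components narrower than this (degenerate ranges, e.g. all points
        at one latitude) are excluded.

    Returns
    -------
    DataFrame with columns ``species, hemisphere, equatorward_limit,
    poleward_limit, range_size_deg, range_size_km, n_occurrences``.
    """
    if native_hemisphere is not None and not isinstance(native_hemisphere, dict):
        native_hemisphere = dict(native_hemisphere)
    native_hemisphere = native_hemisphere or {}

    rows = []
    excluded: list[tuple[str, str]] = []
    for species, grp in occurrences.groupby("species", sort=True):
        lat = grp["latitude"].to_numpy(dtype=float)
        native = native_hemisphere.get(species, "both")
        if native == "north":
            lat = lat[lat >= 0.0]
        elif native == "south":
            lat = lat[lat <= 0.0]
        if len(lat) < min_occurrences:
            excluded.append((species, "too few occurrences"))
            continue

        spans_equator = lat.min() < 0.0 < lat.max()
        if spans_equator:
            components = [("north", lat[lat >= 0.0]), ("south", -lat[lat <= 0.0])]
        elif np.median(lat) < 0.0 or lat.max() <= 0.0:
            components = [("south", -lat)]
        else:
            components = [("north", lat)]

        for hemi, abs_lat in components:
            if len(abs_lat) < min_occurrences:
                excluded.append((species, f"too few {hemi} occurrences"))
                continue
            lo, hi = _component_limits(abs_lat, tail, method)
            if spans_equator:
                lo = 0.0  # the equator is the equatorward limit of each half
            width = hi - lo
            if width <= min_width_deg:
                excluded.append((species, f"degenerate {hemi} range"))
                continue
            rows.append(
                {
                    "species": species,
                    "hemisphere": hemi,
                    "equatorward_limit": lo,
                    "poleward_limit": hi,
                    "range_size_deg": width,
                    "range_size_km": width * KM_PER_DEGREE_LATITUDE,
                    "n_occurrences": int(len(abs_lat)),
                }
            )
    for species, reason in excluded:
        logger.info("trim_and_limit: excluded %s (%s)", species, reason)
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "hemisphere",
            "equatorward_limit",
            "poleward_limit",
            "range_size_deg",
            "range_size_km",
            "n_occurrences",
        ],
    )


def position_in_range(
    site_latitude: float,
    equatorward_limit: float,
    poleward_limit: float,
    clamp: bool = True,
) -> tuple[float, bool]:
    """Relative position of a site within a species range on absolute latitude.

    Returns ``(position, clamped)``.  Raw values can fall outside [0, 1]
    because tail-trimming narrows the limits relative to the true range; by
    default they are clamped to the unit interval with the flag set.  With
    ``clamp=False`` the raw value is returned (flag still marks excursions).
    """
    width = poleward_limit - equatorward_limit
    if width <= 0:
        raise ValueError("zero-width range: should have been excluded upstream")
    raw = (abs(site_latitude) - equatorward_limit) / width
    out_of_range = raw < 0.0 or raw > 1.0
    if clamp and out_of_range:
        return (0.0 if raw < 0.0 else 1.0), True
    return raw, out_of_range


def range_size_km(range_size_deg: float) -> float:
    """Latitudinal range extent in kilometres (111.32 km per degree)."""
    return range_size_deg * KM_PER_DEGREE_LATITUDE


def assign_positions(
    populations: pd.DataFrame,
    ranges: pd.DataFrame,
    clamp: bool = True,
) -> pd.DataFrame:
    """Attach range positions to population (series x species) rows.

    ``populations`` needs columns ``time_series_id, species, latitude``;
    the site's hemisphere (sign of latitude) selects the matching range
    component, so equator-spanning species resolve to the component that
    contains the site.  Populations whose species has no usable range
    component in the site's hemisphere are dropped (logged).

    Returns columns ``time_series_id, species, position, clamped,
    hemisphere, range_size_km``.
    """
    pops = populations[["time_series_id", "species", "latitude"]].drop_duplicates()
    pops = pops.assign(hemisphere=np.where(pops["latitude"] < 0.0, "south", "north"))
    merged = pops.merge(ranges, on=["species", "hemisphere"], how="left")
    unmatched = merged["equatorward_limit"].isna()
    if unmatched.any():
        logger.info(
            "assign_positions: dropped %d populations without a range component",
            int(unmatched.sum()),
        )
        merged = merged[~unmatched]

    width = merged["poleward_limit"] - merged["equatorward_limit"]
    raw = (merged["latitude"].abs() - merged["equatorward_limit"]) / width
    out = (raw < 0.0) | (raw > 1.0)
    pos = np.clip(raw, 0.0, 1.0) if clamp else raw
    return pd.DataFrame(
        {
            "time_series_id": merged["time_series_id"].to_numpy(),
            "species": merged["species"].to_numpy(),
            "position": np.asarray(pos, dtype=float),
            "clamped": out.to_numpy(),
            "hemisphere": merged["hemisphere"].to_numpy(),
            "range_size_km": merged["range_size_km"].to_numpy(),
        }
    )
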