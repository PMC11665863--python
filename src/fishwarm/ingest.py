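"""Reading, validation and filtering of the five input tables.

Input schemas (CSV, UTF-8, header row):

- surveys:      time_series_id, site_id, latitude, longitude, year, species, abundance
- traits:       species, max_length, trophic_level, migratory, native_hemisphere
- sites:        site_id, elevation_m
- climate:      site_id, year, month, tmax_air_c
- occurrences:  species, latitude, longitude

The cleaning chain applied by the pipeline is:

    year cutoff (>= 1958) -> within-year averaging -> zero-filling
    -> series span/richness filters -> trait completeness filter

Zero-filling implements the community-survey assumption: a species recorded
at least once in a series was looked for in every survey year of that
series, so missing years mean "surveyed, not found" and get abundance 0.
Each removal rule is tallied in a :class:`FilterReport`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARLIEST_YEAR = 1958  # climate coverage starts here; older records are dropped

SURVEY_COLUMNS = [
    "time_series_id",
    "site_id",
    "latitude",
    "longitude",
    "year",
    "species",
    "abundance",
]
TRAIT_COLUMNS = ["species", "max_length", "trophic_level", "migratory", "native_hemisphere"]
SITE_COLUMNS = ["site_id", "elevation_m"]
CLIMATE_COLUMNS = ["site_id", "year", "month", "tmax_air_c"]
OCCURRENCE_COLUMNS = ["species", "latitude", "longitude"]


def _require_columns(df: pd.DataFrame, columns: list[str], name: str) -> pd.DataFrame:
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{name} table missing columns: {sorted(missing)}")
    return df


def read_surveys(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SURVEY_COLUMNS, "surveys")
    if not df["latitude"].between(-90, 90).all():
        raise ValueError("survey latitude outside [-90, 90]")
    if (df["abundance"] < 0).any():
        raise ValueError("negative abundance in surveys")
    return df


def read_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, TRAIT_COLUMNS[:3], "traits")
    if "native_hemisphere" not in df.columns:
        df["native_hemisphere"] = "both"
    ok = df["trophic_level"].isna() | df["trophic_level"].between(1.0, 5.5)
    if not ok.all():
        raise ValueError("trophic_level outside [1, 5.5]")
    if (df["max_length"].dropna() <= 0).any():
        raise ValueError("non-positive max_length")
    return df


def read_sites(path) -> pd.DataFrame:
    return _require_columns(pd.read_csv(path), SITE_COLUMNS, "sites")


def read_climate(path) -> pd.DataFrame:
    df = _require_columns(pd.read_csv(path), CLIMATE_COLUMNS, "climate")
    if not df["month"].between(1, 12).all():
        raise ValueError("climate month outside 1..12")
    return df


def read_occurrences(path) -> pd.DataFrame:
    df = _require_columns(pd.read_csv(path), OCCURRENCE_COLUMNS, "occurrences")
    if not df["latitude"].between(-90, 90).all():
        raise ValueError("occurrence latitude outside [-90, 90]")
    return df


# ---------------------------------------------------------------------------
# filter bookkeeping


@dataclass
class FilterStep:
    rule: str
    records_in: int
    records_removed: int
    series_removed: int
    species_removed: int

    @property
    def records_retained(self) -> int:
        return self.records_in - self.records_removed


@dataclass
class FilterReport:
    """Per-rule tallies of removed records/series/species, in application order."""

    steps: list[FilterStep] = field(default_factory=list)

    def add(self, rule: str, before: pd.DataFrame, after: pd.DataFrame) -> None:
        step = FilterStep(
            rule=rule,
            records_in=len(before),
            records_removed=len(before) - len(after),
            series_removed=before["time_series_id"].nunique()
            - after["time_series_id"].nunique(),
            species_removed=before["species"].nunique() - after["species"].nunique(),
        )
        self.steps.append(step)
        logger.info(
            "filter %-18s removed %6d records, %4d series, %4d species",
            rule,
            step.records_removed,
            step.series_removed,
            step.species_removed,
        )

    def removed(self, rule: str) -> FilterStep:
        for step in self.steps:
            if step.rule == rule:
                return step
        raise KeyError(rule)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rule": s.rule,
                    "records_in": s.records_in,
                    "records_removed": s.records_removed,
                    "records_retained": s.records_retained,
                    "series_removed": s.series_removed,
                    "species_removed": s.species_removed,
                }
                for s in self.steps
            ]
        )


# ---------------------------------------------------------------------------
# cleaning operations


def average_within_year(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple observations of a (series, species) within one year
    to their arithmetic mean, keeping one record per series-species-year."""
    keys = ["time_series_id", "site_id", "latitude", "longitude", "year", "species"]
    out = records.groupby(keys, as_index=False, sort=True)["abundance"].mean()
    return out[SURVEY_COLUMNS]


def zero_fill(records: pd.DataFrame) -> pd.DataFrame:
    """Insert abundance-0 records for species missing from survey years.

    For each series, every species seen at least once gets a record in every
    survey year of that series (a survey year is any year with at least one
    record in the series).  Existing abundances are never altered.
    """
    if len(records) == 0:
        return records.copy()
    series_years = records[["time_series_id", "year"]].drop_duplicates()
    series_species = records[
        ["time_series_id", "site_id", "latitude", "longitude", "species"]
    ].drop_duplicates()
    full = series_species.merge(series_years, on="time_series_id")
    out = full.merge(
        records[["time_series_id", "year", "species", "abundance"]],
        on=["time_series_id", "year", "species"],
        how="left",
    )
    out["abundance"] = out["abundance"].fillna(0.0)
    return (
        out[SURVEY_COLUMNS]
        .sort_values(["time_series_id", "species", "year"], kind="mergesort")
        .reset_index(drop=True)
    )


def _series_spans(records: pd.DataFrame) -> pd.DataFrame:
    g = records.groupby("time_series_id")["year"]
    return pd.DataFrame(
        {"n_years": g.nunique(), "span": g.max() - g.min() + 1}
    )


def apply_filters(
    records: pd.DataFrame,
    traits: pd.DataFrame,
    min_survey_years: int = 2,
    min_span: int = 10,
    earliest_year: int = EARLIEST_YEAR,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the inclusion rules, tallying each in application order.

    Rules: (1) drop records before ``earliest_year``; (2) keep series with
    at least ``min_survey_years`` distinct survey years; (3) keep series
    whose inclusive year span (last - first + 1) is at least ``min_span``;
    (4) drop species lacking a max-length or trophic-level entry.
    Idempotent: a second application removes nothing.
    """
    report = FilterReport()

    step = records[records["year"] >= earliest_year]
    report.add("pre_cutoff_year", records, step)
    records = step

    spans = _series_spans(records) if len(records) else pd.DataFrame(columns=["n_years", "span"])

    keep = spans.index[spans["n_years"] >= min_survey_years]
    step = records[records["time_series_id"].isin(keep)]
    report.add("min_survey_years", records, step)
    records = step

    keep = spans.index[(spans["n_years"] >= min_survey_years) & (spans["span"] >= min_span)]
    step = records[records["time_series_id"].isin(keep)]
    report.add("min_span", records, step)
    records = step

    complete = traits.dropna(subset=["max_length", "trophic_level"])["species"]
    step = records[records["species"].isin(set(complete))]
    report.add("missing_traits", records, step)
    records = step

    if len(records) == 0:
        logger.warning("apply_filters: no records survived filtering")
    return records.reset_index(drop=True), report


def clean_surveys(
    raw: pd.DataFrame,
    traits: pd.DataFrame,
    min_survey_years: int = 2,
    min_span: int = 10,
    earliest_year: int = EARLIEST_YEAR,
) -> tuple[pd.DataFrame, FilterReport]:
    """Run the full cleaning chain on raw survey records.

    Order: year cutoff -> within-year averaging -> zero-filling -> series
    span/richness filters -> trait filter.  The cutoff runs before
    zero-filling so that no zeros are invented for pre-coverage years.
    Returns the cleaned records and one FilterReport covering every removal
    rule in application order.
    """
    report = FilterReport()
    cut = raw[raw["year"] >= earliest_year]
    report.add("pre_cutoff_year", raw, cut)
    filled = zero_fill(average_within_year(cut))
    records, tail = apply_filters(
        filled,
        traits,
        min_survey_years=min_survey_years,
        min_span=min_span,
        earliest_year=earliest_year,
    )
    report.steps.extend(tail.steps[1:])  # drop the redundant (empty) cutoff step
    return records, report


def duration_subset(records: pd.DataFrame, min_years: int) -> pd.DataFrame:
    """Retain series whose inclusive span is at least ``min_years``.

    The standard pipeline uses thresholds 10, 20 and 30; smaller values are
    allowed but flagged as outside the analysis design.
    """
    if min_years < 10:
        logger.warning("duration_subset: min_years=%d is below the design minimum of 10", min_years)
    spans = _series_spans(records)
    keep = spans.index[spans["span"] >= min_years]
    return records[records["time_series_id"].isin(keep)].reset_index(drop=True)


def series_durations(records: pd.DataFrame) -> pd.Series:
    """Inclusive span (last - first + 1) per time series."""
    return _series_spans(records)["span"]
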