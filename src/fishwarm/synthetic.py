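"""Synthetic survey, climate, occurrence, trait and elevation tables.

The generator emulates the statistical structure the analysis assumes, with
a known ground truth so every downstream stage can be checked by parameter
recovery:

- Each species occupies a latitudinal band (drawn inside 25-70° absolute
  latitude, a temperate bias mirroring real survey coverage) and carries a
  random intercept u_s ~ N(0, sigma_species) on the log-odds scale.
- Each community time series sits at a site inside its *signal* species'
  band.  The series' latent response sign s = +1/-1 is Bernoulli with
  P(s = +1) = logit^-1(beta0 + beta_pos * position + u_s), where position
  is the site's true relative position in the generative band.
- Monthly maximum air temperature at a site follows a latitude-dependent
  baseline, a seasonal cycle (peaking in July north of the equator, January
  south of it), a linear warming trend and i.i.d. noise.
- The signal population's abundance tracks the annual-mean water
  temperature anomaly (through the same air-to-water transfer the analysis
  applies): in within-series SD units,
  latent = response_effect * anomaly * s + N(0, obs_noise_sd), mapped onto
  a lognormal baseline and observed as rounded counts.  Observation noise
  masks the signal in short series, which is what makes time-series
  duration matter.
- Other community members are background noise populations with no
  temperature response.
- Occurrence clouds are uniform across the species band plus ~1% outlier
  contamination beyond it, so the range-trimming rule has real work to do.
- Zero counts are dropped from the survey table ("surveyed, not found"),
  which is exactly the missingness that zero-filling reconstructs.

Everything is driven by one numpy Generator seeded from the config, so the
same seed yields byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .climate import air_to_water


@dataclass
class GenerativeConfig:
    """Ground-truth parameters of the synthetic study.

    The defaults describe the reference simulation: 150 species over 800
    sites hosting 3,000 community series between 1970 and 2010, a warming
    trend matching the observed 0.279 °C/decade, and abundance noise strong
    enough (obs_noise_sd > response_effect) that short series frequently
    misclassify the response sign.
    """

    n_species: int = 150
    n_sites: int = 800
    n_series: int = 3000
    year_range: tuple[int, int] = (1970, 2010)
    beta0: float = -0.3          # log-odds intercept of a positive response
    beta_pos: float = 0.6        # log-odds slope on range position
    sigma_species: float = 0.8   # SD of species random intercepts (log-odds)
    warming_rate: float = 0.279  # °C air warming per decade
    season_amplitude: float = 8.0    # °C seasonal half-range of monthly maxima
    climate_noise_sd: float = 0.9    # °C i.i.d. noise on monthly maxima
    obs_noise_sd: float = 1.5        # abundance noise, within-series SD units
    response_effect: float = 1.0     # SD units per °C of water T_avg anomaly
    community_size: int = 5          # species per community series (1 signal)
    occurrences_per_species: int = 300
    contamination: float = 0.01      # fraction of occurrences beyond the band
    band_lat_range: tuple[float, float] = (25.0, 70.0)
    min_band_width: float = 4.0      # degrees
    prop_south: float = 0.2          # fraction of southern-hemisphere species
    baseline_log_mean: float = 3.5   # lognormal abundance baseline (log scale)
    baseline_log_sd: float = 0.7
    max_duration: int = 45           # years; series spans drawn U{10..max}
    seed: int = 0

    def __post_init__(self):
        if self.sigma_species < 0:
            raise ValueError("sigma_species must be >= 0")
        if min(self.n_species, self.n_sites, self.n_series) < 1:
            raise ValueError("n_species, n_sites, n_series must all be >= 1")
        y0, y1 = self.year_range
        if y1 < y0:
            raise ValueError("year_range must be a non-empty interval")
        if y1 - y0 + 1 < 10:
            raise ValueError("year_range must span at least 10 years")
        if self.community_size < 1:
            raise ValueError("community_size must be >= 1")
        if self.community_size > self.n_species:
            raise ValueError("community_size cannot exceed n_species")
        if not 0.0 <= self.contamination < 1.0:
            raise ValueError("contamination must be in [0, 1)")

    @classmethod
    def small(cls, **overrides) -> "GenerativeConfig":
        """A quick-running preset (~500 series) for demos and smoke tests."""
        defaults = dict(n_species=60, n_sites=200, n_series=500)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class DatasetBundle:
    """The five input tables plus the generative ground truth."""

    surveys: pd.DataFrame
    climate: pd.DataFrame
    occurrences: pd.DataFrame
    traits: pd.DataFrame
    sites: pd.DataFrame
    ground_truth: pd.DataFrame
    config: GenerativeConfig | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "surveys": self.surveys,
            "climate": self.climate,
            "occurrences": self.occurrences,
            "traits": self.traits,
            "sites": self.sites,
            "ground_truth": self.ground_truth,
        }

    def write(self, directory) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in self.tables().items():
            p = directory / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        return paths


def generate_dataset(config: GenerativeConfig) -> DatasetBundle:
    """Generate the full synthetic bundle under ``config``.

    Raises
    ------
    ValueError
        If the config asks for more series than species x sites can host.
    """
    if config.n_series > config.n_species * config.n_sites:
        raise ValueError(
            f"{config.n_series} series cannot be hosted by "
            f"{config.n_species} species x {config.n_sites} sites"
        )
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.year_range
    years = np.arange(y0, y1 + 1)
    n_years = len(years)

    # --- species: latitudinal bands, hemispheres, intercepts, traits
    lo, hi = config.band_lat_range
    edges = rng.uniform(lo, hi, size=(config.n_species, 2))
    band_lo, band_hi = edges.min(axis=1), edges.max(axis=1)
    narrow = band_hi - band_lo < config.min_band_width
    band_hi[narrow] = np.minimum(band_lo[narrow] + config.min_band_width, hi)
    band_lo[narrow] = band_hi[narrow] - config.min_band_width
    south = rng.random(config.n_species) < config.prop_south
    u_species = (
        rng.normal(0.0, config.sigma_species, config.n_species)
        if config.sigma_species > 0
        else np.zeros(config.n_species)
    )
    species_names = np.array([f"Simulus sp{i:04d}" for i in range(config.n_species)])
    traits = pd.DataFrame(
        {
            "species": species_names,
            "max_length": np.round(np.exp(rng.normal(3.0, 0.8, config.n_species)), 1),
            "trophic_level": np.round(rng.uniform(2.0, 4.5, config.n_species), 2),
            "migratory": (rng.random(config.n_species) < 0.15).astype(int),
            "native_hemisphere": np.where(south, "south", "north"),
        }
    )

    # --- sites: each hosts one species, its latitude inside that band
    host = np.arange(config.n_sites) % config.n_species
    site_abs_lat = rng.uniform(band_lo[host], band_hi[host])
    site_lat = np.round(np.where(south[host], -site_abs_lat, site_abs_lat), 4)
    site_lon = np.round(rng.uniform(-180.0, 180.0, config.n_sites), 4)
    site_ids = np.array([f"L{k:05d}" for k in range(config.n_sites)])
    sites = pd.DataFrame(
        {
            "site_id": site_ids,
            "elevation_m": np.round(rng.lognormal(4.6, 1.0, config.n_sites), 1),
        }
    )

    # --- series: site, signal species, true position, latent sign, years
    site_of = np.arange(config.n_series) % config.n_sites
    sp_of = host[site_of]
    position = (site_abs_lat[site_of] - band_lo[sp_of]) / (band_hi[sp_of] - band_lo[sp_of])
    p_pos = expit(config.beta0 + config.beta_pos * position + u_species[sp_of])
    sign = np.where(rng.random(config.n_series) < p_pos, 1, -1)
    dmax = min(config.max_duration, n_years)
    dur = rng.integers(10, dmax + 1, config.n_series)
    start = y0 + rng.integers(0, n_years - dur + 1)
    series_ids = np.array([f"S{j:05d}" for j in range(config.n_series)])

    # --- climate: baseline + season + warming trend + noise, all site-years
    site_base = 27.0 - 0.42 * np.abs(site_lat) + rng.normal(0.0, 1.0, config.n_sites)
    month = np.arange(1, 13)
    peak = np.where(south[host], 1.0, 7.0)
    seasonal = config.season_amplitude * np.cos(
        2.0 * np.pi * (month[None, :] - peak[:, None]) / 12.0
    )
    trend = config.warming_rate / 10.0 * (years - y0)
    tmax_air = (
        site_base[:, None, None]
        + seasonal[:, None, :]
        + trend[None, :, None]
        + (
            rng.normal(0.0, config.climate_noise_sd, (config.n_sites, n_years, 12))
            if config.climate_noise_sd > 0
            else 0.0
        )
    )
    tmax_air = np.round(tmax_air, 3)
    climate = pd.DataFrame(
        {
            "site_id": np.repeat(site_ids, n_years * 12),
            "year": np.tile(np.repeat(years, 12), config.n_sites),
            "month": np.tile(month, config.n_sites * n_years),
            "tmax_air_c": tmax_air.ravel(),
        }
    )
    # annual mean water temperature per site-year, from the rounded values
    # the climate table actually contains (what the analysis will see)
    tavg_water = air_to_water(tmax_air.ravel()).reshape(config.n_sites, n_years, 12).mean(axis=2)

    # --- populations: signal species + distinct background community members
    c = config.community_size
    if c > 1:
        keys = rng.random((config.n_series, config.n_species))
        keys[np.arange(config.n_series), sp_of] = np.inf
        background = np.argpartition(keys, c - 1, axis=1)[:, : c - 1]
        community = np.concatenate([sp_of[:, None], np.sort(background, axis=1)], axis=1)
    else:
        community = sp_of[:, None]
    n_pop = config.n_series * c
    pop_series = np.repeat(np.arange(config.n_series), c)
    pop_sp = community.ravel()
    pop_signal = np.tile(np.arange(c) == 0, config.n_series).astype(float)
    baseline = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_pop))

    rows_per_pop = dur[pop_series]
    total = int(rows_per_pop.sum())
    row_pop = np.repeat(np.arange(n_pop), rows_per_pop)
    offsets = np.concatenate([[0], np.cumsum(rows_per_pop)])[:-1]
    within = np.arange(total) - offsets[row_pop]
    row_series = pop_series[row_pop]
    row_year = start[row_series] + within
    row_site = site_of[row_series]

    # water T_avg anomaly relative to the series' own window mean
    csum = np.concatenate(
        [np.zeros((config.n_sites, 1)), np.cumsum(tavg_water, axis=1)], axis=1
    )
    window_mean = (
        csum[site_of, start - y0 + dur] - csum[site_of, start - y0]
    ) / dur
    anomaly = tavg_water[row_site, row_year - y0] - window_mean[row_series]

    latent = config.response_effect * anomaly * sign[row_series] * pop_signal[row_pop]
    if config.obs_noise_sd > 0:
        latent = latent + rng.normal(0.0, config.obs_noise_sd, total)
    abundance = np.rint(baseline[row_pop] * np.clip(1.0 + 0.25 * latent, 0.0, None))

    observed = abundance > 0  # zero counts are unrecorded: "surveyed, not found"
    surveys = pd.DataFrame(
        {
            "time_series_id": series_ids[row_series[observed]],
            "site_id": site_ids[row_site[observed]],
            "latitude": site_lat[row_site[observed]],
            "longitude": site_lon[row_site[observed]],
            "year": row_year[observed],
            "species": species_names[pop_sp[row_pop[observed]]],
            "abundance": abundance[observed],
        }
    )

    # --- occurrences: uniform cloud over the band + contamination outside
    n_occ = config.occurrences_per_species
    n_out = int(np.round(config.contamination * n_occ))
    n_in = n_occ - n_out
    abs_in = rng.uniform(
        band_lo[:, None], band_hi[:, None], size=(config.n_species, n_in)
    )
    if n_out > 0:
        above = rng.random((config.n_species, n_out)) < 0.5
        hi_out = rng.uniform(
            band_hi[:, None], np.minimum(band_hi + 8.0, 89.9)[:, None],
            size=(config.n_species, n_out),
        )
        lo_out = rng.uniform(
            np.maximum(band_lo - 8.0, 0.1)[:, None], band_lo[:, None],
            size=(config.n_species, n_out),
        )
        abs_occ = np.concatenate([abs_in, np.where(above, hi_out, lo_out)], axis=1)
    else:
        abs_occ = abs_in
    occ_lat = np.where(south[:, None], -abs_occ, abs_occ)
    occurrences = pd.DataFrame(
        {
            "species": np.repeat(species_names, n_occ),
            "latitude": np.round(occ_lat.ravel(), 4),
            "longitude": np.round(
                rng.uniform(-180.0, 180.0, config.n_species * n_occ), 4
            ),
        }
    )

    ground_truth = pd.DataFrame(
        {
            "time_series_id": series_ids,
            "species": species_names[sp_of],
            "position": position,
            "p_positive": p_pos,
            "sign": sign,
            "species_intercept": u_species[sp_of],
            "duration": dur,
            "start_year": start,
        }
    )
    return DatasetBundle(
        surveys=surveys,
        climate=climate,
        occurrences=occurrences,
        traits=traits,
        sites=sites,
        ground_truth=ground_truth,
        config=config,
    )


def simulate_annual_temperatures(
    n_sites: int = 100,
    years: tuple[int, int] = (1980, 2010),
    trend_per_decade: float = 0.279,
    site_sd: float = 0.8,
    resid_sd: float = 0.35,
    mean_level: float = 16.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Annual water temperatures drawn directly from the warming-trend LMM.

    w_st = mean_level + a_s + (trend_per_decade / 10) * (year - first year)
           + eps_st,   a_s ~ N(0, site_sd^2),  eps ~ N(0, resid_sd^2)

    Used to check that :func:`fishwarm.climate.warming_trend` recovers a
    known decadal trend: the generative model here *is* the fitted model,
    so the true coefficient is unambiguous (pushing an air trend through
    the nonlinear transfer would give every site its own water trend).
    Returns columns ``site_id, year, t_avg, t_max, n_months`` (t_max is set
    a fixed offset above t_avg; n_months = 12).
    """
    rng = np.random.default_rng(seed)
    y0, y1 = years
    yr = np.arange(y0, y1 + 1)
    intercepts = rng.normal(0.0, site_sd, n_sites)
    grid_site = np.repeat(np.arange(n_sites), len(yr))
    grid_year = np.tile(yr, n_sites)
    w = (
        mean_level
        + intercepts[grid_site]
        + trend_per_decade / 10.0 * (grid_year - y0)
        + rng.normal(0.0, resid_sd, len(grid_site))
    )
    return pd.DataFrame(
        {
            "site_id": np.array([f"L{k:04d}" for k in range(n_sites)])[grid_site],
            "year": grid_year,
            "t_avg": w,
            "t_max": w + 4.0,
            "n_months": 12,
        }
    )


# ---------------------------------------------------------------------------
# hand-sized edge-case fixtures


@dataclass
class EdgeFixtures:
    """Hand-built tables exercising every filter, with hand-enumerated
    expected tallies in ``expected`` (counted directly from the rows below,
    so filter bookkeeping can be checked exactly)."""

    surveys: pd.DataFrame
    traits: pd.DataFrame
    sites: pd.DataFrame
    climate: pd.DataFrame
    occurrences: pd.DataFrame
    expected: dict = field(default_factory=dict)


def generate_edge_fixtures() -> EdgeFixtures:
    """Small deterministic tables covering the documented edge cases:

    - "span9": a series spanning 9 years (below the 10-year minimum);
    - "single": a single-survey series;
    - "pre1958": a series with one 1957 record (dropped) plus 1958+ records;
    - "traitless": a species with no length/trophic entry;
    - "constvar": a constant-abundance population (zero variance);
    - "equator": an equator-spanning species (occurrences -20..+30);
    - "southern": a southern-hemisphere series and species.
    """
    site_rows = [
        ("E1", 47.0, 5.0, 200.0),
        ("E2", 46.0, 6.0, 150.0),
        ("E3", -35.0, 146.0, 90.0),
        ("E4", 10.0, -60.0, 50.0),
    ]
    sites = pd.DataFrame(
        [{"site_id": s, "elevation_m": e} for s, _, _, e in site_rows]
    )
    lat = {s: la for s, la, _, _ in site_rows}
    lon = {s: lo for s, _, lo, _ in site_rows}

    def rec(series, site, year, species, abundance):
        return {
            "time_series_id": series,
            "site_id": site,
            "latitude": lat[site],
            "longitude": lon[site],
            "year": year,
            "species": species,
            "abundance": float(abundance),
        }

    rows = []
    # ok10: span 10, sub-annual duplicates in 2000, Salmo seen twice only
    rows += [rec("ok10", "E1", 2000, "Barbus fluvialis", 8),
             rec("ok10", "E1", 2000, "Barbus fluvialis", 12)]
    for i, year in enumerate(range(2001, 2010)):
        rows.append(rec("ok10", "E1", year, "Barbus fluvialis", 11 + (i % 4)))
    rows += [rec("ok10", "E1", 2000, "Salmo frigidus", 3),
             rec("ok10", "E1", 2002, "Salmo frigidus", 5)]
    # span9: 2000-2008 inclusive span 9 -> removed
    for i, year in enumerate(range(2000, 2009)):
        rows.append(rec("span9", "E1", year, "Barbus fluvialis", 10 + (i % 3)))
    # single: one survey year -> removed
    rows.append(rec("single", "E2", 2005, "Barbus fluvialis", 7))
    # pre1958: 1957 record dropped, series retained (1958-1970, span 13)
    for year, ab in [(1957, 4), (1958, 5), (1963, 6), (1970, 7)]:
        rows.append(rec("pre1958", "E2", year, "Barbus fluvialis", ab))
    # traitless: Gobio nullus lacks traits; Barbus keeps the series alive
    for i, year in enumerate(range(1990, 2002)):
        rows.append(rec("traitless", "E1", year, "Barbus fluvialis", 10 + (i % 5)))
    for year in (1990, 1995, 2000):
        rows.append(rec("traitless", "E1", year, "Gobio nullus", 2))
    # constvar: Constans perpetuus has zero abundance variance
    for i, year in enumerate(range(1995, 2006)):
        rows.append(rec("constvar", "E2", year, "Constans perpetuus", 5))
        rows.append(rec("constvar", "E2", year, "Barbus fluvialis", 9 + (i % 4)))
    # equator: species spanning the equator, site at 10 N
    for i, year in enumerate(range(2000, 2011)):
        rows.append(rec("equator", "E4", year, "Aequator transiens", 20 + (i % 6)))
    # southern: southern-hemisphere series
    for i, year in enumerate(range(1988, 2001)):
        rows.append(rec("southern", "E3", year, "Australis meridionalis", 15 + (i % 4)))
    surveys = pd.DataFrame(rows)

    traits = pd.DataFrame(
        [
            {"species": "Barbus fluvialis", "max_length": 45.0, "trophic_level": 3.0,
             "migratory": 0, "native_hemisphere": "north"},
            {"species": "Salmo frigidus", "max_length": 80.0, "trophic_level": 4.2,
             "migratory": 1, "native_hemisphere": "north"},
            {"species": "Gobio nullus", "max_length": np.nan, "trophic_level": np.nan,
             "migratory": 0, "native_hemisphere": "north"},
            {"species": "Constans perpetuus", "max_length": 12.0, "trophic_level": 2.5,
             "migratory": 0, "native_hemisphere": "north"},
            {"species": "Aequator transiens", "max_length": 30.0, "trophic_level": 3.3,
             "migratory": 0, "native_hemisphere": "both"},
            {"species": "Australis meridionalis", "max_length": 25.0,
             "trophic_level": 2.8, "migratory": 0, "native_hemisphere": "south"},
        ]
    )

    occ_rows = []

    def cloud(species, lats):
        for la in lats:
            occ_rows.append({"species": species, "latitude": float(la), "longitude": 0.0})

    cloud("Barbus fluvialis", np.linspace(40, 55, 100))
    cloud("Salmo frigidus", np.linspace(42, 60, 100))
    cloud("Aequator transiens", np.arange(-20, 31))
    cloud("Australis meridionalis", np.linspace(-50, -10, 41))
    cloud("Constans perpetuus", np.linspace(41, 49, 30))
    occurrences = pd.DataFrame(occ_rows)

    clim_rows = []
    for site, la, _, _ in site_rows:
        peak = 1 if la < 0 else 7
        for year in range(1957, 2011):
            for m in range(1, 13):
                t = (
                    25.0
                    - 0.3 * abs(la)
                    + 8.0 * np.cos(2.0 * np.pi * (m - peak) / 12.0)
                    + 0.03 * (year - 1957)
                    + 0.2 * np.sin(2.7 * (year - 1957))
                )
                clim_rows.append(
                    {"site_id": site, "year": year, "month": m, "tmax_air_c": round(t, 3)}
                )
    climate = pd.DataFrame(clim_rows)

    expected = {
        "raw_records": 88,
        "pre_cutoff_records_removed": 1,
        "records_after_averaging": 86,
        "records_after_zero_fill": 103,
        "min_survey_years_series_removed": 1,
        "min_survey_years_records_removed": 1,
        "min_span_series_removed": 1,
        "min_span_records_removed": 9,
        "missing_traits_species_removed": 1,
        "missing_traits_records_removed": 12,
        "retained_records": 81,
        "retained_series": 6,
        "zero_variance_populations": 1,
        "response_rows": 7,
    }
    return EdgeFixtures(
        surveys=surveys,
        traits=traits,
        sites=sites,
        climate=climate,
        occurrences=occurrences,
        expected=expected,
    )


def config_to_dict(config: GenerativeConfig) -> dict:
    d = asdict(config)
    d["year_range"] = list(d["year_range"])
    d["band_lat_range"] = list(d["band_lat_range"])
    return d


def config_from_dict(d: dict) -> GenerativeConfig:
    d = dict(d)
    for key in ("year_range", "band_lat_range"):
        if key in d:
            d[key] = tuple(d[key])
    return GenerativeConfig(**d)
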