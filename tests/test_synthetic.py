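"""Generator contracts: determinism, generative probabilities, edge fixtures."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from fishwarm import GenerativeConfig, generate_dataset
from fishwarm.ingest import CLIMATE_COLUMNS, SURVEY_COLUMNS

EXPIT_1 = 0.731058578630004879251159241822


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        cfg = GenerativeConfig.small(seed=1)
        b1, b2 = generate_dataset(cfg), generate_dataset(cfg)
        for name, t1 in b1.tables().items():
            pd.testing.assert_frame_equal(t1, b2.tables()[name])
            assert t1.to_csv(index=False) == b2.tables()[name].to_csv(index=False)

    def test_different_seed_differs(self):
        b1 = generate_dataset(GenerativeConfig.small(seed=1))
        b2 = generate_dataset(GenerativeConfig.small(seed=2))
        assert not b1.surveys.equals(b2.surveys)


class TestConfigValidation:
    def test_capacity_error(self):
        with pytest.raises(ValueError, match="hosted"):
            generate_dataset(
                GenerativeConfig(n_species=2, n_sites=3, n_series=7, community_size=1)
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sigma_species": -0.1},
            {"n_series": 0},
            {"year_range": (2000, 1999)},
            {"community_size": 0},
            {"contamination": 1.5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GenerativeConfig(**kwargs)


class TestSchemas:
    def test_tables_satisfy_ingest_schemas(self, small_bundle):
        assert list(small_bundle.surveys.columns) == SURVEY_COLUMNS
        assert list(small_bundle.climate.columns) == CLIMATE_COLUMNS
        assert small_bundle.surveys["latitude"].between(-90, 90).all()
        assert (small_bundle.surveys["abundance"] > 0).all()
        assert small_bundle.climate["month"].between(1, 12).all()
        sites = set(small_bundle.sites["site_id"])
        assert set(small_bundle.surveys["site_id"]) <= sites
        assert set(small_bundle.climate["site_id"]) == sites

    def test_one_ground_truth_row_per_series(self, small_bundle):
        gt = small_bundle.ground_truth
        assert gt["time_series_id"].is_unique
        assert set(small_bundle.surveys["time_series_id"]) <= set(gt["time_series_id"])
        assert gt["position"].between(0, 1).all()

    def test_series_latitude_inside_species_occurrence_band(self, small_bundle):
        gt = small_bundle.ground_truth
        meta = small_bundle.surveys[["time_series_id", "latitude"]].drop_duplicates()
        merged = gt.merge(meta, on="time_series_id")
        occ = small_bundle.occurrences.groupby("species")["latitude"]
        lo, hi = occ.min(), occ.max()
        assert (merged["latitude"] >= lo[merged["species"]].to_numpy()).all()
        assert (merged["latitude"] <= hi[merged["species"]].to_numpy()).all()


class TestClimateStructure:
    def test_noise_free_warming_is_strictly_increasing_in_year(self):
        cfg = GenerativeConfig.small(seed=3, climate_noise_sd=0.0)
        clim = generate_dataset(cfg).climate
        one = clim[(clim["site_id"] == clim["site_id"].iloc[0]) & (clim["month"] == 7)]
        assert np.all(np.diff(one.sort_values("year")["tmax_air_c"]) > 0)

    def test_seasonal_peak_depends_on_hemisphere(self):
        cfg = GenerativeConfig.small(seed=3, climate_noise_sd=0.0, prop_south=0.5)
        b = generate_dataset(cfg)
        surveys = b.surveys[["site_id", "latitude"]].drop_duplicates()
        north = surveys[surveys["latitude"] > 0]["site_id"].iloc[0]
        south = surveys[surveys["latitude"] < 0]["site_id"].iloc[0]
        clim = b.climate
        for site, peak in ((north, 7), (south, 1)):
            year1 = clim[(clim["site_id"] == site) & (clim["year"] == 2000)]
            assert int(year1.loc[year1["tmax_air_c"].idxmax(), "month"]) == peak


class TestGenerativeProbabilities:
    def test_sign_probability_matches_logistic_oracle(self):
        # beta0=0, beta_pos=2, zero random intercept: P(+) at position 0.5
        # equals logit^-1(1); checked against the realized frequency
        cfg = GenerativeConfig(
            n_species=40,
            n_sites=400,
            n_series=8000,
            beta0=0.0,
            beta_pos=2.0,
            sigma_species=0.0,
            seed=17,
        )
        gt = generate_dataset(cfg).ground_truth
        band = gt[(gt["position"] - 0.5).abs() < 0.05]
        p_band = expit(2.0 * band["position"]).mean()
        assert p_band == pytest.approx(EXPIT_1, abs=0.01)
        frac = (band["sign"] > 0).mean()
        se = np.sqrt(p_band * (1 - p_band) / len(band))
        assert abs(frac - p_band) < 3 * se

    def test_null_model_has_flat_position_effect(self):
        cfg = GenerativeConfig(
            n_species=50,
            n_sites=500,
            n_series=5000,
            beta_pos=0.0,
            sigma_species=0.0,
            seed=23,
        )
        gt = generate_dataset(cfg).ground_truth
        y = (gt["sign"] > 0).astype(int).to_numpy()
        X = sm.add_constant(gt["position"].to_numpy())
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert abs(res.params[1]) < 3 * res.bse[1]

    def test_positive_fraction_converges_to_inverse_logit_curve(self):
        # empirical positive fraction tracks logit^-1(b0 + b1*pos) at n=10,000
        cfg = GenerativeConfig(
            n_species=100,
            n_sites=1000,
            n_series=10_000,
            sigma_species=0.0,
            seed=29,
        )
        gt = generate_dataset(cfg).ground_truth
        bins = pd.cut(gt["position"], np.linspace(0, 1, 6))
        for _, grp in gt.groupby(bins, observed=True):
            p = expit(cfg.beta0 + cfg.beta_pos * grp["position"]).mean()
            se = np.sqrt(p * (1 - p) / len(grp))
            assert abs((grp["sign"] > 0).mean() - p) < 3 * se


class TestEdgeFixtures:
    def test_constructed_properties(self, edge):
        years = edge.surveys.groupby("time_series_id")["year"]
        span = years.max() - years.min() + 1
        assert (span == 9).sum() == 1  # exactly one 9-year series
        assert (edge.surveys["year"] == 1957).sum() == 1
        eq = edge.occurrences[edge.occurrences["species"] == "Aequator transiens"]
        assert eq["latitude"].min() == -20.0 and eq["latitude"].max() == 30.0
        assert len(edge.surveys) == edge.expected["raw_records"]

    def test_contains_all_documented_cases(self, edge):
        ids = set(edge.surveys["time_series_id"])
        assert {"span9", "single", "pre1958", "traitless", "constvar",
                "equator", "southern", "ok10"} <= ids
        traitless = edge.traits[edge.traits["max_length"].isna()]
        assert len(traitless) == 1
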