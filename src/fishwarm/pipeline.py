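"""End-to-end orchestration: ingest -> climate -> ranges -> response -> models.

`run_pipeline` executes the whole analysis for each requested temperature
variable (t_avg, t_max) and duration threshold (10/20/30 years), fits the
requested model suite, and writes tidy CSV artifacts:

- ``filter_report.csv``      per-rule removal tallies
- ``annual_water.csv``       per site-year t_avg/t_max on the water scale
- ``ranges.csv``             trimmed per-species range limits
- ``positions.csv``          per-population positions in range
- ``warming_trends.csv``     decadal water-temperature trends (LMM)
- ``position_models.csv``    the headline grid: variable x duration rows with
                             the range-position effect (estimate, SE, z, p)
- ``covariate_models.csv``   elevation / trait-interaction / hemisphere rows
- ``slope_sensitivity.csv``  continuous-slope analogue and sign agreement
- ``predictions_*.csv``      population-level probability grids
- ``response_<var>.csv``     the modeling tables themselves
- ``run.json``               provenance: config, hash, seed, timings
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as climate_mod
from . import ingest, ranges, response, synthetic
from .mixedmodels import MixedModelFit, ModelSpec, fit_glmm, predict_probability, slope_sensitivity

logger = logging.getLogger(__name__)

ALL_MODELS = (
    "position",
    "elevation",
    "length",
    "trophic",
    "migratory",
    "range_size",
    "hemisphere",
    "slope_sensitivity",
    "warming_trend",
)

TRAIT_COLUMN = {
    "length": "max_length",
    "trophic": "trophic_level",
    "migratory": "migratory",
    "range_size": "range_size_km",
}


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``input_dir`` (holding surveys/traits/sites/climate/occurrences
    CSVs in the documented schemas) or a synthetic generator config must be
    provided.  ``seed`` overrides the synthetic config's seed when set, so
    one flag controls end-to-end determinism.
    """

    input_dir: str | None = None
    synthetic: synthetic.GenerativeConfig | None = None
    variables: tuple[str, ...] = ("t_avg", "t_max")
    durations: tuple[int, ...] = (10, 20, 30)
    models: tuple[str, ...] = ALL_MODELS
    output_dir: str = "fishwarm_run"
    seed: int | None = None
    min_months: int = 12
    quantile_tail: float = 0.01
    quantile_method: str = "quantile"
    min_occurrences: int = 10
    clamp_positions: bool = True

    def __post_init__(self):
        bad = set(self.models) - set(ALL_MODELS)
        if bad:
            raise ValueError(f"unknown models: {sorted(bad)}")
        bad = set(self.variables) - {"t_avg", "t_max"}
        if bad:
            raise ValueError(f"unknown temperature variables: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = synthetic.config_from_dict(raw["synthetic"])
        for key in ("variables", "durations", "models"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = synthetic.config_to_dict(self.synthetic)
        for key in ("variables", "durations", "models"):
            d[key] = list(d[key])
        return d


@dataclass
class RunReport:
    """All artifacts of one pipeline run, with provenance."""

    config: PipelineConfig
    config_hash: str
    filter_report: ingest.FilterReport
    annual_water: pd.DataFrame
    ranges: pd.DataFrame
    positions: pd.DataFrame
    warming_trends: pd.DataFrame
    position_models: pd.DataFrame
    covariate_models: pd.DataFrame
    slope_sensitivity: pd.DataFrame
    predictions: dict[str, pd.DataFrame]
    response_tables: dict[str, pd.DataFrame]
    fits: dict[str, MixedModelFit] = field(default_factory=dict)
    elapsed_s: float = 0.0

    def write(self, directory) -> Path:
        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        self.filter_report.to_frame().to_csv(out / "filter_report.csv", index=False)
        self.annual_water.to_csv(out / "annual_water.csv", index=False)
        self.ranges.to_csv(out / "ranges.csv", index=False)
        self.positions.to_csv(out / "positions.csv", index=False)
        self.warming_trends.to_csv(out / "warming_trends.csv", index=False)
        self.position_models.to_csv(out / "position_models.csv", index=False)
        self.covariate_models.to_csv(out / "covariate_models.csv", index=False)
        self.slope_sensitivity.to_csv(out / "slope_sensitivity.csv", index=False)
        for name, grid in self.predictions.items():
            grid.to_csv(out / f"predictions_{name}.csv", index=False)
        for var, table in self.response_tables.items():
            table.to_csv(out / f"response_{var}.csv", index=False)
        meta = {
            "config": self.config.to_dict(),
            "config_hash": self.config_hash,
            "elapsed_s": round(self.elapsed_s, 2),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        (out / "run.json").write_text(json.dumps(meta, indent=2))
        return out


def _load_tables(cfg: PipelineConfig):
    if cfg.input_dir is not None:
        d = Path(cfg.input_dir)
        for name in ("surveys", "traits", "sites", "climate", "occurrences"):
            if not (d / f"{name}.csv").exists():
                raise FileNotFoundError(d / f"{name}.csv")
        return (
            ingest.read_surveys(d / "surveys.csv"),
            ingest.read_traits(d / "traits.csv"),
            ingest.read_sites(d / "sites.csv"),
            ingest.read_climate(d / "climate.csv"),
            ingest.read_occurrences(d / "occurrences.csv"),
        )
    if cfg.synthetic is None:
        raise ValueError("config needs either input_dir or a synthetic generator config")
    gen = cfg.synthetic
    if cfg.seed is not None:
        gen = dataclasses.replace(gen, seed=cfg.seed)
    bundle = synthetic.generate_dataset(gen)
    return bundle.surveys, bundle.traits, bundle.sites, bundle.climate, bundle.occurrences


def _coef_row(fit: MixedModelFit, term: str) -> dict:
    row = fit.coefficients.set_index("term").loc[term]
    return {
        "estimate": float(row["estimate"]),
        "se": float(row["se"]),
        "z": float(row["z"]),
        "p": float(row["p"]),
    }


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute every stage for each (variable, duration) cell.

    Model non-convergence is flagged in the output rows and the run
    continues; stage failures abort with a stage-attributed error.
    """
    t0 = time.time()
    hashed = {k: v for k, v in cfg.to_dict().items() if k != "output_dir"}
    cfg_hash = hashlib.sha256(
        json.dumps(hashed, sort_keys=True).encode()
    ).hexdigest()[:16]

    surveys_raw, traits, sites, climate_tbl, occurrences = _load_tables(cfg)
    logger.info("pipeline %s: %d raw survey records", cfg_hash, len(surveys_raw))

    records, filter_report = ingest.clean_surveys(surveys_raw, traits)
    annual = climate_mod.aggregate_annual(climate_tbl, min_months=cfg.min_months)

    range_table = ranges.trim_and_limit(
        occurrences,
        native_hemisphere=traits.set_index("species")["native_hemisphere"],
        min_occurrences=cfg.min_occurrences,
        tail=cfg.quantile_tail,
        method=cfg.quantile_method,
    )
    positions = ranges.assign_positions(records, range_table, clamp=cfg.clamp_positions)

    warming_rows = []
    if "warming_trend" in cfg.models:
        for var in cfg.variables:
            fit = climate_mod.warming_trend(annual, variable=var)
            est, se = climate_mod.decadal_trend(fit)
            warming_rows.append(
                {
                    "temperature_variable": var,
                    "trend_c_per_decade": est,
                    "se": se,
                    "random_intercept_sd": fit.random_intercept_sd,
                    "n_site_years": fit.n_obs,
                    "converged": fit.converged,
                }
            )

    position_rows, covariate_rows, sens_rows = [], [], []
    predictions: dict[str, pd.DataFrame] = {}
    response_tables: dict[str, pd.DataFrame] = {}
    fits: dict[str, MixedModelFit] = {}

    for var in cfg.variables:
        table = response.assemble_response_table(
            records, annual, positions, sites, traits, variable=var, min_duration=10
        )
        response_tables[var] = table

        if "position" in cfg.models:
            for dmin in sorted(cfg.durations):
                sub = table[table["duration"] >= dmin]
                spec = ModelSpec(response="response_binary", fixed_terms=["position"])
                fit = fit_glmm(sub, spec)
                key = f"position_{var}_{dmin}"
                fits[key] = fit
                position_rows.append(
                    {
                        "temperature_variable": var,
                        "duration": f"{dmin}+",
                        **_coef_row(fit, "position"),
                        "random_intercept_sd": fit.random_intercept_sd,
                        "n_obs": fit.n_obs,
                        "n_species": fit.n_groups,
                        "converged": fit.converged,
                    }
                )
                if fit.converged:
                    predictions[key] = predict_probability(fit)

        base = table[table["duration"] >= 10]
        if "elevation" in cfg.models:
            spec = ModelSpec(
                response="response_binary",
                fixed_terms=["position", "elevation"],
                scale_predictors=True,
            )
            fit = fit_glmm(base, spec)
            fits[f"elevation_{var}"] = fit
            covariate_rows.append(
                {
                    "variable": "elevation",
                    "temperature_variable": var,
                    "effect_estimate": _coef_row(fit, "elevation")["estimate"],
                    "interaction_estimate": np.nan,
                    **{k: v for k, v in _coef_row(fit, "elevation").items() if k != "estimate"},
                    "converged": fit.converged,
                }
            )
        for model in ("length", "trophic", "migratory", "range_size"):
            if model not in cfg.models:
                continue
            col = TRAIT_COLUMN[model]
            spec = ModelSpec(
                response="response_binary",
                fixed_terms=["position"],
                interaction=("position", col),
                scale_predictors=True,
            )
            fit = fit_glmm(base, spec)
            fits[f"{model}_{var}"] = fit
            term = f"position:{col}"
            covariate_rows.append(
                {
                    "variable": model,
                    "temperature_variable": var,
                    "effect_estimate": np.nan,
                    "interaction_estimate": _coef_row(fit, term)["estimate"],
                    **{k: v for k, v in _coef_row(fit, term).items() if k != "estimate"},
                    "converged": fit.converged,
                }
            )
            if fit.converged:
                lo, hi, med = fit.data_ranges[col]
                q1, q3 = base[col].quantile([0.25, 0.75])
                grids = []
                for label, value in (("q1", q1), ("median", med), ("q3", q3)):
                    g = predict_probability(fit, at={col: float(value)})
                    g.insert(0, "at", label)
                    grids.append(g)
                predictions[f"{model}_{var}"] = pd.concat(grids, ignore_index=True)
        if "hemisphere" in cfg.models and base["hemisphere"].nunique() > 1:
            spec = ModelSpec(
                response="response_binary",
                fixed_terms=["position"],
                interaction=("position", "hemisphere"),
            )
            fit = fit_glmm(base, spec)
            fits[f"hemisphere_{var}"] = fit
            term = "position:hemisphere"
            covariate_rows.append(
                {
                    "variable": "hemisphere",
                    "temperature_variable": var,
                    "effect_estimate": np.nan,
                    "interaction_estimate": _coef_row(fit, term)["estimate"],
                    **{k: v for k, v in _coef_row(fit, term).items() if k != "estimate"},
                    "converged": fit.converged,
                }
            )
        if "slope_sensitivity" in cfg.models:
            spec = ModelSpec(response="response_binary", fixed_terms=["position"])
            sens = slope_sensitivity(base, spec)
            sens_rows.append(
                {
                    "temperature_variable": var,
                    "binomial_position": sens.binomial.coef("position"),
                    "binomial_se": sens.binomial.se("position"),
                    "gaussian_position": sens.gaussian.coef("position"),
                    "gaussian_se": sens.gaussian.se("position"),
                    "sign_agreement": sens.sign_agreement,
                }
            )

    report = RunReport(
        config=cfg,
        config_hash=cfg_hash,
        filter_report=filter_report,
        annual_water=annual,
        ranges=range_table,
        positions=positions,
        warming_trends=pd.DataFrame(warming_rows),
        position_models=pd.DataFrame(position_rows),
        covariate_models=pd.DataFrame(covariate_rows),
        slope_sensitivity=pd.DataFrame(sens_rows),
        predictions=predictions,
        response_tables=response_tables,
        fits=fits,
        elapsed_s=time.time() - t0,
    )
    report.write(cfg.output_dir)
    logger.info("pipeline %s finished in %.1fs", cfg_hash, report.elapsed_s)
    return report


def render_report(run_dir, figures: bool = True) -> list[Path]:
    """Render summary CSVs (and optionally effect-curve figures) from a
    finished run directory.  Raises if the directory has no run artifacts."""
    run_dir = Path(run_dir)
    if not (run_dir / "run.json").exists():
        raise FileNotFoundError(f"{run_dir} does not contain a finished run (run.json missing)")
    written: list[Path] = []
    if not figures:
        return written
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for grid_path in sorted(run_dir.glob("predictions_*.csv")):
        grid = pd.read_csv(grid_path)
        fig, ax = plt.subplots(figsize=(5, 3.5))
        if "at" in grid.columns:
            for label, g in grid.groupby("at", sort=False):
                ax.plot(g["position"], g["probability"], label=str(label))
                ax.fill_between(g["position"], g["ci_low"], g["ci_high"], alpha=0.15)
            ax.legend(fontsize=8)
        else:
            ax.plot(grid["position"], grid["probability"])
            ax.fill_between(grid["position"], grid["ci_low"], grid["ci_high"], alpha=0.2)
        ax.set_xlabel("position in species range (0 = equatorward, 1 = poleward)")
        ax.set_ylabel("P(abundance increases with warming)")
        ax.set_ylim(0, 1)
        name = grid_path.stem.replace("predictions_", "")
        ax.set_title(name, fontsize=9)
        fig.tight_layout()
        out = run_dir / f"{name}.png"
        fig.savefig(out, dpi=120)
        plt.close(fig)
        written.append(out)
    return written
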