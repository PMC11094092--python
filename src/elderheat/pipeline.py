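"""End-to-end orchestration: synthetic inputs -> exposure and decomposition tables.

``run_pipeline`` wires the stages together for one configuration: generate
(or load) inputs, downscale the age-stratified population per scenario,
compute per-model heat metrics and their ensemble medians, build exposure
surfaces and regional tables, and decompose exposure change into its
drivers. Outputs are plain DataFrames plus (optionally) on-disk artifacts
with a manifest; re-running with an identical configuration reproduces
identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .containers import BASE_YEAR_SCENARIO, PopulationGrid
from .decomposition import decompose
from .demographics import age_fractions, downscale
from .exposure import (
    DANGER_THRESHOLDS,
    EXPOSURE_NAMES,
    aggregate_regions,
    align_population_to_climate_grid,
    exceedance_curve,
    exposure_surface,
    regional_summary,
    regional_t_test,
    threshold_population_change,
)
from .heat_metrics import ensemble_median, metric_surfaces
from .io import write_ascii_grid, write_country_table, write_manifest
from .synthetic import (
    HISTORICAL,
    SyntheticConfig,
    generate_population_inputs,
    generate_temperature_epoch,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one full synthetic pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    n_models: int = 5
    cdd_threshold: float = 24.0
    hot_day_threshold: float = 37.5
    exceedance_benchmarks: dict = field(
        default_factory=lambda: dict(DANGER_THRESHOLDS)
    )
    weight_scheme: str = "paper"
    scenarios: tuple[str, ...] | None = None  # None = all configured
    perturbation: float = 0.0
    output_dir: str | None = None

    def scenario_list(self) -> tuple[str, ...]:
        if self.scenarios is None:
            return self.synthetic.scenarios
        for s in self.scenarios:
            self.synthetic.require_scenario(s)
        return tuple(self.scenarios)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """All in-memory products of one run."""

    config: PipelineConfig
    base_aligned: PopulationGrid
    projected: dict            # scenario -> PopulationGrid (climate grid)
    fractions: dict            # scenario (incl. base) -> AgeFractionSurface
    metrics: dict              # (scenario, metric) -> ensemble-median surface
    metrics_by_model: dict     # (scenario, metric) -> list of per-model surfaces
    exposures: dict            # (scenario, metric) -> ExposureSurface (69+)
    regional_table: pd.DataFrame
    exposure_table: pd.DataFrame
    decomposition_table: pd.DataFrame
    exceedance_changes: pd.DataFrame
    t_tests: pd.DataFrame
    manifest: dict


def _regional_rows(result_rows, scenario, pop, fractions, metrics_by_model,
                   region_ids, region_map):
    """Table-1-style regional summary: population, 69+ share, and the three
    metrics with their person-weighted exposures; ensemble median plus
    interquartile range across climate models."""
    for rid in region_ids:
        mask = region_map == rid
        total_pop = float(pop.total()[mask].sum())
        elderly = float(
            (np.nan_to_num(fractions.a_plus, nan=0.0) * pop.total())[mask].sum()
        )
        row = {
            "region": str(rid),
            "scenario": scenario,
            "population": total_pop,
            "share_69plus": elderly / total_pop if total_pop > 0 else np.nan,
        }
        for metric, surfaces in metrics_by_model.items():
            per_model_metric = []
            per_model_exposure = []
            for s in surfaces:
                summary = regional_summary(s, pop, fractions, "ge69", mask)
                per_model_metric.append(summary.median)
                exp = exposure_surface(s, pop, fractions, "ge69")
                per_model_exposure.append(float(exp.values[mask].sum()))
            pm = np.asarray(per_model_metric)
            pe = np.asarray(per_model_exposure)
            row[metric] = float(np.median(pm))
            row[f"{metric}_q25"], row[f"{metric}_q75"] = (
                float(np.percentile(pm, 25)), float(np.percentile(pm, 75))
            )
            name = EXPOSURE_NAMES[metric]
            row[name] = float(np.median(pe))
            row[f"{name}_q25"], row[f"{name}_q75"] = (
                float(np.percentile(pe, 25)), float(np.percentile(pe, 75))
            )
        result_rows.append(row)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage on one configuration; see module docstring."""
    syn = config.synthetic
    scenarios = config.scenario_list()
    log.info("pipeline: %d scenarios, %d models, grid %s",
             len(scenarios), config.n_models, syn.climate_geometry.shape)

    # --- demographic inputs and downscaling (fine grid) -------------------
    pop_inputs = generate_population_inputs(syn, perturbation=config.perturbation)
    base_fine = pop_inputs.base
    climate_geom = syn.climate_geometry
    base_aligned = align_population_to_climate_grid(base_fine, climate_geom)
    fractions = {BASE_YEAR_SCENARIO: age_fractions(base_aligned)}
    projected = {}
    for scen in scenarios:
        proj_fine, _, _ = downscale(
            base_fine, pop_inputs.total_projection[scen],
            pop_inputs.country_projection, scen, year=syn.target_year,
        )
        proj = align_population_to_climate_grid(proj_fine, climate_geom)
        projected[scen] = proj
        fractions[scen] = age_fractions(proj)

    # --- heat metrics per model and ensemble medians -----------------------
    metrics_by_model: dict = {}
    metrics: dict = {}
    for scen in (HISTORICAL, *scenarios):
        per_metric: dict = {"cdd": [], "tmax95": [], "hd": []}
        for m in range(config.n_models):
            epoch = generate_temperature_epoch(syn, scen, model_index=m)
            for name, surf in metric_surfaces(
                epoch, config.cdd_threshold, config.hot_day_threshold
            ).items():
                per_metric[name].append(surf)
        for name, surfs in per_metric.items():
            metrics_by_model[(scen, name)] = surfs
            metrics[(scen, name)] = ensemble_median(surfs)

    # --- exposure surfaces and regional tables -----------------------------
    region_map = base_aligned.country_id
    region_ids = list(base_aligned.countries())
    exposures: dict = {}
    exposure_rows = []
    regional_rows: list = []
    for scen in (BASE_YEAR_SCENARIO, *scenarios):
        pop = base_aligned if scen == BASE_YEAR_SCENARIO else projected[scen]
        climate_scen = HISTORICAL if scen == BASE_YEAR_SCENARIO else scen
        frac = fractions[scen]
        for metric in ("cdd", "tmax95", "hd"):
            surf = metrics[(climate_scen, metric)]
            exp = exposure_surface(surf, pop, frac, "ge69")
            # label by the demographic scenario, not the climate epoch
            exp.scenario = scen
            exposures[(scen, metric)] = exp
            exposure_rows.append(aggregate_regions(exp, region_map))
        _regional_rows(
            regional_rows, scen, pop, frac,
            {m: metrics_by_model[(climate_scen, m)] for m in ("cdd", "tmax95", "hd")},
            region_ids, region_map,
        )
    exposure_table = pd.concat(exposure_rows, ignore_index=True)
    regional_table = pd.DataFrame(regional_rows)

    # --- exceedance benchmark changes --------------------------------------
    exceed_rows = []
    for scen in scenarios:
        for metric, bench in config.exceedance_benchmarks.items():
            lo = min(bench, 0.0)
            grid = np.unique(np.append(np.linspace(lo, bench * 1.5 + 1.0, 61), bench))
            cur_base = exceedance_curve(
                metrics[(HISTORICAL, metric)], base_aligned,
                fractions[BASE_YEAR_SCENARIO], "ge69", grid,
            )
            cur_fut = exceedance_curve(
                metrics[(scen, metric)], projected[scen],
                fractions[scen], "ge69", grid,
            )
            exceed_rows.append({
                "scenario": scen,
                "metric": metric,
                "threshold": bench,
                "baseline_persons": cur_base.at(bench),
                "future_persons": cur_fut.at(bench),
                "change_persons": threshold_population_change(cur_fut, cur_base, bench),
            })
    exceedance_changes = pd.DataFrame(exceed_rows)

    # --- decomposition ------------------------------------------------------
    decomp_rows = []
    a0 = np.nan_to_num(fractions[BASE_YEAR_SCENARIO].a_plus, nan=0.0)
    n0 = base_aligned.total()
    for scen in scenarios:
        a1 = np.nan_to_num(fractions[scen].a_plus, nan=0.0)
        n1 = projected[scen].total()
        for metric in ("cdd", "tmax95", "hd"):
            h0 = metrics[(HISTORICAL, metric)].values
            h1 = metrics[(scen, metric)].values
            for rid in [*region_ids, "World"]:
                mask = (
                    np.ones_like(region_map, dtype=bool)
                    if rid == "World" else region_map == rid
                )
                try:
                    res = decompose(
                        a0[mask], n0[mask], h0[mask],
                        a1[mask], n1[mask], h1[mask],
                        scheme=config.weight_scheme, region=str(rid),
                        scenario=scen, family=EXPOSURE_NAMES[metric],
                    )
                except ValueError:
                    continue  # zero baseline exposure in this region/family
                decomp_rows.append({
                    "region": res.region, "scenario": scen,
                    "family": res.family, "scheme": res.scheme,
                    "eps_age": res.eps_age,
                    "eps_population": res.eps_population,
                    "eps_climate": res.eps_climate,
                    "emergent": res.emergent, "total": res.total,
                    "residual": res.residual,
                })
    decomposition_table = pd.DataFrame(decomp_rows)

    # --- weighted t-tests (69+ vs <69 CDD exposure) -------------------------
    ttest_rows = []
    for scen in scenarios:
        for rid in [*region_ids, "World"]:
            mask = (
                np.ones_like(region_map, dtype=bool)
                if rid == "World" else region_map == rid
            )
            try:
                t = regional_t_test(
                    metrics[(scen, "cdd")], projected[scen], fractions[scen], mask
                )
            except ValueError:
                continue
            ttest_rows.append({
                "region": str(rid), "scenario": scen, "metric": "cdd",
                "t": t.statistic, "pvalue": t.pvalue, "df": t.df,
                "mean_69plus": t.mean_a, "mean_below69": t.mean_b,
            })
    t_tests = pd.DataFrame(ttest_rows)

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": syn.seed,
        "scenarios": list(scenarios),
        "n_models": config.n_models,
        "artifacts": [],
    }
    result = PipelineResult(
        config=config,
        base_aligned=base_aligned,
        projected=projected,
        fractions=fractions,
        metrics=metrics,
        metrics_by_model=metrics_by_model,
        exposures=exposures,
        regional_table=regional_table,
        exposure_table=exposure_table,
        decomposition_table=decomposition_table,
        exceedance_changes=exceedance_changes,
        t_tests=t_tests,
        manifest=manifest,
    )
    if config.output_dir is not None:
        _write_outputs(result, Path(config.output_dir), pop_inputs)
    return result


def _write_outputs(result: PipelineResult, outdir: Path, pop_inputs) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = result.manifest["artifacts"]

    def _csv(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p, index=False, float_format="%.10g")
        artifacts.append(str(p))

    _csv(result.regional_table, "regional_summary.csv")
    _csv(result.exposure_table, "exposure_regional.csv")
    _csv(result.decomposition_table, "decomposition.csv")
    _csv(result.exceedance_changes, "exceedance_changes.csv")
    _csv(result.t_tests, "t_tests.csv")
    write_country_table(outdir / "country_projections.csv",
                        pop_inputs.country_projection)
    artifacts.append(str(outdir / "country_projections.csv"))
    geom = result.base_aligned.geometry
    for (scen, metric), surf in result.metrics.items():
        p = write_ascii_grid(outdir / f"metric_{metric}_{scen}.asc", surf.values, geom)
        artifacts.append(str(p))
    for (scen, metric), exp in result.exposures.items():
        p = write_ascii_grid(
            outdir / f"exposure_{EXPOSURE_NAMES[metric]}_{scen}.asc",
            exp.values, geom,
        )
        artifacts.append(str(p))
    for scen, frac in result.fractions.items():
        masked = np.ma.masked_invalid(frac.a_plus)
        p = write_ascii_grid(outdir / f"share69plus_{scen}.asc", masked, geom)
        artifacts.append(str(p))
    write_manifest(outdir / "manifest.json", result.manifest)
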