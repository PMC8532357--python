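"""End-to-end orchestration: data -> fluxes -> constrained model -> sampling
-> comparison reports, with a reproducibility manifest.

A run resolves its model (the built-in toy network or a file), derives the
extracellular flux table from time courses (or the built-in benchmark
scenario), applies the anaerobic recipe, fixes the measured fluxes per
strain x time (escalating the relaxation band on infeasibility), samples the
polytope per strain x time, and writes median tables, median-difference
rankings, per-time-point PCA, a Pearson clustergram and a JSON manifest
recording seeds, the config hash, relaxation bands used and timings.
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

from . import compare, enology, rates, sampling, synthetic
from .model import MetabolicModel, build_stoichiometric_system, read_model

logger = logging.getLogger(__name__)

DEFAULT_BAND_LADDER = (0.0, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    model: str = "toy"  # "toy" or a path (.json -> internal format, else SBML)
    series: str | dict[str, str] = "benchmark"  # "benchmark" or strain -> CSV path
    recipe: str | None = "toy"  # "toy", None, or a YAML path
    time_points: tuple[float, ...] = synthetic.DEFAULT_TIME_POINTS
    n_samples: int = 2000
    steps_per_sample: int | None = 30
    seed: int = 0
    k: int = 20
    rank_at: float | None = None  # default: first time point
    pca_scale: bool = True
    linkage_name: str = "average"
    cluster_on_top_k: bool = True
    band_ladder: tuple[float, ...] = DEFAULT_BAND_LADDER
    noise_cv: float = 0.002
    out_dir: str = "vinoflux_run"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config: dict
    config_hash: str
    outputs: dict[str, str] = field(default_factory=dict)  # name -> sha256
    seeds: dict[str, int] = field(default_factory=dict)
    bands_used: dict[str, float] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    status: str = "incomplete"
    failure_stage: str | None = None

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _resolve_model(config: RunConfig) -> MetabolicModel:
    if config.model == "toy":
        return synthetic.build_toy_wine_network()
    path = Path(config.model)
    if not path.exists():
        raise PipelineError(f"model file not found: {path}")
    fmt = "internal-json" if path.suffix == ".json" else "sbml"
    return read_model(str(path), fmt)


def _resolve_recipe(config: RunConfig) -> enology.AnaerobicRecipe | None:
    if config.recipe is None:
        return None
    if config.recipe == "toy":
        return synthetic.toy_anaerobic_recipe()
    return enology.read_recipe_yaml(config.recipe)


def _resolve_series(config: RunConfig) -> tuple[list[rates.FermentationSeries], dict[str, str]]:
    if config.series == "benchmark":
        model, scenario, _ = synthetic.make_benchmark_scenario(
            seed=config.seed, noise_cv=config.noise_cv
        )
        series = synthetic.simulate_strain_timeseries(model, scenario)
        return series, dict(scenario.compound_to_exchange)
    series = []
    for strain, path in config.series.items():
        if not Path(path).exists():
            raise PipelineError(f"series file not found: {path}")
        series.append(rates.read_series_csv(path, strain))
    return series, dict(synthetic.COMPOUND_TO_EXCHANGE)


def _derive_seed(base: int, index: int) -> int:
    return int(np.random.SeedSequence([base, index]).generate_state(1)[0] % 2**31)


def fix_with_band_ladder(
    model: MetabolicModel,
    cs: enology.ConstraintSet,
    ladder: tuple[float, ...],
) -> tuple[MetabolicModel, float]:
    """Fix measured fluxes, widening the relaxation band until feasible."""
    for band in ladder:
        constrained = enology.fix_exchange_fluxes(model, cs, band)
        feasible, _ = enology.check_feasibility(constrained)
        if feasible:
            if band > 0:
                logger.info(
                    "constraints for (%s, %g h) required band %.2f", cs.strain, cs.time_h, band
                )
            return constrained, band
    raise PipelineError(
        f"constraints infeasible for strain {cs.strain!r} at {cs.time_h} h even at "
        f"band {ladder[-1]}"
    )


def run_pipeline(config: RunConfig) -> RunManifest:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), config_hash=config.config_hash())
    manifest_path = out / "manifest.json"
    t_start = time.perf_counter()
    stage = "setup"

    def record(name: str, path: Path) -> None:
        manifest.outputs[name] = _sha256(path)

    try:
        model = _resolve_model(config)
        recipe = _resolve_recipe(config)
        if recipe is not None:
            model = enology.apply_anaerobic_modifications(model, recipe)

        stage = "flux_estimation"
        series, mapping = _resolve_series(config)
        mapping = {c: x for c, x in mapping.items() if model.has_reaction(x)}
        table = rates.build_flux_table(series, list(config.time_points), mapping)
        cpath = out / "constraints.csv"
        enology.write_constraints_csv(table.rows, str(cpath))
        record("constraints.csv", cpath)
        manifest.timings_s["flux_estimation"] = time.perf_counter() - t_start

        stage = "sampling"
        t0 = time.perf_counter()
        sample_sets: dict[tuple[str, float], sampling.SampleSet] = {}
        for idx, cs in enumerate(table.rows):
            constrained, band = fix_with_band_ladder(model, cs, config.band_ladder)
            manifest.bands_used[f"{cs.strain}@{cs.time_h}h"] = band
            system = build_stoichiometric_system(constrained)
            seed = _derive_seed(config.seed, idx)
            manifest.seeds[f"{cs.strain}@{cs.time_h}h"] = seed
            cfg = sampling.SamplerConfig(
                n_samples=config.n_samples,
                seed=seed,
                steps_per_sample=config.steps_per_sample,
            )
            ss = sampling.achr_sample(system, cfg, strain=cs.strain, time_h=cs.time_h)
            report = sampling.check_sample_validity(ss, system)
            if report.n_bound_violations:
                raise PipelineError(
                    f"sample validity failed for ({cs.strain}, {cs.time_h} h): "
                    f"{report.n_bound_violations} bound violations"
                )
            spath = out / f"samples_{cs.strain}_{cs.time_h:g}h.csv"
            sampling.write_sample_csv(ss, str(spath))
            record(spath.name, spath)
            sample_sets[(cs.strain, cs.time_h)] = ss
        manifest.timings_s["sampling"] = time.perf_counter() - t0

        stage = "comparison"
        t0 = time.perf_counter()
        strains = sorted({s for s, _ in sample_sets})
        rank_at = config.rank_at if config.rank_at is not None else config.time_points[0]
        median_tables: dict[float, compare.MedianTable] = {}
        for t in config.time_points:
            mt = compare.reaction_medians([sample_sets[(s, t)] for s in strains])
            median_tables[t] = mt
            mpath = out / f"medians_{t:g}h.csv"
            mt.to_frame().to_csv(mpath)
            record(mpath.name, mpath)

        ranking_abs = compare.rank_absolute_median_difference(median_tables[rank_at], config.k)
        ranking_pct = compare.rank_percent_median_difference(median_tables[rank_at], config.k)
        for ranking, name in ((ranking_abs, "absolute"), (ranking_pct, "percent")):
            rpath = out / f"ranking_{name}.csv"
            ranking.to_frame(model).to_csv(rpath, index=False)
            record(rpath.name, rpath)

        for t in config.time_points:
            mat, cols = _extracellular_matrix(table, strains, t)
            pca = compare.pca_with_cos2(
                mat, scale=config.pca_scale, variable_names=cols, observation_names=strains
            )
            ppath = out / f"pca_{t:g}h.csv"
            _pca_frame(pca).to_csv(ppath, index=False)
            record(ppath.name, ppath)

        subset = ranking_abs.reaction_ids() if config.cluster_on_top_k else None
        cluster = compare.cluster_strains(
            median_tables[rank_at], subset=subset, linkage_name=config.linkage_name
        )
        npath = out / "clustergram.newick"
        npath.write_text(cluster.to_newick() + "\n")
        record(npath.name, npath)
        corr_path = out / "strain_correlation.csv"
        pd.DataFrame(cluster.correlation, index=strains, columns=strains).to_csv(corr_path)
        record(corr_path.name, corr_path)
        manifest.timings_s["comparison"] = time.perf_counter() - t0

        manifest.status = "ok"
        return manifest
    except Exception as exc:
        manifest.status = "failed"
        manifest.failure_stage = f"{stage}: {exc}"
        raise
    finally:
        manifest.timings_s["total"] = time.perf_counter() - t_start
        manifest.write(manifest_path)


def _extracellular_matrix(
    table: rates.FluxTable, strains: list[str], time_h: float
) -> tuple[np.ndarray, list[str]]:
    """strains x variables matrix of measured exchange fluxes + growth rate."""
    rows = [table.row(s, time_h) for s in strains]
    cols = sorted(rows[0].fixed_exchanges)
    mat = np.array(
        [[cs.fixed_exchanges[c] for c in cols] + [cs.growth_rate or 0.0] for cs in rows]
    )
    return mat, cols + ["growth_rate"]


def _pca_frame(pca: compare.PcaResult) -> pd.DataFrame:
    recs = []
    ncomp = pca.scores.shape[1]
    for c in range(ncomp):
        recs.append(
            {"component": c + 1, "variance_explained": float(pca.variance_explained[c])}
        )
    frame = pd.DataFrame(recs)
    for i, name in enumerate(pca.observation_names):
        frame[f"score_{name}"] = pca.scores[i]
        frame[f"cos2_obs_{name}"] = pca.cos2_individuals[i]
    for j, name in enumerate(pca.variable_names):
        frame[f"loading_{name}"] = pca.loadings[j]
        frame[f"cos2_var_{name}"] = pca.cos2_variables[j]
    return frame
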