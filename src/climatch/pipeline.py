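"""End-to-end virtual-ecologist experiment orchestration.

Runs the full factorial experiment — species x dataset version x grid
resolution x sample x algorithm x fold assignment, optionally crossed
with future scenario x GCM x timeframe — through the stages:

    climate -> variables -> species -> samples -> blocks -> fit ->
    project -> compare -> factors

Every stage writes its artifacts (GeoTIFF grids, CSV tables, joblib model
bundles) under the output directory and registers them in a JSON run
manifest together with per-stage seeds and counts; re-running with
``resume=True`` reloads completed stages from disk and recomputes only
the missing ones. With a fixed master seed the whole run is deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
import yaml

from ._rng import spawn_seed, substream
from .factor_importance import assemble_outcomes, rf_factor_importance
from .grids import ClimateStack, read_geotiff, write_geotiff
from .hsm import HsmModel, ensemble_wmean, evaluate, permutation_importance, select_models
from .presets import SPECIES_PRESETS, SpeciesPreset, default_generator_config
from .projection import (
    ProjectionSet,
    median_projection,
    predicted_simulated_r,
    project,
    sample_future_differences,
    version_difference,
)
from .spatial_blocking import (
    assign_points_to_folds,
    build_correlogram,
    checkerboard_folds,
    choose_block_size,
    estimate_sac_range,
    full_data_residuals,
)
from .synthetic_climate import (
    GeneratorConfig,
    aggregate_resolution,
    consensus_variable_selection,
    generate_climate_pair,
    vif_stepwise,
)
from .virtual_species import (
    occurrence_probability,
    realize_presence_absence,
    sample_presabs,
    samples_from_csv,
    samples_to_csv,
    suitability_from_pca_niche,
    suitability_from_responses,
)

__all__ = ["ExperimentConfig", "RunManifest", "count_fits", "run_experiment", "smoke_config"]

logger = logging.getLogger("climatch.pipeline")

STAGES = (
    "climate",
    "variables",
    "species",
    "samples",
    "blocks",
    "fit",
    "project",
    "compare",
    "factors",
)


@dataclass
class ExperimentConfig:
    """Configuration of one full experiment."""

    species: Sequence[str] = ("alpine", "mediterranean", "generalist", "restricted")
    versions: Sequence[str] = ("A", "B")
    resolution_factors: Sequence[int] = (1, 2, 4)  # 1 = base grid
    n_samples: int = 50
    n_points: int = 300
    n_seed_presences: int = 500
    algorithms: Sequence[str] = ("glm", "gam", "gbm", "rf")
    fold_assignments: int = 2
    auc_min: float = 0.7
    tss_min: float = 0.4
    vif_threshold: float = 10.0
    vif_sample_points: int = 1000
    sac_algorithms: Sequence[str] = ("gam", "gbm")
    sac_n_samples: int = 3  # samples pooled for the residual correlograms
    sac_class_width: float = 100.0
    sac_eps: float = 0.05
    importance_n_perm: int = 5
    pred_sim_n_pixels: int = 10000
    pred_sim_n_sets: int = 50
    future_diff_n_pixels: int = 10000
    factor_rf_trees: int = 1000
    factor_rf_n_perm: int = 5
    master_seed: int = 0
    generator: GeneratorConfig | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_points < 1 or self.fold_assignments < 1:
            raise ValueError("all counts must be >= 1")
        if not (0 <= self.auc_min <= 1 and 0 <= self.tss_min <= 1):
            raise ValueError("discrimination thresholds must lie in [0, 1]")
        unknown = set(self.species) - set(SPECIES_PRESETS)
        if unknown:
            raise ValueError(f"unknown species presets: {sorted(unknown)}")

    def generator_config(self) -> GeneratorConfig:
        if self.generator is not None:
            return self.generator
        return default_generator_config(seed=spawn_seed(self.master_seed, "climate"))

    def resolution_tag(self, factor: int) -> str:
        return f"res{factor}"

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            d["generator"] = dataclasses.asdict(self.generator)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        gen = d.get("generator")
        if gen is not None:
            d["generator"] = GeneratorConfig(**gen)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(clean(self.to_dict()), fh, sort_keys=False)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def count_fits(config: ExperimentConfig) -> int:
    """Planned model fits per species:
    versions x resolutions x samples x algorithms x fold assignments."""
    return (
        len(config.versions)
        * len(config.resolution_factors)
        * config.n_samples
        * len(config.algorithms)
        * config.fold_assignments
    )


def smoke_config(master_seed: int = 0, species: Sequence[str] = ("alpine",)) -> ExperimentConfig:
    """Desk-scale configuration: 2 versions x 2 resolutions x 5 samples x
    4 algorithms x 2 assignments (160 fits per species) on a 60x60 grid."""
    return ExperimentConfig(
        species=tuple(species),
        resolution_factors=(1, 2),
        n_samples=5,
        sac_n_samples=2,
        vif_sample_points=400,
        pred_sim_n_pixels=2000,
        pred_sim_n_sets=10,
        future_diff_n_pixels=2000,
        factor_rf_trees=200,
        master_seed=master_seed,
        generator=default_generator_config(
            seed=spawn_seed(master_seed, "climate"),
            n_rows=60,
            n_cols=60,
            cell_size=20.0,
            scenarios=(),
            gcms=(),
        ),
    )


@dataclass
class RunManifest:
    """Provenance of one experiment run."""

    config_hash: str
    master_seed: int
    out_dir: str
    stage_seeds: dict[str, int] = field(default_factory=dict)
    stages_completed: list[str] = field(default_factory=list)
    artifacts: dict[str, list[str]] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    timestamps: dict[str, str] = field(default_factory=dict)

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    def register(self, stage: str, paths: Sequence[Path]) -> None:
        self.artifacts.setdefault(stage, [])
        for p in paths:
            self.artifacts[stage].append(str(p))

    def complete(self, stage: str) -> None:
        if stage not in self.stages_completed:
            self.stages_completed.append(stage)
        self.timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")


class _Run:
    """In-memory state threaded through the pipeline stages."""

    def __init__(self, config: ExperimentConfig, out_dir: Path, manifest: RunManifest):
        self.config = config
        self.out = out_dir
        self.manifest = manifest
        self.stacks: dict[tuple, ClimateStack] = {}  # (version, res, scen, gcm, tf)
        self.retained_variables: list[str] = []
        self.sim_prob = {}  # species -> OccProbMap (base resolution)
        self.samples = {}  # species -> list[PresAbsSample]
        self.block_designs = {}  # species -> (primary, complement)
        self.block_sizes = {}  # species -> km
        self.metrics = None  # DataFrame
        self.importance = None  # DataFrame
        self.ensembles = {}  # (species, version, res) -> {sample_id: model}
        self.medians = {}  # (species, version, res, scen, gcm, tf) -> ClimateGrid
        self.pred_sim = None  # DataFrame
        self.future_diff = None  # DataFrame


def _stack_key(version: str, res: str, scen: str = "current", gcm: str = "none", tf: str = "current"):
    return (version, res, scen, gcm, tf)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_climate(run: _Run) -> None:
    cfg = run.config
    gen = cfg.generator_config()
    pair = generate_climate_pair(gen)
    base_tag = cfg.resolution_tag(cfg.resolution_factors[0])

    current = {"A": pair.current_a, "B": pair.current_b}
    for factor in cfg.resolution_factors:
        tag = cfg.resolution_tag(factor)
        for version in cfg.versions:
            stack = current[version]
            if factor > 1:
                stack = aggregate_resolution(stack, factor, resolution_tag=tag)
            else:
                stack = dataclasses.replace(stack, resolution_tag=tag)
            run.stacks[_stack_key(version, tag)] = stack
        for (version, scen, gcm, tf), fut in pair.futures.items():
            if version not in cfg.versions:
                continue
            stack = fut
            if factor > 1:
                stack = aggregate_resolution(stack, factor, resolution_tag=tag)
            else:
                stack = dataclasses.replace(stack, resolution_tag=tag)
            run.stacks[_stack_key(version, tag, scen, gcm, tf)] = stack

    out = run.out / "climate"
    paths = []
    for stack in run.stacks.values():
        paths.extend(stack.write_dir(out))
    run.manifest.register("climate", paths)
    run.manifest.counts["n_climate_stacks"] = len(run.stacks)


def _load_climate(run: _Run) -> None:
    for stack in ClimateStack.read_dir(run.out / "climate"):
        run.stacks[
            _stack_key(
                stack.version_tag,
                stack.resolution_tag,
                stack.scenario_tag,
                stack.gcm_tag or "none",
                stack.timeframe_tag,
            )
        ] = stack


def _stage_variables(run: _Run) -> None:
    """Stepwise-VIF screening per version x resolution, consensus retention."""
    cfg = run.config
    seed = run.manifest.stage_seeds["variables"]
    reports = {}
    for version in cfg.versions:
        for factor in cfg.resolution_factors:
            tag = cfg.resolution_tag(factor)
            stack = run.stacks[_stack_key(version, tag)]
            table, _ = stack.to_table()
            rng = substream(seed, "vif", version, tag)
            n = min(cfg.vif_sample_points, table.shape[0])
            rows = rng.choice(table.shape[0], size=n, replace=False)
            df = pd.DataFrame(table[rows], columns=stack.variables)
            reports[(version, tag)] = vif_stepwise(df, threshold=cfg.vif_threshold)
    retained = consensus_variable_selection(reports)
    # keep the stack's variable order
    base = run.stacks[_stack_key(cfg.versions[0], cfg.resolution_tag(cfg.resolution_factors[0]))]
    run.retained_variables = [v for v in base.variables if v in retained]
    if not run.retained_variables:
        raise RuntimeError("variable screening retained no variables")
    path = run.out / "retained_variables.json"
    with open(path, "w") as fh:
        json.dump(
            {
                "retained": run.retained_variables,
                "per_combination": {
                    f"{v}_{t}": list(r.retained) for (v, t), r in reports.items()
                },
            },
            fh,
            indent=2,
        )
    run.manifest.register("variables", [path])


def _load_variables(run: _Run) -> None:
    with open(run.out / "retained_variables.json") as fh:
        run.retained_variables = json.load(fh)["retained"]


def _reference_stack(run: _Run) -> ClimateStack:
    """Species truth is simulated on version A at the finest resolution."""
    cfg = run.config
    return run.stacks[_stack_key("A", cfg.resolution_tag(cfg.resolution_factors[0]))]


def _stage_species(run: _Run) -> None:
    cfg = run.config
    seed = run.manifest.stage_seeds["species"]
    ref = _reference_stack(run)
    out = run.out / "species"
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in cfg.species:
        preset = SPECIES_PRESETS[name]
        if preset.niche_kind == "responses":
            hs = suitability_from_responses(ref, preset.responses)
        else:
            hs = suitability_from_pca_niche(ref, preset.pca_niche, seed=spawn_seed(seed, name, "pca"))
        prob = occurrence_probability(hs, preset.conversion)
        run.sim_prob[name] = prob
        for label, grid in (("hs", hs), ("prob", prob)):
            p = out / f"{name}_{label}.tif"
            write_geotiff(p, grid)
            paths.append(p)
    run.manifest.register("species", paths)


def _load_species(run: _Run) -> None:
    for name in run.config.species:
        run.sim_prob[name] = read_geotiff(
            run.out / "species" / f"{name}_prob.tif", "occurrence_probability"
        )


def _stage_samples(run: _Run) -> None:
    cfg = run.config
    seed = run.manifest.stage_seeds["samples"]
    out = run.out / "samples"
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in cfg.species:
        preset = SPECIES_PRESETS[name]
        pa = realize_presence_absence(run.sim_prob[name], seed=spawn_seed(seed, name, "pa"))
        samples = sample_presabs(
            pa,
            strategy=preset.sampling_strategy,
            buffer_km=preset.buffer_km,
            n_seed_presences=cfg.n_seed_presences,
            n_points=cfg.n_points,
            n_samples=cfg.n_samples,
            detection=preset.conversion.detection_prob,
            seed=spawn_seed(seed, name, "sampling"),
            species_tag=name,
        )
        run.samples[name] = samples
        p = out / f"{name}.csv"
        samples_to_csv(samples, p)
        paths.append(p)
    run.manifest.register("samples", paths)


def _load_samples(run: _Run) -> None:
    for name in run.config.species:
        run.samples[name] = samples_from_csv(run.out / "samples" / f"{name}.csv", name)


def _stage_blocks(run: _Run) -> None:
    cfg = run.config
    seed = run.manifest.stage_seeds["blocks"]
    ref = _reference_stack(run)
    out = run.out / "blocks"
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    block_sizes = {}
    for name in cfg.species:
        pooled = {alg: ([], [], []) for alg in cfg.sac_algorithms}
        for sample in run.samples[name][: cfg.sac_n_samples]:
            try:
                residuals = full_data_residuals(
                    sample,
                    ref,
                    algorithms=cfg.sac_algorithms,
                    variables=run.retained_variables,
                    seed=spawn_seed(seed, name, sample.sample_id),
                )
            except ValueError as exc:
                logger.warning("full-data fit skipped for %s sample %d: %s", name, sample.sample_id, exc)
                continue
            for alg, res in residuals.items():
                pooled[alg][0].append(res.x)
                pooled[alg][1].append(res.y)
                pooled[alg][2].append(res.residual)
        ranges = {}
        for alg, (xs, ys, rs) in pooled.items():
            if not xs:
                continue
            from .spatial_blocking import ResidualPoints

            res = ResidualPoints(
                np.concatenate(xs), np.concatenate(ys), np.concatenate(rs), alg
            )
            corr = build_correlogram(res, class_width=cfg.sac_class_width)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ranges[alg] = estimate_sac_range(corr, eps=cfg.sac_eps)
            p = out / f"correlogram_{name}_{alg}.csv"
            corr.to_frame().to_csv(p, index=False)
            paths.append(p)
        block_size = choose_block_size(ranges)
        block_sizes[name] = block_size
        primary, complement = checkerboard_folds(ref.spec, block_size)
        run.block_designs[name] = (primary, complement)
        p = out / f"blocks_{name}.csv"
        pd.concat([primary.to_frame(), complement.to_frame()]).to_csv(p, index=False)
        paths.append(p)
    run.block_sizes = block_sizes
    p = out / "block_sizes.json"
    with open(p, "w") as fh:
        json.dump(block_sizes, fh, indent=2)
    paths.append(p)
    run.manifest.register("blocks", paths)


def _load_blocks(run: _Run) -> None:
    with open(run.out / "blocks" / "block_sizes.json") as fh:
        run.block_sizes = json.load(fh)
    ref = _reference_stack(run)
    for name, size in run.block_sizes.items():
        run.block_designs[name] = checkerboard_folds(ref.spec, size)


def _stage_fit(run: _Run) -> None:
    cfg = run.config
    seed = run.manifest.stage_seeds["fit"]
    out_models = run.out / "models"
    out_models.mkdir(parents=True, exist_ok=True)
    metric_rows = []
    importance_rows = []
    n_attempted = n_fitted = 0
    assignments = ["primary", "complement"][: cfg.fold_assignments]

    for name in cfg.species:
        designs = dict(zip(["primary", "complement"], run.block_designs[name]))
        for version in cfg.versions:
            for factor in cfg.resolution_factors:
                tag = cfg.resolution_tag(factor)
                stack = run.stacks[_stack_key(version, tag)]
                key = (name, version, tag)
                run.ensembles[key] = {}
                for sample in run.samples[name]:
                    pts = sample.points
                    X_all = pd.DataFrame(
                        stack.values_at(
                            pts["x"].to_numpy(), pts["y"].to_numpy(), run.retained_variables
                        ),
                        columns=run.retained_variables,
                    )
                    y_all = pts["label"].to_numpy()
                    fitted = {}
                    metrics = {}
                    sample_rows = []
                    for assignment in assignments:
                        folds = assign_points_to_folds(
                            pts["x"].to_numpy(), pts["y"].to_numpy(), designs[assignment]
                        )
                        train = folds == 1
                        test = folds == 2
                        for alg in cfg.algorithms:
                            n_attempted += 1
                            mkey = (alg, assignment)
                            row = {
                                "species": name,
                                "version": version,
                                "resolution": tag,
                                "sample_id": sample.sample_id,
                                "assignment": assignment,
                                "algorithm": alg,
                            }
                            try:
                                if train.sum() == 0 or test.sum() == 0:
                                    raise ValueError("empty train or test fold")
                                model = HsmModel(
                                    algorithm=alg,
                                    random_state=spawn_seed(
                                        seed, name, version, tag, sample.sample_id, alg, assignment
                                    ),
                                ).fit(X_all[train], y_all[train])
                                pred = model.predict_suitability(X_all[test])
                                m = evaluate(pred, y_all[test])
                            except ValueError as exc:
                                logger.warning(
                                    "fit skipped (%s %s %s s%d %s %s): %s",
                                    name, version, tag, sample.sample_id, alg, assignment, exc,
                                )
                                row.update(
                                    rmse=np.nan, auc=np.nan, tss=np.nan,
                                    tss_threshold=np.nan, retained=False, status="degenerate",
                                )
                                metric_rows.append(row)
                                sample_rows.append(row)
                                continue
                            n_fitted += 1
                            fitted[mkey] = model
                            metrics[mkey] = m
                            row.update(
                                rmse=m.rmse, auc=m.auc, tss=m.tss,
                                tss_threshold=m.tss_threshold,
                                retained=False, status="ok",
                            )
                            metric_rows.append(row)
                            sample_rows.append(row)
                    retained_keys = select_models(metrics, cfg.auc_min, cfg.tss_min)
                    retained_set = set(retained_keys)
                    for row in sample_rows:
                        if row.get("status") == "ok":
                            row["retained"] = (row["algorithm"], row["assignment"]) in retained_set
                    if retained_keys:
                        ens = ensemble_wmean(
                            [fitted[k] for k in retained_keys],
                            [metrics[k].auc for k in retained_keys],
                        )
                        run.ensembles[key][sample.sample_id] = ens
                        imp = permutation_importance(
                            ens,
                            X_all,
                            n_perm=cfg.importance_n_perm,
                            seed=spawn_seed(seed, "imp", name, version, tag, sample.sample_id),
                        )
                        for _, r in imp.iterrows():
                            importance_rows.append(
                                {
                                    "species": name,
                                    "version": version,
                                    "resolution": tag,
                                    "sample_id": sample.sample_id,
                                    "ensemble_tag": ens.tag_,
                                    "variable": r["variable"],
                                    "std_imp": r["std_imp"],
                                }
                            )
                if run.ensembles[key]:
                    joblib.dump(
                        run.ensembles[key],
                        out_models / f"{name}_{version}_{tag}.joblib",
                    )

    run.metrics = pd.DataFrame(metric_rows)
    run.importance = pd.DataFrame(importance_rows)
    mpath = run.out / "metrics.csv"
    ipath = run.out / "importance.csv"
    run.metrics.to_csv(mpath, index=False)
    run.importance.to_csv(ipath, index=False)
    run.manifest.register("fit", [mpath, ipath] + sorted(out_models.glob("*.joblib")))
    run.manifest.counts.update(
        n_fit_attempts=n_attempted,
        n_fitted=n_fitted,
        n_planned_fits_per_species=count_fits(cfg),
        n_retained=int(run.metrics["retained"].sum()) if len(run.metrics) else 0,
        n_samples_with_model=sum(len(v) for v in run.ensembles.values()),
    )


def _load_fit(run: _Run) -> None:
    run.metrics = pd.read_csv(run.out / "metrics.csv")
    imp_path = run.out / "importance.csv"
    run.importance = pd.read_csv(imp_path) if imp_path.exists() else pd.DataFrame()
    cfg = run.config
    for name in cfg.species:
        for version in cfg.versions:
            for factor in cfg.resolution_factors:
                tag = cfg.resolution_tag(factor)
                p = run.out / "models" / f"{name}_{version}_{tag}.joblib"
                run.ensembles[(name, version, tag)] = joblib.load(p) if p.exists() else {}


def _stage_project(run: _Run) -> None:
    cfg = run.config
    out = run.out / "projections"
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    contexts = [("current", "none", "current")]
    gen = cfg.generator_config()
    for scen in gen.scenarios:
        for gcm in (gen.gcms or ["none"]):
            for tf in gen.timeframes:
                contexts.append((scen, gcm or "none", str(tf)))
    for (name, version, tag), models in run.ensembles.items():
        if not models:
            continue
        for scen, gcm, tf in contexts:
            stack = run.stacks.get(_stack_key(version, tag, scen, gcm, tf))
            if stack is None:
                continue
            ps = project(models, stack, variables=run.retained_variables)
            med = median_projection(ps)
            key = (name, version, tag, scen, gcm, tf)
            run.medians[key] = med
            p = out / f"median_{name}_{version}_{tag}_{scen}_{gcm}_{tf}.tif"
            write_geotiff(p, med)
            paths.append(p)
    run.manifest.register("project", paths)
    run.manifest.counts["n_median_grids"] = len(run.medians)


def _load_project(run: _Run) -> None:
    for p in sorted((run.out / "projections").glob("median_*.tif")):
        parts = p.stem.split("_")
        _, name, version, tag, scen, gcm, tf = parts
        run.medians[(name, version, tag, scen, gcm, tf)] = read_geotiff(p, "median_suitability")


def _stage_compare(run: _Run) -> None:
    cfg = run.config
    seed = run.manifest.stage_seeds["compare"]
    out = run.out / "compare"
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    # occurrence-probability truth per resolution (block-mean aggregated)
    sim_by_res: dict[tuple[str, str], object] = {}
    for name in cfg.species:
        prob = run.sim_prob[name]
        for factor in cfg.resolution_factors:
            tag = cfg.resolution_tag(factor)
            if factor == 1:
                sim_by_res[(name, tag)] = prob
            else:
                stack = ClimateStack({"occurrence_probability": prob})
                agg = aggregate_resolution(stack, factor, resolution_tag=tag)
                sim_by_res[(name, tag)] = agg["occurrence_probability"]

    pred_sim_rows = []
    future_rows = []
    for name in cfg.species:
        for factor in cfg.resolution_factors:
            tag = cfg.resolution_tag(factor)
            med_a = run.medians.get((name, "A", tag, "current", "none", "current"))
            med_b = run.medians.get((name, "B", tag, "current", "none", "current"))
            if med_a is not None and med_b is not None:
                diff = version_difference(med_b, med_a)
                p = out / f"diff_current_{name}_{tag}.tif"
                write_geotiff(p, diff)
                paths.append(p)
            for version, med in (("A", med_a), ("B", med_b)):
                if med is None:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rs = predicted_simulated_r(
                        med,
                        sim_by_res[(name, tag)],
                        n_pixels=cfg.pred_sim_n_pixels,
                        n_sets=cfg.pred_sim_n_sets,
                        seed=spawn_seed(seed, "psr", name, version, tag),
                    )
                for s, r in enumerate(rs):
                    pred_sim_rows.append(
                        {
                            "species_tag": name,
                            "version_tag": version,
                            "resolution_tag": tag,
                            "set": s,
                            "pred_sim_r": float(r),
                        }
                    )
            # future contexts
            gen = cfg.generator_config()
            for scen in gen.scenarios:
                for gcm in (gen.gcms or ["none"]):
                    for tf in gen.timeframes:
                        fa = run.medians.get((name, "A", tag, scen, gcm or "none", str(tf)))
                        fb = run.medians.get((name, "B", tag, scen, gcm or "none", str(tf)))
                        if fa is None or fb is None:
                            continue
                        fdiff = version_difference(fb, fa)
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            vals = sample_future_differences(
                                fdiff,
                                n_pixels=cfg.future_diff_n_pixels,
                                seed=spawn_seed(seed, "fd", name, tag, scen, gcm, tf),
                            )
                        for v in vals:
                            future_rows.append(
                                {
                                    "species_tag": name,
                                    "resolution_tag": tag,
                                    "scenario_tag": scen,
                                    "gcm_tag": gcm or "none",
                                    "timeframe_tag": str(tf),
                                    "future_diff": float(v),
                                }
                            )
    run.pred_sim = pd.DataFrame(pred_sim_rows)
    run.future_diff = pd.DataFrame(future_rows)
    p1 = out / "pred_sim_r.csv"
    run.pred_sim.to_csv(p1, index=False)
    paths.append(p1)
    if len(run.future_diff):
        p2 = out / "future_diff_samples.csv"
        run.future_diff.to_csv(p2, index=False)
        paths.append(p2)
    run.manifest.register("compare", paths)


def _load_compare(run: _Run) -> None:
    p1 = run.out / "compare" / "pred_sim_r.csv"
    run.pred_sim = pd.read_csv(p1) if p1.exists() else pd.DataFrame()
    p2 = run.out / "compare" / "future_diff_samples.csv"
    run.future_diff = pd.read_csv(p2) if p2.exists() else pd.DataFrame()


def _stage_factors(run: _Run) -> None:
    cfg = run.config
    seed = run.manifest.stage_seeds["factors"]
    out = run.out / "factors"
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    responses = {}
    if run.importance is not None and len(run.importance):
        responses["std_imp"] = run.importance.rename(
            columns={"species": "species_tag", "version": "version_tag", "resolution": "resolution_tag"}
        )
    if run.pred_sim is not None and len(run.pred_sim):
        responses["pred_sim_r"] = run.pred_sim
    if run.future_diff is not None and len(run.future_diff):
        responses["future_diff"] = run.future_diff
    for kind, records in responses.items():
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = assemble_outcomes(records, kind)
                result = rf_factor_importance(
                    table,
                    n_trees=cfg.factor_rf_trees,
                    n_perm=cfg.factor_rf_n_perm,
                    seed=spawn_seed(seed, kind),
                )
        except (ValueError, KeyError) as exc:
            logger.warning("factor importance skipped for %s: %s", kind, exc)
            continue
        p = out / f"factor_importance_{kind}.csv"
        result.table.to_csv(p, index=False)
        paths.append(p)
    run.manifest.register("factors", paths)


_STAGE_FUNCS = {
    "climate": (_stage_climate, _load_climate),
    "variables": (_stage_variables, _load_variables),
    "species": (_stage_species, _load_species),
    "samples": (_stage_samples, _load_samples),
    "blocks": (_stage_blocks, _load_blocks),
    "fit": (_stage_fit, _load_fit),
    "project": (_stage_project, _load_project),
    "compare": (_stage_compare, _load_compare),
    "factors": (_stage_factors, None),
}


def run_experiment(
    config: ExperimentConfig, out_dir: str | Path, resume: bool = False
) -> RunManifest:
    """Execute (or resume) the full experiment; returns the run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    manifest = None
    if resume and manifest_path.exists():
        manifest = RunManifest.load(manifest_path)
        if manifest.config_hash != config.config_hash():
            raise ValueError("cannot resume: output directory holds a different configuration")
    if manifest is None:
        manifest = RunManifest(
            config_hash=config.config_hash(),
            master_seed=config.master_seed,
            out_dir=str(out_dir),
            stage_seeds={s: spawn_seed(config.master_seed, "stage", s) for s in STAGES},
        )
    config.to_yaml(out_dir / "config.yaml")

    run = _Run(config, out_dir, manifest)
    for stage in STAGES:
        compute, load = _STAGE_FUNCS[stage]
        if resume and stage in manifest.stages_completed and load is not None:
            try:
                load(run)
                logger.info("stage %-9s loaded from disk", stage)
                continue
            except FileNotFoundError:
                logger.info("stage %-9s outputs missing; recomputing", stage)
                manifest.stages_completed.remove(stage)
                manifest.artifacts.pop(stage, None)
        t0 = time.time()
        try:
            compute(run)
        except Exception as exc:
            manifest.save(manifest_path)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.complete(stage)
        manifest.save(manifest_path)
        logger.info("stage %-9s done in %.1fs", stage, time.time() - t0)
    manifest.save(manifest_path)
    return manifest
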