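"""Self-contained desk-scale experiments on synthetic climate.

These functions re-run the study's headline analyses end to end at reduced
problem sizes: each generates its own paired climate versions and virtual
species, fits and gates suitability models on checkerboard folds, and
measures the quantity of interest. They are used by the acceptance
checks and are convenient entry points for exploring how the pipeline
behaves as the generator's parameters move.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import spawn_seed
from .grids import ClimateStack
from .hsm import HsmModel, ensemble_wmean, evaluate, permutation_importance, select_models
from .projection import median_projection, predicted_simulated_r, project, version_difference
from .spatial_blocking import (
    assign_points_to_folds,
    build_correlogram,
    checkerboard_folds,
    choose_block_size,
    estimate_sac_range,
    full_data_residuals,
)
from .synthetic_climate import GeneratorConfig, generate_climate_pair
from .virtual_species import (
    ConversionParams,
    ResponseFunction,
    occurrence_probability,
    realize_presence_absence,
    sample_presabs,
    suitability_from_responses,
)

__all__ = [
    "parameter_recovery",
    "mismatch_monotonicity",
    "fidelity_direction",
]


def _driver_pair(seed: int, driver_decorrelation: float, n_rows: int = 40) -> tuple:
    """Two-variable climate pair: a gradient-dominated driver variable and a
    weakly structured nuisance variable; only the driver decorrelates
    between versions."""
    cfg = GeneratorConfig(
        n_rows=n_rows,
        n_cols=n_rows,
        cell_size=20.0,
        origin_y=n_rows * 20.0,
        variable_names=("bio1", "bio2"),
        spatial_correlation_length=120.0,
        base_level={"bio1": 8.0, "bio2": 8.0},
        latitudinal_gradient_strength={"bio1": -8.0, "bio2": 1.0},
        anomaly_sd={"bio1": 2.5, "bio2": 1.5},
        between_version_decorrelation={"bio1": driver_decorrelation, "bio2": 0.05},
        seed=seed,
    )
    return generate_climate_pair(cfg)


def _driver_species(stack: ClimateStack, seed: int):
    """Single-driver virtual species: strong increasing sigmoid on bio1."""
    fn = ResponseFunction("increasing_sigmoid", "bio1", x0=8.0, s=1.5)
    hs = suitability_from_responses(stack, [fn])
    prob = occurrence_probability(hs, ConversionParams(alpha=-0.05, beta=0.5))
    pa = realize_presence_absence(prob, seed=seed)
    return hs, prob, pa


def _fit_gate_ensemble(
    samples,
    stack: ClimateStack,
    designs,
    algorithms=("glm",),
    seed: int = 0,
    auc_min: float = 0.7,
    tss_min: float = 0.4,
):
    """Fit algorithms on fold 1 of both assignments, gate on fold 2, and
    build the per-sample AUC-weighted ensemble. Returns {sample_id: model}."""
    variables = stack.variables
    ensembles = {}
    for sample in samples:
        pts = sample.points
        X = pd.DataFrame(
            stack.values_at(pts["x"].to_numpy(), pts["y"].to_numpy(), variables),
            columns=variables,
        )
        y = pts["label"].to_numpy()
        fitted, metrics = {}, {}
        for assignment, design in zip(("primary", "complement"), designs):
            folds = assign_points_to_folds(pts["x"].to_numpy(), pts["y"].to_numpy(), design)
            train, test = folds == 1, folds == 2
            for alg in algorithms:
                try:
                    model = HsmModel(
                        algorithm=alg,
                        random_state=spawn_seed(seed, sample.sample_id, alg, assignment),
                    ).fit(X[train], y[train])
                    m = evaluate(model.predict_suitability(X[test]), y[test])
                except ValueError:
                    continue
                fitted[(alg, assignment)] = model
                metrics[(alg, assignment)] = m
        retained = select_models(metrics, auc_min, tss_min)
        if retained:
            ensembles[sample.sample_id] = ensemble_wmean(
                [fitted[k] for k in retained], [metrics[k].auc for k in retained]
            )
    return ensembles


def _block_designs_from_residuals(samples, stack, seed):
    """SAC-range-based checkerboard designs, as in the full pipeline."""
    res = full_data_residuals(samples[0], stack, algorithms=("glm",), seed=seed)["glm"]
    corr = build_correlogram(res, class_width=100.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sac = estimate_sac_range(corr)
    return checkerboard_folds(stack.spec, choose_block_size([sac]))


def parameter_recovery(
    seed: int = 0,
    n_samples: int = 20,
    n_points: int = 300,
    algorithms=("glm", "gbm"),
) -> dict:
    """Fraction of retained per-sample models whose top importance variable
    is the species' true driver.

    A single-driver species (strong sigmoid on one variable) is simulated
    and sampled; models are fitted on checkerboard folds, gated, ensembled
    per sample, and scored with standardized permutation importance.
    """
    pair = _driver_pair(seed, driver_decorrelation=0.05, n_rows=50)
    stack = pair.current_a
    _, _, pa = _driver_species(stack, seed=spawn_seed(seed, "pa"))
    samples = sample_presabs(
        pa, n_points=n_points, n_samples=n_samples, detection=1.0, seed=spawn_seed(seed, "samp")
    )
    designs = _block_designs_from_residuals(samples, stack, seed)
    ensembles = _fit_gate_ensemble(samples, stack, designs, algorithms, seed=seed)
    top_hits = 0
    for sid, ens in ensembles.items():
        pts = samples[sid].points
        X = pd.DataFrame(
            stack.values_at(pts["x"].to_numpy(), pts["y"].to_numpy(), stack.variables),
            columns=stack.variables,
        )
        imp = permutation_importance(ens, X, n_perm=5, seed=spawn_seed(seed, "imp", sid))
        top = imp.loc[imp["std_imp"].idxmax(), "variable"]
        top_hits += top == "bio1"
    n_models = len(ensembles)
    return {
        "n_samples": n_samples,
        "n_retained_models": n_models,
        "recovery_rate": top_hits / n_models if n_models else np.nan,
    }


def mismatch_monotonicity(
    seed: int = 0,
    levels=(0.0, 0.25, 0.5, 0.75, 1.0),
    n_seeds: int = 10,
    n_samples: int = 4,
) -> dict:
    """Between-version mismatch versus driver decorrelation.

    For each decorrelation level of the driver variable and each replicate
    seed, models are fitted separately on the two climate versions and the
    median |difference| between the two median prediction grids is
    measured; the association between level and mismatch is summarized by
    a Spearman trend over all (level, replicate) pairs.
    """
    rows = []
    for level in levels:
        for rep in range(n_seeds):
            rep_seed = spawn_seed(seed, "mm", level, rep)
            pair = _driver_pair(rep_seed, driver_decorrelation=level)
            _, _, pa = _driver_species(pair.current_a, seed=spawn_seed(rep_seed, "pa"))
            samples = sample_presabs(
                pa, n_points=300, n_samples=n_samples, detection=1.0,
                seed=spawn_seed(rep_seed, "samp"),
            )
            designs = _block_designs_from_residuals(samples, pair.current_a, rep_seed)
            medians = {}
            for version, stack in (("A", pair.current_a), ("B", pair.current_b)):
                ensembles = _fit_gate_ensemble(samples, stack, designs, seed=rep_seed)
                if not ensembles:
                    break
                ps = project(ensembles, stack)
                medians[version] = median_projection(ps)
            if len(medians) < 2:
                continue
            diff = version_difference(medians["B"], medians["A"])
            rows.append(
                {"level": level, "replicate": rep, "median_abs_diff": float(np.median(np.abs(diff.values)))}
            )
    table = pd.DataFrame(rows)
    rho, pval = stats.spearmanr(table["level"], table["median_abs_diff"])
    # one-sided p for a positive trend
    p_one_sided = pval / 2 if rho > 0 else 1 - pval / 2
    return {
        "table": table,
        "spearman_rho": float(rho),
        "p_one_sided": float(p_one_sided),
        "n_runs": len(table),
    }


def fidelity_direction(
    seed: int = 0,
    n_seeds: int = 10,
    driver_decorrelation: float = 0.8,
    n_samples: int = 4,
) -> dict:
    """Predicted-simulated correlation: generating version vs decorrelated one.

    The species truth is simulated on version A; models fitted on A should
    track the simulated occurrence probability better than models fitted
    on a strongly decorrelated version B. Returns the per-seed medians and
    a one-sided sign test on the number of seeds where r_A > r_B.
    """
    wins = 0
    r_a_all, r_b_all = [], []
    for rep in range(n_seeds):
        rep_seed = spawn_seed(seed, "fid", rep)
        pair = _driver_pair(rep_seed, driver_decorrelation=driver_decorrelation)
        _, prob, pa = _driver_species(pair.current_a, seed=spawn_seed(rep_seed, "pa"))
        samples = sample_presabs(
            pa, n_points=300, n_samples=n_samples, detection=1.0,
            seed=spawn_seed(rep_seed, "samp"),
        )
        designs = _block_designs_from_residuals(samples, pair.current_a, rep_seed)
        med_r = {}
        for version, stack in (("A", pair.current_a), ("B", pair.current_b)):
            ensembles = _fit_gate_ensemble(samples, stack, designs, seed=rep_seed)
            if not ensembles:
                break
            med = median_projection(project(ensembles, stack))
            rs = predicted_simulated_r(
                med, prob, n_pixels=800, n_sets=10, seed=spawn_seed(rep_seed, "psr", version)
            )
            med_r[version] = float(np.median(rs))
        if len(med_r) < 2:
            continue
        r_a_all.append(med_r["A"])
        r_b_all.append(med_r["B"])
        wins += med_r["A"] > med_r["B"]
    n = len(r_a_all)
    p = float(stats.binomtest(wins, n, 0.5, alternative="greater").pvalue) if n else np.nan
    return {
        "n_seeds": n,
        "wins_generating_version": wins,
        "median_r_generating": float(np.median(r_a_all)) if n else np.nan,
        "median_r_decorrelated": float(np.median(r_b_all)) if n else np.nan,
        "p_one_sided": p,
    }
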