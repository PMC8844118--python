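"""Projection of retained models and between-version mismatch diagnostics.

Retained per-sample models (ensembles or single models) are projected over
a climate stack to per-sample suitability grids; the per-cell median
across samples summarizes each version x resolution x scenario context.
Mismatch between dataset versions is then the per-cell difference of the
two median grids (B - A), and fidelity to the simulation truth is the
Pearson correlation between median predicted suitability and the
simulated occurrence probability, computed on repeated random pixel
samples (predicted-simulated r). A hexagonal heatmap summary of the
(simulated, predicted) plane supports the standard visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .grids import ClimateGrid, ClimateStack, GridSpec, OccProbMap

__all__ = [
    "ProjectionSet",
    "HexbinSummary",
    "project",
    "median_projection",
    "version_difference",
    "predicted_simulated_r",
    "sample_future_differences",
    "hexbin_summary",
]


@dataclass
class ProjectionSet:
    """Per-sample suitability grids sharing one GridSpec, plus context tags."""

    grids: dict[int, ClimateGrid]
    version_tag: str = "A"
    resolution_tag: str = "base"
    scenario_tag: str = "current"
    gcm_tag: str | None = None
    timeframe_tag: str = "current"

    def __post_init__(self) -> None:
        specs = [g.spec for g in self.grids.values()]
        for s in specs[1:]:
            if s != specs[0]:
                raise ValueError("projection grids must share one GridSpec")

    @property
    def spec(self) -> GridSpec:
        return next(iter(self.grids.values())).spec

    @property
    def n_samples(self) -> int:
        return len(self.grids)


def project(models: dict[int, object], stack: ClimateStack, variables=None) -> ProjectionSet:
    """Predict suitability on every unmasked cell for each sample's model."""
    spec = stack.spec
    first = next(iter(models.values()), None)
    if first is None:
        raise ValueError("no models to project")
    variables = list(variables) if variables is not None else getattr(first, "variables_", None)
    if variables is None:
        variables = stack.variables
    missing = [v for v in variables if v not in stack]
    if missing:
        raise KeyError(f"stack is missing model variables: {missing}")
    table, idx = stack.to_table(variables)
    X = pd.DataFrame(table, columns=variables)
    grids = {}
    for sample_id, model in models.items():
        pred = model.predict_suitability(X)
        values = np.zeros(spec.shape).ravel()
        values[idx] = pred
        grids[sample_id] = ClimateGrid(spec, values.reshape(spec.shape), "suitability")
    return ProjectionSet(
        grids=grids,
        version_tag=stack.version_tag,
        resolution_tag=stack.resolution_tag,
        scenario_tag=stack.scenario_tag,
        gcm_tag=stack.gcm_tag,
        timeframe_tag=stack.timeframe_tag,
    )


def median_projection(ps: ProjectionSet) -> ClimateGrid:
    """Per-cell median across samples (even counts: mean of the central two)."""
    if ps.n_samples == 0:
        raise ValueError("empty projection set")
    stack = np.stack([g.values for g in ps.grids.values()])
    med = np.median(stack, axis=0)
    med = np.where(ps.spec.mask, 0.0, med)
    return ClimateGrid(ps.spec, med, "median_suitability")


def version_difference(median_b: ClimateGrid, median_a: ClimateGrid) -> ClimateGrid:
    """Per-cell difference of median predictions, version B minus version A."""
    if median_b.spec != median_a.spec:
        raise ValueError("median grids must share one GridSpec")
    diff = median_b.values - median_a.values
    diff = np.where(median_b.spec.mask, 0.0, diff)
    return ClimateGrid(median_b.spec, diff, "version_difference")


def _pixel_sample(spec: GridSpec, n_pixels: int, rng: np.random.Generator) -> np.ndarray:
    idx = np.flatnonzero(~spec.mask.ravel())
    if idx.size < n_pixels:
        import warnings

        warnings.warn(
            f"only {idx.size} unmasked pixels available for a sample of {n_pixels}; using all",
            stacklevel=3,
        )
        return idx
    return rng.choice(idx, size=n_pixels, replace=False)


def predicted_simulated_r(
    median_grid: ClimateGrid,
    sim_prob: OccProbMap,
    n_pixels: int = 10000,
    n_sets: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Pearson r between median predicted suitability and simulated
    occurrence probability, per seeded random pixel sample (without
    replacement within a set, independent across sets)."""
    if median_grid.spec != sim_prob.spec:
        raise ValueError("grids must share one GridSpec")
    pred = median_grid.values.ravel()
    sim = sim_prob.values.ravel()
    out = np.empty(n_sets)
    for s in range(n_sets):
        rng = substream(seed, "pred_sim_r", s)
        idx = _pixel_sample(median_grid.spec, n_pixels, rng)
        a, b = pred[idx], sim[idx]
        if a.std() == 0 or b.std() == 0:
            raise ValueError("zero variance in a sampled vector; correlation undefined")
        out[s] = np.corrcoef(a, b)[0, 1]
    return out


def sample_future_differences(
    diff_grid: ClimateGrid, n_pixels: int = 10000, seed: int = 0
) -> np.ndarray:
    """Seeded uniform sample of between-version difference values."""
    idx = _pixel_sample(diff_grid.spec, n_pixels, substream(seed, "future_diff"))
    if idx.size == 0:
        raise ValueError("empty unmasked extent")
    return diff_grid.values.ravel()[idx]


@dataclass
class HexbinSummary:
    """Hexagonal binning of the (simulated, predicted) unit plane.

    Flat-top hexagons of the given width (corner-to-corner), grid origin
    at (0, 0); ``table`` holds axial coordinates, count and log10(count),
    ``slope``/``intercept`` the least-squares line predicted ~ simulated.
    """

    table: pd.DataFrame
    cell_width: float
    slope: float
    intercept: float
    total: int


def _hex_axial(x: np.ndarray, y: np.ndarray, size: float) -> tuple[np.ndarray, np.ndarray]:
    """Axial (q, r) of the flat-top hexagon containing each point."""
    qf = (2.0 / 3.0) * x / size
    rf = (-1.0 / 3.0) * x / size + (np.sqrt(3.0) / 3.0) * y / size
    # cube rounding
    xf, zf = qf, rf
    yf = -xf - zf
    rx, ry, rz = np.round(xf), np.round(yf), np.round(zf)
    dx, dy, dz = np.abs(rx - xf), np.abs(ry - yf), np.abs(rz - zf)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)
    return rx.astype(int), rz.astype(int)


def hexbin_summary(
    pred_grid: ClimateGrid, sim_grid: ClimateGrid, cell_width: float = 0.04
) -> HexbinSummary:
    """Bin unmasked (simulated, predicted) pairs into hexagonal cells."""
    if pred_grid.spec != sim_grid.spec:
        raise ValueError("grids must share one GridSpec")
    keep = ~pred_grid.spec.mask
    sim = sim_grid.values[keep].ravel()
    pred = pred_grid.values[keep].ravel()
    if sim.size == 0:
        raise ValueError("empty unmasked extent")
    size = cell_width / 2.0  # flat-top: width = 2 * size
    q, r = _hex_axial(sim, pred, size)
    counts = (
        pd.DataFrame({"hex_q": q, "hex_r": r})
        .groupby(["hex_q", "hex_r"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    counts["log10_count"] = np.log10(counts["count"])
    if np.ptp(sim) > 0:  # ptp, not std: rounding can make std of a constant tiny-positive
        from scipy.stats import linregress

        fit = linregress(sim, pred)
        slope, intercept = fit.slope, fit.intercept
    else:
        slope, intercept = 0.0, float(np.mean(pred))
    return HexbinSummary(
        table=counts,
        cell_width=cell_width,
        slope=float(slope),
        intercept=float(intercept),
        total=int(sim.size),
    )
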