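"""Synthetic paired climate-surface generator and between-version diagnostics.

The generator emulates the situation where the same bioclimatic variables
are published in two *versions* of a gridded climate dataset that agree on
the broad geography but disagree locally: each variable is a deterministic
north-south gradient plus a spatially autocorrelated anomaly field, and
version B reuses version A's anomaly mixed with an independent field in
proportion to a per-variable decorrelation parameter ``d``:

    A = base + gradient + f_A
    B = base + gradient + sqrt(1 - d) * f_A + sqrt(d) * f_B

with f_A, f_B independent unit-variance smoothed-noise fields, so ``d``
maps monotonically onto the between-version correlation of the anomaly
(r = sqrt(1 - d) on the anomaly component). Future-scenario stacks add a
per-scenario mean shift plus a GCM-specific autocorrelated perturbation.

The module also carries the standard predictor-screening and comparison
steps: block-mean aggregation to coarser grids, bilinear resampling,
temperature unit rescaling, stepwise VIF selection, and the two
between-version correlation diagnostics (pairwise r on stratified random
point sets, and focal-window local r maps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from ._rng import substream
from .grids import ClimateGrid, ClimateStack, GridSpec

__all__ = [
    "GeneratorConfig",
    "ClimatePair",
    "VifReport",
    "CorrelationDiagnostics",
    "generate_climate_pair",
    "aggregate_resolution",
    "resample_bilinear",
    "rescale_temperature_units",
    "vif_stepwise",
    "consensus_variable_selection",
    "pairwise_between_version_r",
    "local_focal_r",
]

# Timeframe scaling of the scenario mean shift: the nearer horizon realizes
# half of the full-scenario shift, the farther one all of it.
_TIMEFRAME_FRACTION = {"2050": 0.5, "2070": 1.0}


def _per_variable(value, names: Sequence[str], what: str) -> dict[str, float]:
    """Broadcast a scalar or mapping to a per-variable dict."""
    if isinstance(value, Mapping):
        out = {n: float(value.get(n, 0.0)) for n in names}
    else:
        out = {n: float(value) for n in names}
    return out


@dataclass
class GeneratorConfig:
    """Parameters of the paired-version climate generator.

    Units: kilometres for lengths, variable units for levels and shifts.
    ``between_version_decorrelation`` is the per-variable mixing weight
    ``d`` in [0, 1]: 0 makes the two versions identical, 1 makes their
    anomaly fields independent.
    """

    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 20.0  # km
    origin_x: float = 0.0
    origin_y: float = 2000.0
    variable_names: Sequence[str] = ("bio1", "bio2", "bio4", "bio8", "bio15", "bio18", "bio19")
    spatial_correlation_length: float = 200.0  # km, Gaussian kernel bandwidth
    base_level: Mapping[str, float] | float = 0.0
    latitudinal_gradient_strength: Mapping[str, float] | float = 1.0
    anomaly_sd: Mapping[str, float] | float = 1.0
    between_version_decorrelation: Mapping[str, float] | float = 0.1
    scenarios: Sequence[str] = ()
    scenario_shift: Mapping[str, Mapping[str, float] | float] = field(default_factory=dict)
    gcms: Sequence[str] = ()
    timeframes: Sequence[str] = ("2050", "2070")
    gcm_perturbation_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid dimensions must be at least 2x2")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.gcm_perturbation_sd < 0:
            raise ValueError("gcm_perturbation_sd must be >= 0")
        names = list(self.variable_names)
        d = _per_variable(self.between_version_decorrelation, names, "decorrelation")
        for name, val in d.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"decorrelation for {name} outside [0, 1]: {val}")

    @property
    def names(self) -> list[str]:
        return list(self.variable_names)

    def grid_spec(self) -> GridSpec:
        return GridSpec(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size,
        )


@dataclass
class ClimatePair:
    """The two current-climate versions plus their future variants."""

    current_a: ClimateStack
    current_b: ClimateStack
    futures: dict[tuple[str, str, str, str], ClimateStack] = field(default_factory=dict)
    # keyed by (version_tag, scenario_tag, gcm_tag, timeframe_tag)

    def current(self, version: str) -> ClimateStack:
        return self.current_a if version == "A" else self.current_b


def _smooth_field(rng: np.random.Generator, spec: GridSpec, corr_length_km: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated field: Gaussian-smoothed white
    noise with kernel bandwidth = correlation length."""
    noise = rng.standard_normal(spec.shape)
    sigma_cells = corr_length_km / spec.cell_size
    if sigma_cells > 0:
        smoothed = ndimage.gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    else:
        smoothed = noise
    sd = smoothed.std()
    if sd > 0:
        smoothed = smoothed / sd
    return smoothed


def generate_climate_pair(config: GeneratorConfig) -> ClimatePair:
    """Generate version A and B stacks plus future-scenario variants.

    Deterministic given ``config.seed``: every random field is drawn from a
    named substream, so regenerating is bit-identical.
    """
    spec = config.grid_spec()
    names = config.names
    base = _per_variable(config.base_level, names, "base_level")
    grad = _per_variable(config.latitudinal_gradient_strength, names, "gradient")
    amp = _per_variable(config.anomaly_sd, names, "anomaly_sd")
    decor = _per_variable(config.between_version_decorrelation, names, "decorrelation")

    # northness in [-1, 1]: +1 at the top (north) row, -1 at the bottom.
    northness = 1.0 - 2.0 * (np.arange(config.n_rows) + 0.5) / config.n_rows
    northness = northness[:, None] * np.ones((1, config.n_cols))

    grids_a, grids_b = {}, {}
    for name in names:
        f_a = _smooth_field(substream(config.seed, "field", name, "A"), spec, config.spatial_correlation_length)
        f_b = _smooth_field(substream(config.seed, "field", name, "B"), spec, config.spatial_correlation_length)
        d = decor[name]
        deterministic = base[name] + grad[name] * northness
        grids_a[name] = ClimateGrid(spec, deterministic + amp[name] * f_a, name)
        mixed = np.sqrt(1.0 - d) * f_a + np.sqrt(d) * f_b
        grids_b[name] = ClimateGrid(spec, deterministic + amp[name] * mixed, name)

    current_a = ClimateStack(grids_a, version_tag="A")
    current_b = ClimateStack(grids_b, version_tag="B")

    futures: dict[tuple[str, str, str, str], ClimateStack] = {}
    gcms = list(config.gcms) or [None]
    for scenario in config.scenarios:
        shift = _per_variable(config.scenario_shift.get(scenario, 0.0), names, "shift")
        for gcm in gcms:
            for tf in config.timeframes:
                frac = _TIMEFRAME_FRACTION.get(str(tf), 1.0)
                # GCM perturbation is shared between versions: it represents
                # the climate model, not the dataset version.
                pert = {}
                for name in names:
                    if config.gcm_perturbation_sd > 0 and gcm is not None:
                        f = _smooth_field(
                            substream(config.seed, "gcm", gcm, scenario, tf, name),
                            spec,
                            config.spatial_correlation_length,
                        )
                        pert[name] = config.gcm_perturbation_sd * f
                    else:
                        pert[name] = 0.0
                for version, cur in (("A", current_a), ("B", current_b)):
                    grids = {
                        name: ClimateGrid(
                            spec, cur[name].values + frac * shift[name] + pert[name], name
                        )
                        for name in names
                    }
                    futures[(version, scenario, gcm or "none", str(tf))] = ClimateStack(
                        grids,
                        version_tag=version,
                        scenario_tag=scenario,
                        gcm_tag=gcm,
                        timeframe_tag=str(tf),
                    )
    return ClimatePair(current_a, current_b, futures)


def aggregate_resolution(stack: ClimateStack, factor: int, resolution_tag: str | None = None) -> ClimateStack:
    """Block-mean aggregation to a grid ``factor`` times coarser.

    Trailing partial blocks (when ``factor`` does not divide the dims) are
    averaged over their available cells; masked cells are excluded from
    block means, and blocks with no unmasked cell are masked.
    """
    if factor < 2:
        raise ValueError("aggregation factor must be >= 2")
    spec = stack.spec
    row_idx = np.arange(0, spec.n_rows, factor)
    col_idx = np.arange(0, spec.n_cols, factor)
    mask = spec.mask
    counts = np.add.reduceat(np.add.reduceat((~mask).astype(float), row_idx, 0), col_idx, 1)
    out_mask = counts == 0

    new_spec = GridSpec(
        n_rows=len(row_idx),
        n_cols=len(col_idx),
        origin_x=spec.origin_x,
        origin_y=spec.origin_y,
        cell_size=spec.cell_size * factor,
        nodata_mask=out_mask if out_mask.any() else None,
    )
    new_grids = {}
    for name, grid in stack.grids.items():
        vals = np.where(mask, 0.0, grid.values)
        sums = np.add.reduceat(np.add.reduceat(vals, row_idx, 0), col_idx, 1)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        new_grids[name] = ClimateGrid(new_spec, means, name)
    return replace(stack, grids=new_grids,
                   resolution_tag=resolution_tag or f"{stack.resolution_tag}x{factor}")


def resample_bilinear(stack: ClimateStack, target: GridSpec) -> ClimateStack:
    """Resample every grid to ``target`` by bilinear interpolation between
    source cell centres; outside the source centre hull the nearest-edge
    value is used. Masked source cells propagate (any target cell whose
    interpolation stencil touches a masked source cell is masked)."""
    src = stack.spec
    sx0, sx1, sy0, sy1 = src.extent
    tx0, tx1, ty0, ty1 = target.extent
    if sx1 <= tx0 or tx1 <= sx0 or sy1 <= ty0 or ty1 <= sy0:
        raise ValueError("source and target extents are disjoint")

    # RegularGridInterpolator wants ascending axes: flip rows (y descending).
    ys = src.y_centers[::-1]
    xs = src.x_centers
    tx = np.clip(target.x_centers, xs[0], xs[-1])
    ty = np.clip(target.y_centers, ys[0], ys[-1])
    pts_y, pts_x = np.meshgrid(ty, tx, indexing="ij")
    query = np.column_stack([pts_y.ravel(), pts_x.ravel()])

    new_grids = {}
    out_mask = None
    for name, grid in stack.grids.items():
        vals = np.where(src.mask, np.nan, grid.values)[::-1, :]
        interp = RegularGridInterpolator((ys, xs), vals, method="linear", bounds_error=False)
        out = interp(query).reshape(target.shape)
        grid_mask = ~np.isfinite(out)
        out_mask = grid_mask if out_mask is None else (out_mask | grid_mask)
        new_grids[name] = (np.where(grid_mask, 0.0, out), name)

    new_spec = GridSpec(
        n_rows=target.n_rows,
        n_cols=target.n_cols,
        origin_x=target.origin_x,
        origin_y=target.origin_y,
        cell_size=target.cell_size,
        nodata_mask=out_mask if out_mask is not None and out_mask.any() else None,
    )
    grids = {name: ClimateGrid(new_spec, vals, name) for name, (vals, _) in new_grids.items()}
    return replace(stack, grids=grids)


def rescale_temperature_units(
    stack: ClimateStack, variables: set[str], divisor: float = 10.0
) -> ClimateStack:
    """Divide the listed (temperature) variables by ``divisor`` — the unit
    harmonization needed when one dataset version reports tenths of a
    degree. Stateless: applying twice divides twice."""
    unknown = set(variables) - set(stack.variables)
    if unknown:
        raise KeyError(f"unknown variables: {sorted(unknown)}")
    return stack.map_values(lambda v: v / divisor, variables=set(variables))


# ---------------------------------------------------------------------------
# Collinearity screening
# ---------------------------------------------------------------------------


@dataclass
class VifReport:
    """Outcome of stepwise variance-inflation-factor selection."""

    vif: dict[str, float]  # final VIF of each retained variable
    retained: tuple[str, ...]
    dropped: tuple[str, ...]  # in removal order
    threshold: float


def _vifs(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 - R^2_j) from regressing column j on the others,
    on standardized columns. Exact collinearity yields inf."""
    n, p = X.shape
    if p == 1:
        return np.array([1.0])
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(yj @ yj)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        if r2 >= 1.0 - 1e-12:
            out[j] = np.inf
        else:
            out[j] = 1.0 / (1.0 - r2)
    return out


def vif_stepwise(data: pd.DataFrame, threshold: float = 10.0) -> VifReport:
    """Iteratively drop the highest-VIF variable until all VIFs <= threshold."""
    data = pd.DataFrame(data)
    if data.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    if data.shape[0] <= data.shape[1]:
        raise ValueError("need more points than variables")
    sds = data.std(ddof=1)
    constants = sds.index[sds == 0].tolist()
    if constants:
        raise ValueError(f"constant columns (undefined R^2): {constants}")

    cols = list(data.columns)
    X = ((data - data.mean()) / sds).to_numpy()
    dropped: list[str] = []
    while len(cols) >= 2:
        vifs = _vifs(X)
        worst = int(np.argmax(vifs))
        if vifs[worst] <= threshold:
            break
        dropped.append(cols.pop(worst))
        X = np.delete(X, worst, axis=1)
    final = _vifs(X) if len(cols) >= 1 else np.array([])
    return VifReport(
        vif={c: float(v) for c, v in zip(cols, final)},
        retained=tuple(cols),
        dropped=tuple(dropped),
        threshold=threshold,
    )


def consensus_variable_selection(
    reports: Mapping[object, VifReport], n_combinations: int | None = None
) -> set[str]:
    """Variables retained in strictly more than half of the version x
    resolution combinations."""
    if not reports:
        raise ValueError("empty report map")
    n = n_combinations if n_combinations is not None else len(reports)
    counts: dict[str, int] = {}
    for rep in reports.values():
        for v in rep.retained:
            counts[v] = counts.get(v, 0) + 1
    return {v for v, c in counts.items() if c > n / 2}


# ---------------------------------------------------------------------------
# Between-version correlation diagnostics
# ---------------------------------------------------------------------------


@dataclass
class CorrelationDiagnostics:
    """Pairwise r per point set (rows) x variable (columns), and optional
    local focal-r grids per variable."""

    pairwise_r: pd.DataFrame
    local_r: dict[str, ClimateGrid] = field(default_factory=dict)


def _stratified_points(
    spec: GridSpec, n_points: int, rng: np.random.Generator, max_tries: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """One uniform point per stratum of a regular k x k grid (k^2 ~ n_points),
    redrawn within the stratum if it lands on a masked cell."""
    k = max(2, int(np.ceil(np.sqrt(n_points))))
    n_unmasked = int((~spec.mask).sum())
    if n_unmasked < k * k:
        raise ValueError(f"fewer unmasked cells ({n_unmasked}) than strata ({k * k})")
    xmin, xmax, ymin, ymax = spec.extent
    sw = (xmax - xmin) / k
    sh = (ymax - ymin) / k
    xs, ys = [], []
    for i in range(k):
        for j in range(k):
            for _ in range(max_tries):
                x = xmin + (j + rng.uniform()) * sw
                y = ymin + (i + rng.uniform()) * sh
                row, col = spec.cell_of(np.array([x]), np.array([y]))
                r, c = int(row[0]), int(col[0])
                if 0 <= r < spec.n_rows and 0 <= c < spec.n_cols and not spec.mask[r, c]:
                    xs.append(x)
                    ys.append(y)
                    break
    return np.asarray(xs), np.asarray(ys)


def pairwise_between_version_r(
    stack_a: ClimateStack,
    stack_b: ClimateStack,
    n_points: int = 100,
    n_sets: int = 50,
    seed: int = 0,
) -> CorrelationDiagnostics:
    """Pearson r per variable between the two versions, on ``n_sets``
    stratified-random point sets (one point per regular stratum)."""
    if stack_a.spec != stack_b.spec:
        raise ValueError("stacks must share one GridSpec")
    if n_points < 3:
        raise ValueError("need at least 3 points")
    spec = stack_a.spec
    variables = stack_a.variables
    rows = []
    for s in range(n_sets):
        rng = substream(seed, "pairwise_r", s)
        x, y = _stratified_points(spec, n_points, rng)
        va = stack_a.values_at(x, y, variables)
        vb = stack_b.values_at(x, y, variables)
        row = {}
        for j, name in enumerate(variables):
            a, b = va[:, j], vb[:, j]
            if a.std() == 0 or b.std() == 0:
                row[name] = np.nan
            else:
                row[name] = float(np.corrcoef(a, b)[0, 1])
        rows.append(row)
    return CorrelationDiagnostics(pairwise_r=pd.DataFrame(rows, columns=variables))


def local_focal_r(grid_a: ClimateGrid, grid_b: ClimateGrid, window: int = 5) -> ClimateGrid:
    """Per-cell Pearson r between two grids over a window x window focal
    neighborhood (truncated at edges). Cells whose neighborhood has zero
    variance in either grid, and masked cells, are masked in the output."""
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if grid_a.spec != grid_b.spec:
        raise ValueError("grids must share one GridSpec")
    spec = grid_a.spec
    valid = (~spec.mask).astype(float)
    a = np.where(spec.mask, 0.0, grid_a.values)
    b = np.where(spec.mask, 0.0, grid_b.values)
    kernel = np.ones((window, window))

    def boxsum(arr: np.ndarray) -> np.ndarray:
        return ndimage.correlate(arr, kernel, mode="constant", cval=0.0)

    n = boxsum(valid)
    sa, sb = boxsum(a), boxsum(b)
    saa, sbb, sab = boxsum(a * a), boxsum(b * b), boxsum(a * b)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_a = n * saa - sa**2
        var_b = n * sbb - sb**2
        cov = n * sab - sa * sb
        denom = np.sqrt(var_a * var_b)
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
    tol = 1e-9 * np.maximum(1.0, n * np.maximum(saa, sbb))
    out_mask = spec.mask | (n < 2) | (var_a <= tol) | (var_b <= tol)
    out_spec = GridSpec(
        n_rows=spec.n_rows,
        n_cols=spec.n_cols,
        origin_x=spec.origin_x,
        origin_y=spec.origin_y,
        cell_size=spec.cell_size,
        nodata_mask=out_mask if out_mask.any() else None,
    )
    values = np.where(out_mask, 0.0, np.clip(r, -1.0, 1.0))
    return ClimateGrid(out_spec, values, f"local_r_{grid_a.variable_name}")
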