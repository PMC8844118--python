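"""Residual spatial autocorrelation and checkerboard block cross-validation.

Habitat suitability models validated on randomly withheld points that sit
inside the residual spatial-autocorrelation (SAC) range of the training
points report inflated skill. The remedy implemented here follows the
standard block-CV recipe: fit full-data models, build a Moran's I
correlogram of their residuals over contiguous distance classes, read off
the SAC range (first class where I drops to ~0), add a 100 km safety
margin to get the block size, tile the extent with square blocks of that
size, and assign blocks to two folds in a checkerboard pattern (plus the
complementary assignment with folds swapped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .grids import GridSpec

__all__ = [
    "ResidualPoints",
    "Correlogram",
    "BlockDesign",
    "morans_i",
    "morans_i_distance_class",
    "build_correlogram",
    "estimate_sac_range",
    "choose_block_size",
    "checkerboard_folds",
    "assign_points_to_folds",
    "full_data_residuals",
    "CheckerboardCV",
]

BLOCK_MARGIN_KM = 100.0  # added to the SAC range when choosing block size


@dataclass
class ResidualPoints:
    """Residuals (observed 0/1 - predicted suitability) at training points."""

    x: np.ndarray
    y: np.ndarray
    residual: np.ndarray
    source_model: str = "model"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.residual = np.asarray(self.residual, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.residual)):
            raise ValueError("x, y, residual must have equal length")
        if not np.all(np.isfinite(self.residual)):
            raise ValueError("residuals must be finite")


@dataclass
class Correlogram:
    """Moran's I per contiguous distance class; NaN where undefined."""

    class_edges: np.ndarray  # length n_classes + 1, starting at 0
    morans_i: np.ndarray
    pair_count: np.ndarray

    @property
    def class_center(self) -> np.ndarray:
        return 0.5 * (self.class_edges[:-1] + self.class_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class_center_km": self.class_center,
                "morans_I": self.morans_i,
                "pair_count": self.pair_count,
            }
        )


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I with an explicit (symmetric, zero-diagonal) weight matrix.

    I = (n / S0) * sum_ij w_ij (x_i - m)(x_j - m) / sum_i (x_i - m)^2
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 values")
    if w.shape != (n, n):
        raise ValueError("weight matrix shape mismatch")
    dev = x - x.mean()
    ss = float(dev @ dev)
    if ss == 0:
        raise ValueError("zero variance in values")
    s0 = float(w.sum())
    if s0 == 0:
        raise ValueError("no weighted pairs")
    num = float(dev @ w @ dev)
    return (n / s0) * num / ss


def morans_i_distance_class(
    values: np.ndarray, coords: np.ndarray, d_lo: float, d_hi: float
) -> float:
    """Moran's I with indicator weights w_ij = 1 iff d_lo <= dist(i,j) < d_hi."""
    coords = np.asarray(coords, dtype=float)
    dmat = squareform(pdist(coords))
    w = ((dmat >= d_lo) & (dmat < d_hi)).astype(float)
    np.fill_diagonal(w, 0.0)
    return morans_i(values, w)


def build_correlogram(
    res: ResidualPoints,
    class_width: float = 100.0,
    max_distance: float | None = None,
) -> Correlogram:
    """Moran's I of residuals over contiguous distance classes from 0.

    ``max_distance`` defaults to half the diagonal of the point bounding
    box. Classes with fewer than 2 point pairs (or degenerate variance)
    are masked (NaN)."""
    if class_width <= 0:
        raise ValueError("class_width must be > 0")
    if len(res.residual) < 10:
        raise ValueError("need at least 10 points")
    coords = np.column_stack([res.x, res.y])
    if max_distance is None:
        dx = res.x.max() - res.x.min()
        dy = res.y.max() - res.y.min()
        max_distance = 0.5 * float(np.hypot(dx, dy))
    n_classes = max(1, int(np.ceil(max_distance / class_width)))
    edges = np.arange(n_classes + 1) * class_width

    dmat = squareform(pdist(coords))
    dev = res.residual - res.residual.mean()
    ss = float(dev @ dev)
    n = len(dev)
    i_vals = np.full(n_classes, np.nan)
    counts = np.zeros(n_classes, dtype=int)
    cross = np.outer(dev, dev)
    for k in range(n_classes):
        w = (dmat >= edges[k]) & (dmat < edges[k + 1])
        np.fill_diagonal(w, False)
        s0 = int(w.sum())
        counts[k] = s0 // 2  # unordered pairs
        if counts[k] >= 2 and ss > 0:
            i_vals[k] = (n / s0) * float(cross[w].sum()) / ss
    return Correlogram(class_edges=edges, morans_i=i_vals, pair_count=counts)


def estimate_sac_range(c: Correlogram, eps: float = 0.05) -> float:
    """Distance at which residual autocorrelation has decayed: the centre of
    the first defined class with I <= eps. If I never drops to eps within
    the correlogram, the maximum distance is returned with a warning."""
    defined = np.flatnonzero(np.isfinite(c.morans_i))
    if defined.size == 0:
        raise ValueError("correlogram has no defined classes")
    centers = c.class_center
    for k in defined:
        if c.morans_i[k] <= eps:
            return float(centers[k])
    max_distance = float(c.class_edges[-1])
    warnings.warn(
        f"Moran's I never dropped to {eps}; returning max distance {max_distance}",
        stacklevel=2,
    )
    return max_distance


def choose_block_size(sac_ranges: Mapping[str, float] | Sequence[float]) -> float:
    """Conservative block size: max SAC range over algorithms + 100 km."""
    values = list(sac_ranges.values()) if isinstance(sac_ranges, Mapping) else list(sac_ranges)
    values = [v for v in values if np.isfinite(v)]
    if not values:
        raise ValueError("need at least one finite SAC range")
    return float(max(values)) + BLOCK_MARGIN_KM


@dataclass
class BlockDesign:
    """Checkerboard assignment of square spatial blocks to two folds.

    Blocks tile the extent from its origin (top-left); fold of block
    (row, col) is ((row + col) mod 2) + 1 for the primary assignment and
    the swap for the complement.
    """

    block_size: float
    n_block_rows: int
    n_block_cols: int
    origin_x: float
    origin_y: float
    assignment_id: str = "primary"

    def fold_of_block(self, block_row: np.ndarray, block_col: np.ndarray) -> np.ndarray:
        parity = (np.asarray(block_row) + np.asarray(block_col)) % 2
        fold = parity + 1
        if self.assignment_id == "complement":
            fold = 3 - fold
        return fold

    def complement(self) -> "BlockDesign":
        other = "complement" if self.assignment_id == "primary" else "primary"
        return BlockDesign(
            self.block_size,
            self.n_block_rows,
            self.n_block_cols,
            self.origin_x,
            self.origin_y,
            assignment_id=other,
        )

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.meshgrid(
            np.arange(self.n_block_rows), np.arange(self.n_block_cols), indexing="ij"
        )
        return pd.DataFrame(
            {
                "block_row": rows.ravel(),
                "block_col": cols.ravel(),
                "fold": self.fold_of_block(rows, cols).ravel(),
                "assignment_id": self.assignment_id,
            }
        )


def checkerboard_folds(spec: GridSpec, block_size: float) -> tuple[BlockDesign, BlockDesign]:
    """Tile the extent with square blocks and return both the primary
    checkerboard assignment and its fold-swapped complement."""
    if block_size <= 0:
        raise ValueError("block_size must be > 0")
    xmin, xmax, ymin, ymax = spec.extent
    n_block_cols = int(np.ceil((xmax - xmin) / block_size))
    n_block_rows = int(np.ceil((ymax - ymin) / block_size))
    if max(n_block_rows, n_block_cols) < 2:
        raise ValueError("extent must cover at least 2 blocks along one axis")
    primary = BlockDesign(block_size, n_block_rows, n_block_cols, xmin, ymax)
    return primary, primary.complement()


def assign_points_to_folds(
    x: np.ndarray, y: np.ndarray, design: BlockDesign
) -> np.ndarray:
    """Fold label per point, inherited from the containing block.

    Blocks are half-open [start, start + size) in both axes, measured
    rightward in x and downward from the top edge in y, so a point exactly
    on a shared edge belongs to the lower-index block.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    col = np.floor((x - design.origin_x) / design.block_size).astype(int)
    row = np.floor((design.origin_y - y) / design.block_size).astype(int)
    # points exactly on the far extent edge fall in the last block
    col = np.where((col == design.n_block_cols) & np.isclose(x, design.origin_x + design.n_block_cols * design.block_size), col - 1, col)
    row = np.where((row == design.n_block_rows) & np.isclose(y, design.origin_y - design.n_block_rows * design.block_size), row - 1, row)
    bad = (col < 0) | (col >= design.n_block_cols) | (row < 0) | (row >= design.n_block_rows)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} points fall outside the blocked extent")
    return design.fold_of_block(row, col)


class CheckerboardCV:
    """Minimal CV-splitter view of the two checkerboard assignments.

    ``split(x, y)`` yields one (train_idx, test_idx) pair per assignment:
    train on fold 1, test on fold 2 (the complement assignment swaps which
    spatial blocks play each role). Compatible with manual CV loops and
    with estimators from this package.
    """

    def __init__(self, design: BlockDesign):
        self.design = design

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return 2

    def split(self, x: np.ndarray, y: np.ndarray):
        for design in (self.design, self.design.complement()):
            folds = assign_points_to_folds(x, y, design)
            train = np.flatnonzero(folds == 1)
            test = np.flatnonzero(folds == 2)
            yield train, test


def full_data_residuals(
    sample,
    stack,
    algorithms: Sequence[str] = ("gam", "gbm"),
    variables: Sequence[str] | None = None,
    seed: int = 0,
) -> dict[str, ResidualPoints]:
    """Residuals of full-data models (fit on every point of the sample),
    per algorithm — the input to the correlogram/SAC-range step."""
    from .hsm import HsmModel  # deferred: avoids a module cycle

    pts = sample.points
    y = pts["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("sample has a single class; cannot fit full-data models")
    variables = list(variables) if variables is not None else stack.variables
    X = pd.DataFrame(
        stack.values_at(pts["x"].to_numpy(), pts["y"].to_numpy(), variables),
        columns=variables,
    )
    out = {}
    for alg in algorithms:
        model = HsmModel(algorithm=alg, random_state=seed)
        model.fit(X, y)
        pred = model.predict_suitability(X)
        out[alg] = ResidualPoints(
            x=pts["x"].to_numpy(),
            y=pts["y"].to_numpy(),
            residual=y - pred,
            source_model=alg,
        )
    return out
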