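"""Planar gridded climate surfaces.

All rasters live on an abstract planar kilometre grid: axis-aligned square
cells, cell-centre value convention, row 0 at the top (north), origin at
the top-left corner of the top-left cell. A :class:`GridSpec` carries the
geometry plus an optional nodata mask; a :class:`ClimateGrid` is one named
variable on a spec; a :class:`ClimateStack` bundles the variables of one
dataset version / resolution / scenario combination.

GeoTIFF I/O is single-band float64 per variable, with the geotransform
encoded through the standard ModelPixelScale / ModelTiepoint tags and
nodata through the GDAL nodata tag.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import tifffile

__all__ = [
    "GridSpec",
    "ClimateGrid",
    "ClimateStack",
    "read_geotiff",
    "write_geotiff",
]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class GridSpec:
    """Geometry shared by every grid in a stack.

    ``origin_x``/``origin_y`` locate the top-left *corner* of cell (0, 0);
    x grows eastward, y grows northward, so row indices increase toward
    the south. ``nodata_mask`` is True on cells that carry no data.
    """

    n_rows: int
    n_cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is not None:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != (self.n_rows, self.n_cols):
                raise ValueError("nodata_mask shape does not match grid dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def mask(self) -> np.ndarray:
        """Boolean nodata mask (all-False when none was given)."""
        if self.nodata_mask is None:
            return np.zeros(self.shape, dtype=bool)
        return self.nodata_mask

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        """Cell-centre y coordinates, row 0 first (northmost, largest y)."""
        return self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the outer grid edges."""
        return (
            self.origin_x,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_y,
        )

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point (half-open cells)."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def center_of(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def same_geometry(self, other: "GridSpec") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.origin_x, other.origin_x)
            and math.isclose(self.origin_y, other.origin_y)
            and math.isclose(self.cell_size, other.cell_size)
        )

    def __eq__(self, other: object) -> bool:  # mask-aware equality
        if not isinstance(other, GridSpec):
            return NotImplemented
        return self.same_geometry(other) and np.array_equal(self.mask, other.mask)


@dataclass
class ClimateGrid:
    """One variable's values on a :class:`GridSpec`."""

    spec: GridSpec
    values: np.ndarray
    variable_name: str = "var"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.spec.shape}"
            )
        unmasked = self.values[~self.spec.mask]
        if unmasked.size and not np.all(np.isfinite(unmasked)):
            raise ValueError(f"non-finite values on unmasked cells of {self.variable_name!r}")

    @property
    def unmasked_values(self) -> np.ndarray:
        return self.values[~self.spec.mask]

    def with_values(self, values: np.ndarray) -> "ClimateGrid":
        return ClimateGrid(self.spec, values, self.variable_name)


# Value-level aliases used by the virtual-species layer: suitability and
# occurrence-probability maps are grids bounded to [0, 1]; presence-absence
# maps hold {0, 1}.
SuitabilityMap = ClimateGrid
OccProbMap = ClimateGrid
PresAbsMap = ClimateGrid


@dataclass
class ClimateStack:
    """Named variables sharing one GridSpec, tagged with provenance."""

    grids: dict[str, ClimateGrid]
    version_tag: str = "A"
    resolution_tag: str = "base"
    scenario_tag: str = "current"
    gcm_tag: str | None = None
    timeframe_tag: str = "current"

    def __post_init__(self) -> None:
        specs = [g.spec for g in self.grids.values()]
        if not specs:
            raise ValueError("stack must contain at least one grid")
        for g in specs[1:]:
            if g != specs[0]:
                raise ValueError("all grids in a stack must share one GridSpec")
        for name, g in self.grids.items():
            if g.variable_name != name:
                raise ValueError(f"grid registered under {name!r} is named {g.variable_name!r}")

    @property
    def spec(self) -> GridSpec:
        return next(iter(self.grids.values())).spec

    @property
    def variables(self) -> list[str]:
        return list(self.grids)

    def __getitem__(self, name: str) -> ClimateGrid:
        return self.grids[name]

    def __contains__(self, name: str) -> bool:
        return name in self.grids

    def __iter__(self) -> Iterator[str]:
        return iter(self.grids)

    def map_values(self, fn, variables: set[str] | None = None) -> "ClimateStack":
        """New stack with ``fn(values)`` applied to the listed variables."""
        new = {}
        for name, g in self.grids.items():
            if variables is None or name in variables:
                new[name] = g.with_values(fn(g.values))
            else:
                new[name] = g
        return replace(self, grids=new)

    def to_table(self, variables: list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(n_unmasked, p) value matrix and the flat indices of those cells."""
        variables = variables or self.variables
        keep = ~self.spec.mask
        idx = np.flatnonzero(keep.ravel())
        mat = np.column_stack([self.grids[v].values.ravel()[idx] for v in variables])
        return mat, idx

    def values_at(self, x: np.ndarray, y: np.ndarray, variables: list[str] | None = None) -> np.ndarray:
        """(n_points, p) matrix of cell values at the given coordinates."""
        variables = variables or self.variables
        row, col = self.spec.cell_of(x, y)
        return np.column_stack([self.grids[v].values[row, col] for v in variables])

    # -- GeoTIFF interface ------------------------------------------------

    def file_stem(self, variable: str) -> str:
        gcm = self.gcm_tag or "none"
        return f"{self.version_tag}_{self.resolution_tag}_{self.scenario_tag}_{gcm}_{self.timeframe_tag}_{variable}"

    def write_dir(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, grid in self.grids.items():
            path = directory / f"{self.file_stem(name)}.tif"
            write_geotiff(path, grid)
            paths.append(path)
        return paths

    @classmethod
    def read_dir(cls, directory: str | Path, pattern: str = "*.tif") -> list["ClimateStack"]:
        """Read every GeoTIFF under ``directory`` and regroup into stacks by
        the tag fields encoded in the file names."""
        groups: dict[tuple, dict[str, ClimateGrid]] = {}
        for path in sorted(Path(directory).glob(pattern)):
            m = re.match(r"(.+?)_(.+?)_(.+?)_(.+?)_(.+?)_(.+)$", path.stem)
            if not m:
                raise ValueError(f"unrecognized stack file name: {path.name}")
            version, res, scen, gcm, tf, var = m.groups()
            grid = read_geotiff(path, variable_name=var)
            groups.setdefault((version, res, scen, gcm, tf), {})[var] = grid
        stacks = []
        for (version, res, scen, gcm, tf), grids in groups.items():
            stacks.append(
                cls(
                    grids=grids,
                    version_tag=version,
                    resolution_tag=res,
                    scenario_tag=scen,
                    gcm_tag=None if gcm == "none" else gcm,
                    timeframe_tag=tf,
                )
            )
        return stacks


def write_geotiff(path: str | Path, grid: ClimateGrid) -> None:
    """Write one single-band float64 GeoTIFF; masked cells become NaN.

    Float64 keeps write -> read -> recompute cycles bit-identical, which
    the resumable pipeline relies on."""
    values = grid.values.astype(np.float64).copy()
    values[grid.spec.mask] = np.nan
    spec = grid.spec
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (spec.cell_size, spec.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.origin_x, spec.origin_y, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, "nan"),
    ]
    tifffile.imwrite(path, values, extratags=extratags)


def read_geotiff(path: str | Path, variable_name: str | None = None) -> ClimateGrid:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        scale = page.tags[_TAG_PIXEL_SCALE].value
        tie = page.tags[_TAG_TIEPOINT].value
    mask = ~np.isfinite(values)
    values = np.where(mask, 0.0, values)
    spec = GridSpec(
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        origin_x=float(tie[3]),
        origin_y=float(tie[4]),
        cell_size=float(scale[0]),
        nodata_mask=mask if mask.any() else None,
    )
    name = variable_name if variable_name is not None else Path(path).stem
    return ClimateGrid(spec, values, name)
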