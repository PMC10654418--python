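"""Planar raster grids and a plain-text raster codec.

Environmental predictors live on a shared axis-aligned grid in projected
metric coordinates.  Layers are float arrays with NaN as nodata, stored
row 0 = northernmost row (the usual raster convention).  On disk each
layer is one ESRI ASCII grid (``.asc``): a six-line header followed by
the value matrix, which keeps every artifact human-readable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an axis-aligned raster: ``x0, y0`` is the lower-left
    corner, cells are square with side ``cell_size`` meters."""

    n_rows: int
    n_cols: int
    cell_size: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(f"grid dimensions must be positive, got {self.n_rows}x{self.n_cols}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate arrays, shaped (n_rows, n_cols)."""
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y0 + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col) with half-open cell
        intervals [edge, next_edge): a point on a shared edge belongs to
        the higher-index cell along that axis.  Returns (row, col,
        inside) where ``inside`` flags points within the extent."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row_from_bottom = np.floor((y - self.y0) / self.cell_size).astype(int)
        row = self.n_rows - 1 - row_from_bottom
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return row, col, inside


@dataclass
class EnvStack:
    """Named, aligned raster layers sharing one :class:`GridSpec`."""

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = (self.grid.n_rows, self.grid.n_cols)
        for name, arr in self.layers.items():
            if arr.shape != shape:
                raise ValueError(f"layer {name!r} has shape {arr.shape}, grid expects {shape}")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def sample(self, x: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
        """Nearest-cell values of every layer at the given points;
        points outside the extent yield NaN."""
        row, col, inside = self.grid.index_of(x, y)
        out: dict[str, np.ndarray] = {}
        r = np.where(inside, row, 0)
        c = np.where(inside, col, 0)
        for name, arr in self.layers.items():
            vals = arr[r, c].astype(float)
            vals[~inside] = np.nan
            out[name] = vals
        return out


def write_ascii_grid(path: str | Path, grid: GridSpec, values: np.ndarray) -> None:
    """Write one layer as an ESRI ASCII grid; NaN becomes the NODATA code."""
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_rows, grid.n_cols):
        raise ValueError("array shape does not match grid")
    body = np.where(np.isnan(values), NODATA, values)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x0!r}\n"
        f"yllcorner {grid.y0!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for r in range(grid.n_rows):
            fh.write(" ".join(repr(float(v)) for v in body[r]) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    with open(path) as fh:
        head: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        grid = GridSpec(
            n_rows=int(head["nrows"]),
            n_cols=int(head["ncols"]),
            cell_size=head["cellsize"],
            x0=head["xllcorner"],
            y0=head["yllcorner"],
        )
        values = np.loadtxt(fh, dtype=float, ndmin=2)
    if values.shape != (grid.n_rows, grid.n_cols):
        raise ValueError(f"{path}: body shape {values.shape} does not match header")
    nodata = head.get("nodata_value", NODATA)
    values[values == nodata] = np.nan
    return grid, values


def write_env_stack(stack: EnvStack, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in stack.layers.items():
        p = out_dir / f"{name}.asc"
        write_ascii_grid(p, stack.grid, arr)
        paths.append(p)
    return paths


def read_env_stack(paths: Iterable[str | Path] | str | Path) -> EnvStack:
    """Assemble an :class:`EnvStack` from ``.asc`` files (a directory or an
    explicit list).  Layers must agree on grid geometry; a mismatch is
    rejected with a report naming every differing field."""
    if isinstance(paths, (str, Path)) and Path(paths).is_dir():
        paths = sorted(Path(paths).glob("*.asc"))
    else:
        paths = [Path(p) for p in np.atleast_1d(paths)]  # type: ignore[arg-type]
    if not paths:
        raise ValueError("no .asc layers found")
    layers: dict[str, np.ndarray] = {}
    ref_grid: GridSpec | None = None
    ref_name = ""
    for p in paths:
        grid, values = read_ascii_grid(p)
        name = Path(p).stem
        if ref_grid is None:
            ref_grid, ref_name = grid, name
        elif grid != ref_grid:
            diffs = [
                f"{f}: {getattr(ref_grid, f)} ({ref_name}) vs {getattr(grid, f)} ({name})"
                for f in ("n_rows", "n_cols", "cell_size", "x0", "y0")
                if not math.isclose(float(getattr(ref_grid, f)), float(getattr(grid, f)))
            ]
            raise ValueError("misaligned raster layers: " + "; ".join(diffs))
        layers[name] = values
    assert ref_grid is not None
    return EnvStack(grid=ref_grid, layers=layers)


def stack_from_arrays(grid: GridSpec, arrays: Mapping[str, np.ndarray]) -> EnvStack:
    return EnvStack(grid=grid, layers=dict(arrays))
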