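"""Raster, occurrence-table and scenario plumbing.

Rasters are single-band ESRI ASCII grids (``.asc``) in geographic degrees
(WGS84 by convention).  Grids are square-celled with row 0 at the north and
half-open cells: a point exactly on an interior cell edge belongs to the cell
south/east of the edge.  No reprojection is performed anywhere — inputs are
required to share geometry already.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "EnvStack",
    "OccurrenceTable",
    "ScenarioSpec",
    "GeodataError",
    "GridMismatchError",
    "ValidationError",
    "read_raster",
    "write_raster",
    "read_env_stack",
    "read_occurrences",
    "read_scenario",
    "point_to_cell",
    "cell_center",
]

POPULATIONS = ("southern", "central", "northern")

#: layer names required by the default five-predictor model configuration:
#: climatic moisture index, winter precipitation, relative humidity,
#: continentality (warm-cold month temperature difference), Strahler order.
REQUIRED_LAYERS = ("cmi", "ppt_wt", "rh", "td", "stream_order")

DEFAULT_NODATA = -9999.0


class GeodataError(Exception):
    """Base class for raster/table plumbing errors."""


class GridMismatchError(GeodataError):
    """Two rasters do not share dimensions or georeferencing."""


class ValidationError(GeodataError):
    """A table or config value violates its contract."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up, square-celled geographic raster.

    ``origin_lon``/``origin_lat`` locate the north-west corner.  Cell
    ``(r, c)`` covers the half-open box
    ``[origin_lon + c*s, origin_lon + (c+1)*s) x (origin_lat - (r+1)*s,
    origin_lat - r*s]`` with ``s = cell_size`` in degrees.
    """

    n_rows: int
    n_cols: int
    origin_lon: float
    origin_lat: float
    cell_size: float
    crs_label: str = "WGS84"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValidationError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def approx_equal(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.origin_lon - other.origin_lon) <= tol
            and abs(self.origin_lat - other.origin_lat) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )


def point_to_cell(grid: GridSpec, lon: float, lat: float) -> tuple[int, int] | None:
    """Map a point to its 0-based (row, col), or ``None`` if out of extent.

    Floor rule: interior-edge points fall in the cell south/east of the edge;
    the north and west outer edges are in extent, the south and east outer
    edges are not.
    """
    col = int(np.floor((lon - grid.origin_lon) / grid.cell_size))
    row = int(np.floor((grid.origin_lat - lat) / grid.cell_size))
    if 0 <= row < grid.n_rows and 0 <= col < grid.n_cols:
        return (row, col)
    return None


def cell_center(grid: GridSpec, row: int, col: int) -> tuple[float, float]:
    """(lon, lat) of the centre of cell (row, col)."""
    lon = grid.origin_lon + (col + 0.5) * grid.cell_size
    lat = grid.origin_lat - (row + 0.5) * grid.cell_size
    return (lon, lat)


@dataclass
class EnvStack:
    """Named environmental layers on a shared grid with one validity mask.

    Values at masked-out cells are undefined and ignored by every consumer.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray]
    valid_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.grid.shape, dtype=bool)
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise GridMismatchError(
                    f"layer {name!r} has shape {arr.shape}, grid is {self.grid.shape}"
                )
        if self.valid_mask.shape != self.grid.shape:
            raise GridMismatchError("valid_mask shape does not match grid")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def values_at(self, cells: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        """Raw layer values at ``cells`` (an (n, 2) array of row/col), as (n, n_layers)."""
        names = names if names is not None else self.layer_names
        cells = np.asarray(cells)
        rows, cols = cells[:, 0], cells[:, 1]
        return np.column_stack([self.layers[n][rows, cols] for n in names])

    def copy_shifted(self, shifts: dict[str, float]) -> "EnvStack":
        """New stack with additive per-layer shifts (absent layers unshifted)."""
        layers = {
            name: arr + shifts.get(name, 0.0) for name, arr in self.layers.items()
        }
        return EnvStack(self.grid, layers, self.valid_mask.copy())


@dataclass(frozen=True)
class ScenarioSpec:
    """A climate scenario: general circulation model x RCP x period.

    The baseline period ``current`` uses the sentinel ``"none"`` for both
    gcm and rcp.
    """

    gcm: str = "none"
    rcp: str = "none"
    period: str = "current"

    def __post_init__(self) -> None:
        if self.period not in ("current", "2050s", "2080s"):
            raise ValidationError(f"unknown period {self.period!r}")
        if self.period == "current":
            if self.gcm != "none" or self.rcp != "none":
                raise ValidationError("period 'current' requires gcm and rcp 'none'")
        else:
            if self.rcp not in ("4.5", "8.5"):
                raise ValidationError(f"rcp must be '4.5' or '8.5', got {self.rcp!r}")
            if self.gcm == "none":
                raise ValidationError("future scenarios need a gcm label")

    @property
    def is_current(self) -> bool:
        return self.period == "current"

    @property
    def label(self) -> str:
        if self.is_current:
            return "current"
        return f"{self.gcm}_rcp{self.rcp}_{self.period}"

    @classmethod
    def current(cls) -> "ScenarioSpec":
        return cls()


@dataclass
class OccurrenceTable:
    """Genotype occurrences: id, lon/lat, population label, leaf-out day.

    Leaf-out is the greenhouse-measured Julian day the first leaf unfurled,
    i.e. the genetically based trait value of the genotype.
    """

    df: pd.DataFrame = field(repr=False)

    COLUMNS = ("genotype_id", "lon", "lat", "population", "leafout_day")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"occurrence table missing columns: {missing}")
        df = self.df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        df["genotype_id"] = df["genotype_id"].astype(str)
        df["leafout_day"] = df["leafout_day"].astype(int)
        dup = df["genotype_id"].duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate genotype_id(s): {sorted(df.loc[dup, 'genotype_id'].unique())}"
            )
        bad_day = ~df["leafout_day"].between(1, 366)
        if bad_day.any():
            rows = df.index[bad_day].tolist()
            raise ValidationError(f"leafout_day outside [1, 366] at row(s) {rows}")
        bad_pop = ~df["population"].isin(POPULATIONS)
        if bad_pop.any():
            raise ValidationError(
                f"unknown population label(s): {sorted(df.loc[bad_pop, 'population'].unique())}"
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_raster(array: np.ndarray, grid: GridSpec, path, nodata: float = DEFAULT_NODATA) -> None:
    """Write a 2-D array as an ESRI ASCII grid.

    Integer arrays round-trip bit-exactly; NaNs are written as the nodata
    value.  Raises on a shape mismatch with ``grid``.
    """
    array = np.asarray(array)
    if array.shape != grid.shape:
        raise GridMismatchError(
            f"array shape {array.shape} does not match grid {grid.shape}"
        )
    is_int = np.issubdtype(array.dtype, np.integer)
    out = array.astype(float, copy=True)
    out[~np.isfinite(out)] = nodata
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_lon!r}\n"
        f"yllcorner {grid.origin_lat - grid.n_rows * grid.cell_size!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    fmt = "%d" if is_int else "%.10g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)


def read_raster(path) -> tuple[np.ndarray, GridSpec, float]:
    """Read an ESRI ASCII grid; returns (array, grid, nodata value).

    Nodata cells are returned as NaN in the array.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(n_rows, n_cols)
    cell = header["cellsize"]
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
    )
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    data = data.astype(float)
    data[data == nodata] = np.nan
    return data, grid, nodata


def read_env_stack(paths: list, names: list[str]) -> EnvStack:
    """Read co-registered rasters into one stack.

    The validity mask is the conjunction of the per-layer nodata masks.
    Raises :class:`GridMismatchError` naming the first offending layer.
    """
    if len(paths) != len(names):
        raise ValidationError("paths and names must have equal length")
    layers: dict[str, np.ndarray] = {}
    grid: GridSpec | None = None
    mask: np.ndarray | None = None
    for path, name in zip(paths, names):
        arr, g, _ = read_raster(path)
        if grid is None:
            grid, mask = g, np.isfinite(arr)
        else:
            if not grid.approx_equal(g):
                raise GridMismatchError(
                    f"layer {name!r} ({path}) does not match the first layer's grid"
                )
            mask &= np.isfinite(arr)
        layers[name] = arr
    assert grid is not None and mask is not None
    return EnvStack(grid, layers, mask)


def read_occurrences(path) -> OccurrenceTable:
    """Read the five-column occurrence CSV with full validation."""
    df = pd.read_csv(path)
    return OccurrenceTable(df)


def read_scenario(path) -> tuple[ScenarioSpec, dict[str, str]]:
    """Read scenario metadata JSON: {gcm, rcp, period, layers: {name: path}}."""
    with open(path) as fh:
        meta = json.load(fh)
    spec = ScenarioSpec(
        gcm=str(meta.get("gcm", "none")),
        rcp=str(meta.get("rcp", "none")),
        period=str(meta.get("period", "current")),
    )
    return spec, dict(meta.get("layers", {}))
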