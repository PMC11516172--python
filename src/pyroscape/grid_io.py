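"""Raster and occurrence-point I/O.

All analysis layers live on a single aligned grid of square cells in a
projected (metric) coordinate system.  ``RasterGrid`` is the one raster
container every other module consumes; ``RasterStack`` bundles aligned
layers; ``OccurrenceSet`` holds labelled, season-tagged points.

Rasters are stored as single-band GeoTIFFs (float32 for continuous layers,
int32 plus a sidecar JSON legend for categorical layers) carrying the
standard GeoTIFF georeferencing tags.  Point tables are CSV with header
``x,y,season,label,source``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

SEASONS = ("spring", "summer", "autumn")
LABELS = ("presence", "pseudo_absence")

#: CRS tags treated as geographic (degree) systems and rejected: area
#: accounting requires metric cells.
_GEOGRAPHIC_TAGS = frozenset({"EPSG:4326", "EPSG:4258", "EPSG:4269", "WGS84", "CRS84"})

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GridValidationError(ValueError):
    """A raster or point set violates a structural invariant."""


def _check_crs(crs_tag: str) -> str:
    if not crs_tag:
        raise GridValidationError("raster has no CRS tag; georeferencing is required")
    if crs_tag.strip().upper().replace(" ", "") in _GEOGRAPHIC_TAGS:
        raise GridValidationError(
            f"CRS {crs_tag!r} is geographic (degrees); reproject to a metric CRS "
            "before analysis — km² area accounting requires metric cells"
        )
    return crs_tag


@dataclass
class RasterGrid:
    """A single aligned 2-D layer with nodata mask and metric cell size.

    ``origin`` is the (x, y) of the grid's **upper-left corner**; rows run
    downward (row r spans y in (origin_y-(r+1)*cell, origin_y-r*cell]).
    ``legend`` maps integer class codes to names for categorical grids.
    """

    values: np.ndarray
    nodata_mask: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    crs_tag: str
    legend: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2:
            raise GridValidationError("raster values must be 2-D")
        if self.values.shape != self.nodata_mask.shape:
            raise GridValidationError("values and nodata_mask shapes differ")
        if not self.cell_size > 0:
            raise GridValidationError("cell_size must be positive")
        _check_crs(self.crs_tag)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        return ~self.nodata_mask

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-9)
            and math.isclose(self.origin[0], other.origin[0], abs_tol=1e-6)
            and math.isclose(self.origin[1], other.origin[1], abs_tol=1e-6)
            and self.crs_tag == other.crs_tag
        )

    def like(self, values: np.ndarray, nodata_mask: np.ndarray | None = None,
             legend: dict[int, str] | None = None) -> "RasterGrid":
        """New grid on this grid's georeferencing."""
        mask = self.nodata_mask.copy() if nodata_mask is None else nodata_mask
        return RasterGrid(np.asarray(values), mask, self.cell_size, self.origin,
                          self.crs_tag, legend)

    def cell_of(self, x: float | np.ndarray, y: float | np.ndarray):
        """Map point coordinates to (row, col) under half-open cell intervals.

        A point exactly on a shared edge belongs to the cell on its
        right/below.  Returned indices may fall outside the grid; callers
        check bounds.
        """
        col = np.floor((np.asarray(x, float) - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((self.origin[1] - np.asarray(y, float)) / self.cell_size).astype(int)
        return row, col

    def cell_center(self, row: np.ndarray, col: np.ndarray):
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin[1] - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2


@dataclass
class RasterStack:
    """Ordered collection of aligned layers with unique names."""

    layers: list[RasterGrid]
    names: list[str]

    def __post_init__(self) -> None:
        if len(self.layers) != len(self.names):
            raise GridValidationError("layers and names differ in length")
        if len(set(self.names)) != len(self.names) or any(not n for n in self.names):
            raise GridValidationError("layer names must be unique and non-empty")
        ref = self.layers[0]
        for name, layer in zip(self.names, self.layers):
            if not layer.aligned_with(ref):
                raise GridValidationError(
                    f"layer {name!r} is not aligned with {self.names[0]!r} "
                    "(shape/cell_size/origin/CRS must match; this tool does not resample)"
                )

    def __getitem__(self, name: str) -> RasterGrid:
        try:
            return self.layers[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no layer named {name!r}; have {self.names}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.names

    @property
    def grid(self) -> RasterGrid:
        return self.layers[0]

    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for layer in self.layers:
            mask &= layer.valid
        return mask

    def subset(self, names: Sequence[str]) -> "RasterStack":
        return RasterStack([self[n] for n in names], list(names))


@dataclass
class OccurrenceSet:
    """Labelled point records with a season tag.

    Backed by a DataFrame with columns ``x, y, season, label, source``.
    Seasons are restricted to spring/summer/autumn (winter fires are not
    modelled: they are rare and low-intensity in the study system).
    """

    table: pd.DataFrame

    COLUMNS = ("x", "y", "season", "label", "source")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise GridValidationError(f"occurrence table missing columns {missing}")
        bad = set(self.table["season"]) - set(SEASONS)
        if bad:
            raise GridValidationError(
                f"unknown seasons {sorted(bad)}; modelled seasons are {SEASONS}"
            )
        bad = set(self.table["label"]) - set(LABELS)
        if bad:
            raise GridValidationError(f"unknown labels {sorted(bad)}; allowed {LABELS}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[float, float, str, str, str]]
    ) -> "OccurrenceSet":
        return cls(pd.DataFrame(list(records), columns=list(cls.COLUMNS)))

    def __len__(self) -> int:
        return len(self.table)

    def season(self, season: str) -> "OccurrenceSet":
        return OccurrenceSet(self.table[self.table["season"] == season])

    def label(self, label: str) -> "OccurrenceSet":
        return OccurrenceSet(self.table[self.table["label"] == label])

    def concat(self, other: "OccurrenceSet") -> "OccurrenceSet":
        return OccurrenceSet(pd.concat([self.table, other.table], ignore_index=True))

    def xy(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(float)


# ---------------------------------------------------------------------------
# GeoTIFF I/O (tifffile backend, standard GeoTIFF tags)
# ---------------------------------------------------------------------------

def write_raster(grid: RasterGrid, path: str | Path, nodata: float = -9999.0,
                 dtype=None) -> Path:
    """Write a grid as a single-band GeoTIFF.

    Integer grids go out as int32; continuous grids keep their float dtype
    so a write/read round-trip is value-preserving (pass ``dtype=np.float32``
    to force compact storage).  A legend, if attached, is written to
    ``<path>.legend.json``.
    """
    path = Path(path)
    values = grid.values
    if np.issubdtype(values.dtype, np.integer):
        out = values.astype(np.int32).copy()
        out[grid.nodata_mask] = int(nodata)
    else:
        out = values.astype(dtype or values.dtype).copy()
        out[grid.nodata_mask] = nodata
    desc = json.dumps({"crs_tag": grid.crs_tag})
    ox, oy = grid.origin
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(grid.cell_size), float(grid.cell_size), 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(ox), float(oy), 0.0), True),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata), True),
    ]
    tifffile.imwrite(path, out, description=desc, metadata=None, extratags=extratags)
    if grid.legend is not None:
        legend_path = path.with_suffix(path.suffix + ".legend.json")
        legend_path.write_text(json.dumps({str(k): v for k, v in grid.legend.items()},
                                          indent=0, sort_keys=True))
    return path


def read_raster(path: str | Path) -> RasterGrid:
    """Read a single-band GeoTIFF written by :func:`write_raster` (or any
    GeoTIFF carrying pixel-scale and tiepoint tags plus a CRS identifier).

    Fails loudly on missing georeferencing rather than guessing.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"raster file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            values = page.asarray()
            scale = page.tags.get(_TAG_PIXEL_SCALE)
            tiepoint = page.tags.get(_TAG_TIEPOINT)
            nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
            scale_val = scale.value if scale is not None else None
            tiepoint_val = tiepoint.value if tiepoint is not None else None
            nodata_val = nodata_tag.value if nodata_tag is not None else None
            desc = page.description or ""
    except tifffile.TiffFileError as exc:
        raise IOError(f"unreadable raster {path}: {exc}") from exc
    if values.ndim == 3 and values.shape[0] == 1:
        values = values[0]
    if scale_val is None or tiepoint_val is None:
        raise GridValidationError(
            f"{path} lacks GeoTIFF georeferencing tags (pixel scale / tiepoint)"
        )
    sx, sy = scale_val[0], scale_val[1]
    if not math.isclose(sx, sy, rel_tol=1e-9):
        raise GridValidationError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
    tp = tiepoint_val
    origin = (tp[3] - tp[0] * sx, tp[4] + tp[1] * sy)
    crs_tag = ""
    if desc:
        try:
            crs_tag = json.loads(desc).get("crs_tag", "")
        except (json.JSONDecodeError, AttributeError):
            pass
    if not crs_tag:
        raise GridValidationError(f"{path} carries no CRS identifier")
    mask = np.zeros(values.shape, dtype=bool)
    if nodata_val is not None:
        nd = float(str(nodata_val))
        mask = (values == (int(nd) if np.issubdtype(values.dtype, np.integer) else nd))
    legend = None
    legend_path = path.with_suffix(path.suffix + ".legend.json")
    if legend_path.exists():
        legend = {int(k): v for k, v in json.loads(legend_path.read_text()).items()}
    return RasterGrid(values, mask, float(sx), origin, crs_tag, legend)


def write_points(points: OccurrenceSet, path: str | Path) -> Path:
    path = Path(path)
    points.table.to_csv(path, index=False)
    return path


def read_points(path: str | Path) -> OccurrenceSet:
    path = Path(path)
    if not path.exists():
        raise IOError(f"point file not found: {path}")
    return OccurrenceSet(pd.read_csv(path, dtype={"season": str, "label": str, "source": str}))


# ---------------------------------------------------------------------------
# Point sampling
# ---------------------------------------------------------------------------

@dataclass
class ExtractionResult:
    """Feature rows for points, with bookkeeping of dropped records."""

    features: pd.DataFrame          # one row per retained point, one column per layer
    kept_index: np.ndarray          # positions into the input point table
    n_outside: int
    n_nodata: int


def extract_at_points(stack: RasterStack, points: OccurrenceSet) -> ExtractionResult:
    """Nearest-cell sampling of every stack layer at each point.

    Row order follows point order.  Points outside the stack extent, and
    points whose cell is nodata in any layer, are dropped and counted.
    Raises if no point falls inside the extent.
    """
    grid = stack.grid
    xy = points.xy()
    if len(xy) == 0:
        raise GridValidationError("no points to extract")
    row, col = grid.cell_of(xy[:, 0], xy[:, 1])
    nrow, ncol = grid.shape
    inside = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
    if not inside.any():
        raise GridValidationError("all points fall outside the stack extent")
    valid = stack.valid_mask()
    ok = inside.copy()
    ok[inside] &= valid[row[inside], col[inside]]
    kept = np.flatnonzero(ok)
    data = {
        name: layer.values[row[kept], col[kept]]
        for name, layer in zip(stack.names, stack.layers)
    }
    features = pd.DataFrame(data, index=kept)
    return ExtractionResult(
        features=features,
        kept_index=kept,
        n_outside=int((~inside).sum()),
        n_nodata=int((inside & ~ok).sum()),
    )
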