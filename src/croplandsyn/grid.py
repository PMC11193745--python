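"""Raster data model: georeferenced binary label grids and their harmonization.

All maps in the pipeline live on a common analysis grid in an equal-area
projected coordinate system, so that pixel counts translate directly into
areas.  The model is deliberately minimal: north-up, square pixels, an opaque
CRS tag that must match between grids (reprojection is delegated to external
tooling), and labels restricted to {0 non-cropland, 1 cropland, nodata}.

Coordinate convention
---------------------
Row 0 is the northernmost row.  ``origin_x``/``origin_y`` are the easting and
northing of the *outer top-left corner* of pixel (0, 0).  A point (x, y) falls
in column ``floor((x - origin_x) / pixel_size)`` and row
``floor((origin_y - y) / pixel_size)``; pixels are half-open
``[edge, edge + size)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "GridSpec",
    "LabelGrid",
    "ClassMap",
    "read_label_grid",
    "write_label_grid",
    "binarize",
    "resample_nearest",
    "clip_mask",
    "temporal_majority",
    "mapped_area",
    "GridAlignmentError",
]

#: Default reserved nodata code for uint8 label rasters.
DEFAULT_NODATA = 255

# GeoTIFF tag codes used for georeferencing.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_MODEL_TRANSFORMATION = 34264
_TAG_GEO_ASCII_PARAMS = 34737
_TAG_GDAL_NODATA = 42113


class GridAlignmentError(ValueError):
    """Raised when an operation requires aligned grids and they are not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up raster grid with square pixels.

    Parameters
    ----------
    origin_x, origin_y
        Easting / northing of the outer top-left corner, in map units of an
        equal-area projected CRS.
    pixel_size
        Side length of a (square) pixel in map units; must be positive.
    n_rows, n_cols
        Grid dimensions.
    crs_tag
        Opaque CRS identifier.  Two grids interoperate only if their tags are
        equal; the library performs no reprojection.
    """

    origin_x: float
    origin_y: float
    pixel_size: float
    n_rows: int
    n_cols: int
    crs_tag: str = "equal-area"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def aligned(self, other: "GridSpec") -> bool:
        return self == other

    def rowcol(self, x, y):
        """Vectorized point-in-pixel lookup: (x, y) -> (row, col).

        Returned indices may fall outside the grid; callers decide how to
        treat out-of-extent points.
        """
        col = np.floor((np.asarray(x, dtype=float) - self.origin_x) / self.pixel_size)
        row = np.floor((self.origin_y - np.asarray(y, dtype=float)) / self.pixel_size)
        return row.astype(np.int64), col.astype(np.int64)

    def cell_center(self, row, col):
        """Map coordinates of the center of pixel (row, col)."""
        x = self.origin_x + (np.asarray(col, dtype=float) + 0.5) * self.pixel_size
        y = self.origin_y - (np.asarray(row, dtype=float) + 0.5) * self.pixel_size
        return x, y

    def contains(self, x, y):
        row, col = self.rowcol(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


@dataclass
class LabelGrid:
    """A georeferenced grid of binary labels: 1 cropland, 0 non-cropland.

    ``labels`` is an integer array of shape ``spec.shape`` over
    ``{0, 1, nodata_code}``.
    """

    spec: GridSpec
    labels: np.ndarray
    nodata_code: int = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.spec.shape:
            raise ValueError(
                f"label array shape {self.labels.shape} != grid spec shape {self.spec.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        bad = ~np.isin(self.labels, (0, 1, self.nodata_code))
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} cells outside {{0, 1, {self.nodata_code}}}"
            )

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of observed (non-nodata) cells."""
        return self.labels != self.nodata_code

    @property
    def ones(self) -> np.ndarray:
        return self.labels == 1

    def copy(self) -> "LabelGrid":
        return LabelGrid(self.spec, self.labels.copy(), self.nodata_code)


@dataclass(frozen=True)
class ClassMap:
    """How a source product's class codes map onto the binary cropland legend."""

    product_name: str
    cropland_codes: frozenset = field(default_factory=frozenset)
    nodata_codes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cropland_codes", frozenset(self.cropland_codes))
        object.__setattr__(self, "nodata_codes", frozenset(self.nodata_codes))
        if not self.cropland_codes:
            raise ValueError(f"{self.product_name}: cropland_codes must be non-empty")
        if self.cropland_codes & self.nodata_codes:
            raise ValueError(
                f"{self.product_name}: cropland and nodata codes overlap"
            )


# ---------------------------------------------------------------------------
# GeoTIFF I/O (tifffile-backed; single integer band, north-up only)
# ---------------------------------------------------------------------------


def write_label_grid(grid, path, *, dtype=None) -> None:
    """Write a grid to a single-band GeoTIFF.

    Accepts a :class:`LabelGrid` or a ``(array, spec, nodata)`` triple packed
    as a LabelGrid-like object.  Georeferencing is stored in the standard
    GeoTIFF tags so the output opens in GDAL-based tools.
    """
    arr = np.asarray(grid.labels)
    if dtype is None:
        dtype = np.uint8 if arr.max(initial=0) <= 255 and arr.min(initial=0) >= 0 else arr.dtype
    spec = grid.spec
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (float(spec.pixel_size), float(spec.pixel_size), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, float(spec.origin_x), float(spec.origin_y), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(int(grid.nodata_code))),
        (_TAG_GEO_ASCII_PARAMS, "s", 0, spec.crs_tag + "|"),
    ]
    tifffile.imwrite(str(path), arr.astype(dtype), extratags=extratags)


def read_label_grid(path, band: int = 0):
    """Read a single-band integer GeoTIFF.

    Returns ``(raw, spec, nodata)`` where ``raw`` is the unmodified integer
    array, ``spec`` a :class:`GridSpec` derived from the geotransform tags
    and ``nodata`` the raster's declared nodata code (``None`` if absent).
    Rotated/sheared rasters and non-integer samples are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tif:
        if band >= len(tif.pages):
            raise IndexError(f"band {band} out of range ({len(tif.pages)} pages)")
        page = tif.pages[band]
        raw = page.asarray()
        if raw.ndim != 2:
            raise ValueError(f"expected a single-band 2-D raster, got shape {raw.shape}")
        if not np.issubdtype(raw.dtype, np.integer):
            raise ValueError(f"non-integer samples ({raw.dtype}); label rasters must be integer")

        xform = page.tags.get(_TAG_MODEL_TRANSFORMATION)
        if xform is not None:
            m = np.asarray(xform.value, dtype=float).reshape(4, 4)
            if m[0, 1] != 0.0 or m[1, 0] != 0.0:
                raise ValueError("non-north-up raster: rotation/shear terms present")
            sx, sy = m[0, 0], -m[1, 1]
            ox, oy = m[0, 3], m[1, 3]
        else:
            scale = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
            tiepoint = page.tags.get(_TAG_MODEL_TIEPOINT)
            if scale is None or tiepoint is None:
                raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
            sx, sy = float(scale.value[0]), float(scale.value[1])
            i, j, _, x, y, _ = (float(v) for v in tiepoint.value[:6])
            ox, oy = x - i * sx, y + j * sy
        if sy <= 0:
            raise ValueError("non-north-up raster: non-positive row pixel size")
        if abs(sx - sy) > 1e-9 * max(abs(sx), abs(sy)):
            raise ValueError(f"non-square pixels ({sx} x {sy}) are not supported")

        crs_tag = "equal-area"
        ascii_params = page.tags.get(_TAG_GEO_ASCII_PARAMS)
        if ascii_params is not None:
            crs_tag = str(ascii_params.value).rstrip("|").rstrip("\x00") or crs_tag

        nodata = None
        nd_tag = page.tags.get(_TAG_GDAL_NODATA)
        if nd_tag is not None:
            nodata = int(float(str(nd_tag.value).strip("\x00 ")))

    spec = GridSpec(ox, oy, sx, raw.shape[0], raw.shape[1], crs_tag)
    return raw, spec, nodata


def load_label_grid(path, band: int = 0, nodata_code: int = DEFAULT_NODATA) -> LabelGrid:
    """Read a GeoTIFF already in the binary {0,1,nodata} legend as a LabelGrid."""
    raw, spec, nodata = read_label_grid(path, band)
    if nodata is None:
        nodata = nodata_code
    return LabelGrid(spec, raw, int(nodata))


# ---------------------------------------------------------------------------
# Harmonization operations
# ---------------------------------------------------------------------------


def binarize(raw: np.ndarray, spec: GridSpec, class_map: ClassMap,
             nodata_code: int = DEFAULT_NODATA) -> LabelGrid:
    """Collapse a product's native class codes to the binary cropland legend.

    Codes in ``cropland_codes`` become 1, codes in ``nodata_codes`` become
    nodata, every other code is non-cropland (0) by contract.
    """
    raw = np.asarray(raw)
    out = np.zeros(raw.shape, dtype=np.uint8 if nodata_code <= 255 else np.int32)
    if class_map.cropland_codes:
        out[np.isin(raw, list(class_map.cropland_codes))] = 1
    if class_map.nodata_codes:
        out[np.isin(raw, list(class_map.nodata_codes))] = nodata_code
    return LabelGrid(spec, out, nodata_code)


def resample_nearest(grid: LabelGrid, target: GridSpec) -> LabelGrid:
    """Nearest-neighbour (point-in-pixel) resampling onto ``target``.

    Each target cell takes the label of the source cell containing the target
    cell's *center*; centers falling outside the source extent map to nodata.
    """
    src = grid.spec
    if src.crs_tag != target.crs_tag:
        raise GridAlignmentError(
            f"CRS mismatch: {src.crs_tag!r} vs {target.crs_tag!r}"
        )
    rows = np.arange(target.n_rows)
    cols = np.arange(target.n_cols)
    cx, _ = target.cell_center(0, cols)
    _, cy = target.cell_center(rows, 0)
    src_col = np.floor((cx - src.origin_x) / src.pixel_size).astype(np.int64)
    src_row = np.floor((src.origin_y - cy) / src.pixel_size).astype(np.int64)
    ok_col = (src_col >= 0) & (src_col < src.n_cols)
    ok_row = (src_row >= 0) & (src_row < src.n_rows)
    out = np.full(target.shape, grid.nodata_code, dtype=grid.labels.dtype)
    if ok_row.any() and ok_col.any():
        rr = src_row[ok_row]
        cc = src_col[ok_col]
        out[np.ix_(ok_row, ok_col)] = grid.labels[np.ix_(rr, cc)]
    return LabelGrid(target, out, grid.nodata_code)


def _require_aligned(a: GridSpec, b: GridSpec, what: str) -> None:
    if not a.aligned(b):
        raise GridAlignmentError(f"{what}: grids are not aligned ({a} vs {b})")


def clip_mask(grid: LabelGrid, mask: LabelGrid) -> LabelGrid:
    """Set cells to nodata wherever ``mask`` is 0 or nodata (study-area clip)."""
    _require_aligned(grid.spec, mask.spec, "clip_mask")
    out = grid.labels.copy()
    out[~mask.ones] = grid.nodata_code
    return LabelGrid(grid.spec, out, grid.nodata_code)


def temporal_majority(grids: list[LabelGrid], tie_value: int = 1) -> LabelGrid:
    """Per-cell majority label across a temporal stack of aligned grids.

    Nodata observations are ignored; an all-nodata cell stays nodata.  Ties
    default to cropland (``tie_value=1``), favouring detection the way
    multi-year cropland composites do; pass ``tie_value=0`` for the
    conservative rule.
    """
    if not grids:
        raise ValueError("temporal_majority requires at least one grid")
    first = grids[0]
    for g in grids[1:]:
        _require_aligned(first.spec, g.spec, "temporal_majority")
    ones = np.zeros(first.spec.shape, dtype=np.int32)
    zeros = np.zeros(first.spec.shape, dtype=np.int32)
    for g in grids:
        ones += g.ones
        zeros += (g.labels == 0)
    out = np.full(first.spec.shape, first.nodata_code,
                  dtype=first.labels.dtype)
    out[zeros > ones] = 0
    out[ones > zeros] = 1
    tied = (ones == zeros) & (ones > 0)
    out[tied] = tie_value
    return LabelGrid(first.spec, out, first.nodata_code)


def mapped_area(grid: LabelGrid) -> float:
    """Total cropland area of a grid, in 10^4 ha.

    Valid only under an equal-area CRS, where each pixel covers
    ``pixel_size**2`` square map units (m^2); nodata cells are excluded.
    A 30 m pixel is 0.09 ha.
    """
    n_ones = int(grid.ones.sum())
    # m^2 -> ha is /1e4; ha -> 10^4 ha is another /1e4.
    return n_ones * grid.spec.pixel_size ** 2 / 1e8
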