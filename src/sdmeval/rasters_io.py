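"""Grid and point data model plus GeoTIFF / ESRI ASCII grid / CSV I/O.

Coordinate convention: planar (projected) map units throughout.  A grid's
origin ``(x_origin, y_origin)`` is the *top-left corner*; row 0 is the
northernmost row, so cell ``(r, c)`` has its center at::

    x = x_origin + (c + 0.5) * cell_size
    y = y_origin - (r + 0.5) * cell_size

Cells are half-open ``[x_left, x_right) x (y_bottom, y_top]`` so every
point inside the extent maps to exactly one cell.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

# GeoTIFF tag ids used for georeferencing (GDAL-compatible).
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

_PRESENCE_ALIASES = {"presence", "present", "p", "1", "1.0", "true", "yes"}
_ABSENCE_ALIASES = {"absence", "absent", "a", "0", "0.0", "false", "no"}


class RasterFormatError(ValueError):
    """Raised when a raster file cannot be parsed under the named standard."""


@dataclass
class GridRaster:
    """Georeferenced 2-D lattice of real values; NaN marks nodata cells."""

    values: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    nodata_value: float = -9999.0
    crs_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    # -- coordinate transforms -------------------------------------------

    def cell_center(self, row, col):
        """Map coordinates of the center of cell ``(row, col)``."""
        x = self.x_origin + (np.asarray(col) + 0.5) * self.cell_size
        y = self.y_origin - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def cell_of(self, x, y):
        """Cell index ``(row, col)`` containing point(s) ``(x, y)``.

        Half-open membership: x on a left edge belongs to that column,
        y on a top edge belongs to that row.  Out-of-extent points get
        indices outside ``[0, n_rows) x [0, n_cols)``.
        """
        col = np.floor((np.asarray(x, dtype=float) - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((self.y_origin - np.asarray(y, dtype=float)) / self.cell_size).astype(int)
        # y exactly on the top edge of the extent belongs to row 0
        row = np.where(np.asarray(y, dtype=float) == self.y_origin, 0, row)
        return row, col

    def in_extent(self, x, y):
        row, col = self.cell_of(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def georef_matches(self, other: "GridRaster | CategoricalMap") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.x_origin, other.x_origin)
            and math.isclose(self.y_origin, other.y_origin)
            and math.isclose(self.cell_size, other.cell_size)
        )

    def copy_with(self, values: np.ndarray) -> "GridRaster":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class CategoricalMap:
    """Georeferenced 2-D lattice of small-integer category codes.

    Binary maps use exactly ``{0: absent, 1: present}``.
    """

    values: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    valid_categories: frozenset = frozenset({0, 1})
    nodata_code: int = -1
    crs_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")
        self.valid_categories = frozenset(int(c) for c in self.valid_categories)
        if self.nodata_code in self.valid_categories:
            raise ValueError("nodata_code must not be a valid category")
        bad = set(np.unique(self.values)) - self.valid_categories - {self.nodata_code}
        if bad:
            raise ValueError(f"cells contain codes outside valid_categories: {sorted(bad)}")

    n_rows = GridRaster.n_rows
    n_cols = GridRaster.n_cols
    shape = GridRaster.shape
    cell_center = GridRaster.cell_center
    cell_of = GridRaster.cell_of
    in_extent = GridRaster.in_extent
    georef_matches = GridRaster.georef_matches

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata_code


@dataclass
class OccurrenceSet:
    """Point records with planar coordinates and presence/absence labels."""

    table: pd.DataFrame  # columns: id, x, y, label [, weight]

    def __post_init__(self) -> None:
        required = {"id", "x", "y", "label"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        bad = set(self.table["label"].unique()) - {"presence", "absence"}
        if bad:
            raise ValueError(f"labels must be presence/absence, got {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def xy(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(dtype=float)

    def subset(self, mask) -> "OccurrenceSet":
        return OccurrenceSet(self.table.loc[np.asarray(mask)].reset_index(drop=True))

    @property
    def presences(self) -> "OccurrenceSet":
        return self.subset((self.table["label"] == "presence").to_numpy())

    @property
    def absences(self) -> "OccurrenceSet":
        return self.subset((self.table["label"] == "absence").to_numpy())

    @classmethod
    def from_arrays(cls, x, y, label, ids=None) -> "OccurrenceSet":
        x = np.asarray(x, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(len(x))]
        if isinstance(label, str):
            label = [label] * len(x)
        return cls(pd.DataFrame({"id": ids, "x": x, "y": np.asarray(y, dtype=float),
                                 "label": list(label)}))


class EnvStack:
    """Named, ordered collection of aligned predictor layers.

    All layers must share shape, origin, cell size and nodata mask;
    mismatches are construction errors.
    """

    def __init__(self, layers: dict[str, GridRaster]):
        if not layers:
            raise ValueError("EnvStack needs at least one layer")
        self.layers = dict(layers)
        names = list(self.layers)
        ref = self.layers[names[0]]
        for name in names[1:]:
            lyr = self.layers[name]
            if not ref.georef_matches(lyr):
                raise ValueError(f"layer {name!r} georeference differs from {names[0]!r}")
            if not np.array_equal(ref.valid_mask, lyr.valid_mask):
                raise ValueError(f"layer {name!r} nodata mask differs from {names[0]!r}")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def template(self) -> GridRaster:
        return next(iter(self.layers.values()))

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> GridRaster:
        return self.layers[name]

    def subset(self, names) -> "EnvStack":
        return EnvStack({n: self.layers[n] for n in names})

    def as_array(self, names=None) -> np.ndarray:
        """Stack layer values into an ``(n_layers, n_rows, n_cols)`` array."""
        names = self.names if names is None else list(names)
        return np.stack([self.layers[n].values for n in names])


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("geotiff", "ascii_grid"):
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        return "geotiff"
    if ext in (".asc", ".txt"):
        return "ascii_grid"
    raise ValueError(f"cannot infer raster format from {path!r}; pass format=")


def read_raster(path: str, format: str | None = None) -> GridRaster:
    """Read a GeoTIFF or ESRI ASCII grid into a :class:`GridRaster`.

    Nodata cells come back as NaN.  Non-square cells and missing
    georeference are errors.
    """
    fmt = _infer_format(path, format)
    if fmt == "ascii_grid":
        return _read_ascii(path)
    return _read_geotiff(path)


def _read_ascii(path: str) -> GridRaster:
    header: dict[str, float] = {}
    body_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise RasterFormatError(f"{path}: ASCII grid header missing {key}")
    if "xllcorner" in header:
        xll = header["xllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - header["cellsize"] / 2
    else:
        raise RasterFormatError(f"{path}: ASCII grid header missing xllcorner")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - header["cellsize"] / 2
    else:
        raise RasterFormatError(f"{path}: ASCII grid header missing yllcorner")

    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    cell_size = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    tokens = " ".join(lines[body_start:]).split()
    if len(tokens) != n_rows * n_cols:
        raise RasterFormatError(
            f"{path}: expected {n_rows * n_cols} values, found {len(tokens)}")
    try:
        values = np.array(tokens, dtype=float).reshape(n_rows, n_cols)
    except ValueError as exc:
        raise RasterFormatError(f"{path}: unparseable ASCII grid body: {exc}") from exc
    values[values == nodata] = np.nan
    return GridRaster(
        values=values,
        x_origin=xll,
        y_origin=yll + n_rows * cell_size,
        cell_size=cell_size,
        nodata_value=nodata,
    )


def _read_geotiff(path: str) -> GridRaster:
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            values = page.asarray().astype(float)
            scale_tag = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
            tiepoint_tag = page.tags.get(_TAG_MODEL_TIEPOINT)
            nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
            scale = scale_tag.value if scale_tag is not None else None
            tie = tiepoint_tag.value if tiepoint_tag is not None else None
            nodata_raw = nodata_tag.value if nodata_tag is not None else None
    except (tifffile.TiffFileError, OSError) as exc:
        raise RasterFormatError(f"{path}: unreadable TIFF: {exc}") from exc
    if values.ndim != 2:
        raise RasterFormatError(f"{path}: expected single-band raster, got shape {values.shape}")
    if scale is None or tie is None:
        raise RasterFormatError(f"{path}: missing georeference tags (not a GeoTIFF?)")
    sx, sy = scale[0], scale[1]
    if not math.isclose(sx, sy, rel_tol=1e-9):
        raise RasterFormatError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
    # tiepoint maps raster (i, j) to map (x, y); stored at the raster origin
    x_origin = tie[3] - tie[0] * sx
    y_origin = tie[4] + tie[1] * sy
    nodata = None
    if nodata_raw is not None:
        try:
            nodata = float(str(nodata_raw).strip().rstrip("\x00"))
        except ValueError:
            nodata = None
    if nodata is not None:
        if math.isnan(nodata):
            pass  # NaN already marks nodata
        else:
            values[values == nodata] = np.nan
    return GridRaster(
        values=values,
        x_origin=x_origin,
        y_origin=y_origin,
        cell_size=sx,
        nodata_value=nodata if nodata is not None and not math.isnan(nodata) else -9999.0,
    )


def write_raster(r: GridRaster | CategoricalMap, path: str, format: str | None = None) -> str:
    """Write a raster to GeoTIFF (float32/int16) or ESRI ASCII grid.

    Round-trips through :func:`read_raster`: values (within float32
    precision for GeoTIFF), shape, origin, cell size and nodata mask are
    preserved.
    """
    fmt = _infer_format(path, format)
    categorical = isinstance(r, CategoricalMap)
    if categorical:
        nodata = float(r.nodata_code)
        body = r.values.astype(np.int16 if fmt == "geotiff" else np.int64)
    else:
        nodata = float(r.nodata_value)
        body = np.where(np.isnan(r.values), nodata, r.values)
        body = body.astype(np.float32 if fmt == "geotiff" else np.float64)

    if fmt == "ascii_grid":
        n_rows, n_cols = r.shape
        header = (
            f"ncols {n_cols}\n"
            f"nrows {n_rows}\n"
            f"xllcorner {r.x_origin:.10g}\n"
            f"yllcorner {r.y_origin - n_rows * r.cell_size:.10g}\n"
            f"cellsize {r.cell_size:.10g}\n"
            f"NODATA_value {nodata:.10g}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            for row in body:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
        return path

    nodata_str = f"{nodata:.10g}"
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (r.cell_size, r.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, r.x_origin, r.y_origin, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, nodata_str),
    ]
    try:
        tifffile.imwrite(path, body, extratags=extratags)
    except OSError as exc:
        raise OSError(f"cannot write raster to {path}: {exc}") from exc
    return path


def raster_to_categorical(r: GridRaster, valid_categories=frozenset({0, 1}),
                          nodata_code: int = -1) -> CategoricalMap:
    """Reinterpret an integer-valued :class:`GridRaster` as a CategoricalMap."""
    values = np.where(np.isnan(r.values), nodata_code, r.values).astype(np.int64)
    return CategoricalMap(
        values=values, x_origin=r.x_origin, y_origin=r.y_origin,
        cell_size=r.cell_size, valid_categories=valid_categories,
        nodata_code=nodata_code, crs_label=r.crs_label,
    )


# ---------------------------------------------------------------------------
# point I/O
# ---------------------------------------------------------------------------

def _normalize_label(raw) -> str:
    s = str(raw).strip().lower()
    if s in _PRESENCE_ALIASES:
        return "presence"
    if s in _ABSENCE_ALIASES:
        return "absence"
    raise ValueError(f"unrecognized occurrence label {raw!r}")


def read_points(path: str) -> OccurrenceSet:
    """Read an ``id,x,y,label`` CSV; drops exact duplicate (x, y, label) rows.

    Labels are normalized to ``presence``/``absence`` (accepting 1/0,
    present/absent, p/a, ...).
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"id", "x", "y", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    try:
        df["x"] = df["x"].astype(float)
        df["y"] = df["y"].astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: unparseable coordinate: {exc}") from exc
    df["label"] = df["label"].map(_normalize_label)
    df["id"] = df["id"].astype(str)
    before = len(df)
    df = df.drop_duplicates(subset=["x", "y", "label"])
    dropped = before - len(df)
    if dropped:
        logger.warning("%s: dropped %d duplicate (x, y, label) records", path, dropped)
    return OccurrenceSet(df[["id", "x", "y", "label"]].reset_index(drop=True))


def write_points(pts: OccurrenceSet, path: str) -> str:
    pts.table.to_csv(path, index=False)
    return path


def extract_values(stack: EnvStack, pts: OccurrenceSet) -> pd.DataFrame:
    """Look up predictor values at each point's containing cell.

    Returns a frame with one row per *in-extent* point (id, x, y, label,
    one column per layer) plus a boolean ``valid`` column that is False
    for points landing on nodata cells; those rows are excluded from
    modelling by callers.  ``frame.attrs['n_out_of_extent']`` counts the
    dropped out-of-extent points.
    """
    template = stack.template
    xy = pts.xy
    if len(xy) == 0:
        raise ValueError("empty occurrence set")
    inside = template.in_extent(xy[:, 0], xy[:, 1])
    n_out = int((~inside).sum())
    if n_out:
        logger.warning("extract_values: %d point(s) outside raster extent", n_out)
    kept = pts.subset(inside)
    if len(kept) == 0:
        raise ValueError("no points fall inside the raster extent")
    rows, cols = template.cell_of(kept.xy[:, 0], kept.xy[:, 1])
    out = kept.table[["id", "x", "y", "label"]].copy()
    valid = np.ones(len(kept), dtype=bool)
    for name in stack.names:
        vals = stack[name].values[rows, cols]
        out[name] = vals
        valid &= ~np.isnan(vals)
    out["valid"] = valid
    if not valid.any():
        raise ValueError("all in-extent points fall on nodata cells")
    if (~valid).sum():
        logger.warning("extract_values: %d point(s) on nodata cells flagged invalid",
                       int((~valid).sum()))
    out.attrs["n_out_of_extent"] = n_out
    return out.reset_index(drop=True)
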