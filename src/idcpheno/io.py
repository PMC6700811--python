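"""Raster and vector I/O with fixed coordinate conventions.

Rasters are GeoTIFFs read and written through :mod:`tifffile`; the
georeferencing lives in the standard GeoTIFF tags (ModelPixelScale,
ModelTiepoint, GeoKeyDirectory) which are written and parsed here directly.
Only north-up rasters with square-axis pixel scales are supported — the
orthomosaics this pipeline consumes are produced that way.

Vector plot boundaries travel as GeoJSON FeatureCollections with the
attributes ``plot_id`` (unique), ``trial_id``, ``entry_id`` and ``block_id``.

Coordinate conventions
----------------------
Pixel indices are 0-based ``(row, col)`` with row 0 at the top (maximum
northing).  The world coordinate of a pixel *center* is::

    x = origin_x + (col + 0.5) * pixel_width
    y = origin_y - (row + 0.5) * pixel_height

A pixel belongs to a polygon iff its center lies inside; centers exactly on
the boundary count as inside on the minimum-row / minimum-col (top / left)
edges only.  This deterministic rule replaces whatever a GIS zonal-statistics
plugin happens to do and makes the zonal extraction exactly testable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from shapely import contains_xy
from shapely.geometry import mapping as shp_mapping, shape as shp_shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
# GeoKey ids
_KEY_GT_MODEL_TYPE = 1024
_KEY_GEOGRAPHIC_TYPE = 2048
_KEY_PROJECTED_CS_TYPE = 3072

REQUIRED_PLOT_ATTRS = ("plot_id", "trial_id", "entry_id", "block_id")

#: Relative inward shift applied to pixel centers before the point-in-polygon
#: test; implements the "boundary counts on the top/left edge" rule.
_EDGE_EPS = 1e-7


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine transform: world origin at the top-left raster corner."""

    origin_x: float
    origin_y: float
    pixel_width: float
    pixel_height: float

    def __post_init__(self) -> None:
        if self.pixel_width <= 0 or self.pixel_height <= 0:
            raise ValueError(
                f"pixel size must be positive, got "
                f"{self.pixel_width} x {self.pixel_height}"
            )

    def pixel_center(self, row, col):
        """World (x, y) of the center of pixel (row, col); accepts arrays."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.pixel_width
        y = self.origin_y - (np.asarray(row) + 0.5) * self.pixel_height
        return x, y

    def world_to_pixel(self, x, y):
        """Fractional (row, col) of a world coordinate."""
        col = (np.asarray(x) - self.origin_x) / self.pixel_width
        row = (self.origin_y - np.asarray(y)) / self.pixel_height
        return row, col


@dataclass
class RgbRaster:
    """Georeferenced 3-band 8-bit pixel grid, band order R, G, B."""

    pixels: np.ndarray  # (rows, cols, 3) uint8
    transform: GeoTransform
    crs: str | None = None
    nodata: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"expected (rows, cols, 3) pixel array, got shape {self.pixels.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class PlotPolygonSet:
    """Plot-boundary polygons with trial design attributes.

    ``records`` is a list of dicts each holding the four required attributes;
    ``geometries`` the matching shapely polygons.
    """

    records: list[dict]
    geometries: list[BaseGeometry]
    crs: str | None = None

    def __post_init__(self) -> None:
        if len(self.records) != len(self.geometries):
            raise ValueError("records and geometries length mismatch")
        seen: dict = {}
        for rec in self.records:
            missing = [a for a in REQUIRED_PLOT_ATTRS if a not in rec or rec[a] is None]
            if missing:
                raise ValueError(f"plot record missing attributes {missing}: {rec}")
            pid = rec["plot_id"]
            if pid in seen:
                raise ValueError(f"duplicate plot_id: {pid!r}")
            seen[pid] = True
        for rec, geom in zip(self.records, self.geometries):
            if geom.is_empty:
                raise ValueError(f"empty geometry for plot_id {rec['plot_id']!r}")

    def __len__(self) -> int:
        return len(self.records)

    def plot_ids(self) -> list:
        return [r["plot_id"] for r in self.records]


# ---------------------------------------------------------------------------
# GeoTIFF


def _geo_extratags(transform: GeoTransform, crs: str | None):
    tags = [
        (
            _TAG_MODEL_PIXEL_SCALE,
            "d",
            3,
            (transform.pixel_width, transform.pixel_height, 0.0),
            True,
        ),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, transform.origin_x, transform.origin_y, 0.0),
            True,
        ),
    ]
    if crs is not None:
        epsg = _epsg_code(crs)
        if epsg is not None:
            # Minimal key directory: projected model type + the EPSG code.
            keys = (1, 1, 0, 2, _KEY_GT_MODEL_TYPE, 0, 1, 1,
                    _KEY_PROJECTED_CS_TYPE, 0, 1, epsg)
            tags.append((_TAG_GEO_KEY_DIRECTORY, "H", len(keys), keys, True))
    return tags


def _epsg_code(crs: str) -> int | None:
    s = str(crs).upper()
    if s.startswith("EPSG:"):
        try:
            return int(s.split(":", 1)[1])
        except ValueError:
            return None
    return None


def _parse_geotags(page) -> tuple[GeoTransform | None, str | None]:
    tags = page.tags
    transform = None
    crs = None
    scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
    tiepoint = tags.get(_TAG_MODEL_TIEPOINT)
    if scale is not None and tiepoint is not None:
        sx, sy = float(scale.value[0]), float(scale.value[1])
        i, j, _, x, y, _ = (float(v) for v in tiepoint.value[:6])
        # tiepoint maps raster (i=col, j=row) to world (x, y)
        origin_x = x - i * sx
        origin_y = y + j * sy
        transform = GeoTransform(origin_x, origin_y, sx, sy)
    keydir = tags.get(_TAG_GEO_KEY_DIRECTORY)
    if keydir is not None:
        vals = list(keydir.value)
        for off in range(4, len(vals) - 3, 4):
            key_id, location, _count, value = vals[off : off + 4]
            if location == 0 and key_id in (_KEY_PROJECTED_CS_TYPE, _KEY_GEOGRAPHIC_TYPE):
                crs = f"EPSG:{value}"
    return transform, crs


def write_orthomosaic(path, raster: RgbRaster) -> None:
    """Write a 3-band uint8 GeoTIFF."""
    tifffile.imwrite(
        str(path),
        np.ascontiguousarray(raster.pixels.astype(np.uint8)),
        photometric="rgb",
        extratags=_geo_extratags(raster.transform, raster.crs),
    )


def write_class_raster(path, labels: np.ndarray, transform: GeoTransform,
                       crs: str | None = None, description: str | None = None) -> None:
    """Write a 1-band uint8 label/mask GeoTIFF with optional provenance text."""
    kwargs = {}
    if description:
        kwargs["description"] = description
    tifffile.imwrite(
        str(path),
        np.ascontiguousarray(np.asarray(labels).astype(np.uint8)),
        photometric="minisblack",
        extratags=_geo_extratags(transform, crs),
        **kwargs,
    )


def read_orthomosaic(path, band_order: tuple[int, int, int] = (0, 1, 2)) -> RgbRaster:
    """Read a georeferenced orthomosaic, returning the first three bands as R,G,B.

    Parameters
    ----------
    band_order
        Permutation mapping file bands to (R, G, B); default assumes the file
        stores R,G,B in that order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        data = page.asarray()
        transform, crs = _parse_geotags(page)
    if data.ndim == 2:
        raise ValueError(f"{path.name}: expected >= 3 bands, found 1")
    if data.ndim == 3 and data.shape[0] in (3, 4) and data.shape[2] not in (3, 4):
        data = np.moveaxis(data, 0, 2)  # band-sequential layout
    if data.ndim != 3 or data.shape[2] < 3:
        nb = data.shape[2] if data.ndim == 3 else 1
        raise ValueError(f"{path.name}: expected >= 3 bands, found {nb}")
    if data.dtype != np.uint8:
        raise ValueError(
            f"{path.name}: unsupported dtype {data.dtype} (expected uint8 "
            f"8-bit digital numbers)"
        )
    rgb = data[:, :, list(band_order)]
    if transform is None:
        logger.warning("%s: no georeferencing tags found; using unit transform",
                       path.name)
        transform = GeoTransform(0.0, rgb.shape[0], 1.0, 1.0)
    return RgbRaster(pixels=rgb, transform=transform, crs=crs)


def read_class_raster(path) -> tuple[np.ndarray, GeoTransform, str | None]:
    """Read a 1-band label raster written by :func:`write_class_raster`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        data = page.asarray()
        transform, crs = _parse_geotags(page)
    if data.ndim != 2:
        raise ValueError(f"{path.name}: expected a single-band raster")
    if transform is None:
        transform = GeoTransform(0.0, data.shape[0], 1.0, 1.0)
    return data, transform, crs


# ---------------------------------------------------------------------------
# GeoJSON plot polygons


def write_plot_polygons(path, plots: PlotPolygonSet) -> None:
    features = []
    for rec, geom in zip(plots.records, plots.geometries):
        features.append(
            {"type": "Feature", "properties": dict(rec), "geometry": shp_mapping(geom)}
        )
    doc = {"type": "FeatureCollection", "features": features}
    if plots.crs is not None:
        doc["crs"] = {"type": "name", "properties": {"name": plots.crs}}
    Path(path).write_text(json.dumps(doc))


def read_plot_polygons(path, raster: RgbRaster | None = None) -> PlotPolygonSet:
    """Read plot polygons from GeoJSON and validate design attributes.

    If ``raster`` is given its CRS must match the vector CRS (when both are
    declared); a mismatch is an error — reproject upstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    doc = json.loads(path.read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path.name}: expected a GeoJSON FeatureCollection")
    crs = None
    if isinstance(doc.get("crs"), dict):
        crs = doc["crs"].get("properties", {}).get("name")
    records, geometries = [], []
    for feat in doc.get("features", []):
        records.append(dict(feat.get("properties") or {}))
        geometries.append(shp_shape(feat["geometry"]))
    plots = PlotPolygonSet(records=records, geometries=geometries, crs=crs)
    if raster is not None and raster.crs is not None and crs is not None:
        if _epsg_code(raster.crs) != _epsg_code(crs) and raster.crs != crs:
            raise ValueError(
                f"CRS mismatch: raster {raster.crs!r} vs plots {crs!r}; "
                f"reproject the vector layer to the raster CRS first"
            )
    return plots


# ---------------------------------------------------------------------------
# Pixel-in-polygon membership


def pixels_in_polygon(
    geom: BaseGeometry, transform: GeoTransform, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Rows and cols of raster pixels whose centers fall inside ``geom``.

    Implements the shared membership rule: center strictly inside counts;
    a center exactly on the boundary counts only on the top/left edges.
    Realised by nudging each test point by a sub-pixel epsilon towards
    increasing row and col before the containment test.

    Returns ``(rows, cols)`` index arrays clipped to the raster ``shape``.
    """
    nrows, ncols = shape
    minx, miny, maxx, maxy = geom.bounds
    r0, c0 = transform.world_to_pixel(minx, maxy)
    r1, c1 = transform.world_to_pixel(maxx, miny)
    row_lo = max(int(np.floor(r0 - 0.5)), 0)
    col_lo = max(int(np.floor(c0 - 0.5)), 0)
    row_hi = min(int(np.ceil(r1 + 0.5)), nrows)
    col_hi = min(int(np.ceil(c1 + 0.5)), ncols)
    if row_hi <= row_lo or col_hi <= col_lo:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    rr, cc = np.meshgrid(
        np.arange(row_lo, row_hi), np.arange(col_lo, col_hi), indexing="ij"
    )
    x, y = transform.pixel_center(rr.ravel(), cc.ravel())
    x = x + _EDGE_EPS * transform.pixel_width
    y = y - _EDGE_EPS * transform.pixel_height
    inside = contains_xy(geom, x, y)
    return rr.ravel()[inside], cc.ravel()[inside]
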