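"""Image, annotation and measurement I/O.

This module owns the coordinate and unit conventions used throughout the
package: images are indexed ``(row, col)`` with origin at the top-left,
coordinates are 0-based, and polygon containment is evaluated at pixel
centers. Physical units derive from a single isotropic pixel size in
micrometres; the area of one pixel is ``pixel_size_um**2`` µm².

Supported formats: plain/tiled TIFF and PNG for RGB images; single-channel
PNG/TIFF for label maps (integer class codes, see :class:`TissueClass`);
QuPath-style GeoJSON ``FeatureCollection`` for polygonal annotations (class
name read from the ``classification.name`` feature property); CSV for
measurement tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from PIL import Image
from shapely.geometry import shape as shapely_shape
from shapely.geometry import Polygon
from shapely.validation import make_valid

#: Acquisition pixel edge length (µm) of a 20x CD-31 IHC scan; used as the
#: default when an image carries no resolution metadata.
DEFAULT_PIXEL_SIZE_UM = 0.5034


class TissueClass(IntEnum):
    """The ten tissue classes of the segmentation model.

    Code order encodes the overwrite precedence used when rasterizing
    overlapping annotations and when breaking argmax ties (lower code wins):
    vessels first, background last.
    """

    VESSEL = 0
    LEUKOCYTE = 1
    NERVE = 2
    MUSCLE = 3
    LYMPHOCYTE = 4
    TUMOUR = 5
    BENIGN = 6
    ADIPOSE = 7
    STROMA = 8
    BACKGROUND = 9


N_CLASSES = len(TissueClass)

#: Precedence for overlapping annotations, highest first.
CLASS_PRECEDENCE: tuple[TissueClass, ...] = tuple(TissueClass)


@dataclass(frozen=True)
class ImageMeta:
    """Physical metadata of a 2-D image."""

    pixel_size_um: float
    width_px: int
    height_px: int

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    def px_to_um2(self, n_pixels: float) -> float:
        """Convert a pixel count to an area in µm²."""
        return float(n_pixels) * self.pixel_area_um2

    def px_to_mm2(self, n_pixels: float) -> float:
        return self.px_to_um2(n_pixels) * 1e-6

    def um_to_px(self, distance_um: float) -> float:
        """Convert a physical distance to (fractional) pixels."""
        return distance_um / self.pixel_size_um


@dataclass
class LabelMap:
    """Integer-coded class map with physical metadata."""

    codes: np.ndarray  # (H, W) uint8
    meta: ImageMeta

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2:
            raise ValueError("label map must be 2-D")
        h, w = self.codes.shape
        if (w, h) != (self.meta.width_px, self.meta.height_px):
            raise ValueError(
                f"label map shape {self.codes.shape} does not match meta "
                f"({self.meta.height_px}, {self.meta.width_px})"
            )
        if self.codes.max(initial=0) >= N_CLASSES:
            raise ValueError("label map contains codes outside the tissue-class range")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def mask(self, cls: TissueClass) -> np.ndarray:
        return self.codes == int(cls)

    def one_hot(self) -> np.ndarray:
        """Expand to a (H, W, C) float32 one-hot stack."""
        return one_hot(self.codes)

    def class_counts(self) -> dict[TissueClass, int]:
        counts = np.bincount(self.codes.ravel(), minlength=N_CLASSES)
        return {cls: int(counts[cls]) for cls in TissueClass}

    def copy(self) -> "LabelMap":
        return LabelMap(self.codes.copy(), self.meta)


@dataclass
class AnnotationSet:
    """Polygonal annotations (pixel coordinates, (x=col, y=row)) with classes."""

    polygons: list[tuple[Polygon, TissueClass]]
    image_path: str | None = None


def one_hot(codes: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    out = np.zeros(codes.shape + (n_classes,), dtype=np.float32)
    rows, cols = np.indices(codes.shape)
    out[rows, cols, codes] = 1.0
    return out


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def read_image(path: str | Path, pixel_size_um: float | None = None) -> tuple[np.ndarray, ImageMeta]:
    """Read an RGB image and its physical metadata.

    TIFF resolution tags are honoured when present; otherwise
    ``pixel_size_um`` (or the package default) is used. Returns an
    8-bit ``(H, W, 3)`` array.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    suffix = path.suffix.lower()
    embedded: float | None = None
    if suffix in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            rgb = page.asarray()
            embedded = _tiff_pixel_size(page)
    elif suffix == ".png":
        rgb = np.asarray(Image.open(path).convert("RGB"))
    else:
        raise ValueError(f"unsupported image format: {suffix!r} (expected TIFF or PNG)")
    rgb = _as_rgb8(rgb)
    size = pixel_size_um if pixel_size_um is not None else embedded
    if size is None:
        size = DEFAULT_PIXEL_SIZE_UM
    meta = ImageMeta(pixel_size_um=float(size), width_px=rgb.shape[1], height_px=rgb.shape[0])
    return rgb, meta


def _tiff_pixel_size(page) -> float | None:
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    px_per_unit = num / den
    unit = tags["ResolutionUnit"].value
    unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit))  # inch, centimetre
    if unit_um is None:
        return None
    return unit_um / px_per_unit


def _as_rgb8(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return np.ascontiguousarray(arr)


def write_image(path: str | Path, rgb: np.ndarray, meta: ImageMeta | None = None) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        kwargs = {}
        if meta is not None:
            ppcm = 10000.0 / meta.pixel_size_um
            kwargs = {"resolution": (ppcm, ppcm), "resolutionunit": "CENTIMETER"}
        tifffile.imwrite(path, rgb, **kwargs)
    else:
        Image.fromarray(rgb).save(path)


# ---------------------------------------------------------------------------
# label maps
# ---------------------------------------------------------------------------


def read_labelmap(path: str | Path, pixel_size_um: float | None = None) -> LabelMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label map not found: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            codes = page.asarray()
            embedded = _tiff_pixel_size(page)
    else:
        codes = np.asarray(Image.open(path))
        embedded = None
    if codes.ndim != 2:
        raise ValueError("label maps must be single-channel")
    size = pixel_size_um if pixel_size_um is not None else (embedded or DEFAULT_PIXEL_SIZE_UM)
    meta = ImageMeta(float(size), width_px=codes.shape[1], height_px=codes.shape[0])
    return LabelMap(codes.astype(np.uint8), meta)


def write_labelmap(path: str | Path, labelmap: LabelMap) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        ppcm = 10000.0 / labelmap.meta.pixel_size_um
        tifffile.imwrite(path, labelmap.codes, resolution=(ppcm, ppcm), resolutionunit="CENTIMETER")
    else:
        Image.fromarray(labelmap.codes).save(path)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read a GeoJSON FeatureCollection of polygon annotations.

    The tissue class is taken from the feature property
    ``classification.name`` (case-insensitive); ``MultiPolygon`` geometries
    are split into their parts. Raises on unknown class names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    data = json.loads(path.read_text())
    features = data["features"] if data.get("type") == "FeatureCollection" else [data]
    polygons: list[tuple[Polygon, TissueClass]] = []
    for feat in features:
        props = feat.get("properties", {}) or {}
        classification = props.get("classification", {})
        if isinstance(classification, str):
            name = classification
        else:
            name = classification.get("name", props.get("name", ""))
        try:
            cls = TissueClass[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown tissue class in annotation file: {name!r}") from None
        geom = make_valid(shapely_shape(feat["geometry"]))
        for poly in _iter_polygons(geom):
            polygons.append((poly, cls))
    return AnnotationSet(polygons)


def _iter_polygons(geom) -> Iterator[Polygon]:
    if geom.is_empty:
        return
    if geom.geom_type == "Polygon":
        yield geom
    elif geom.geom_type in {"MultiPolygon", "GeometryCollection"}:
        for part in geom.geoms:
            yield from _iter_polygons(part)


def rasterize_annotations(
    annotations: AnnotationSet,
    meta: ImageMeta,
    precedence: Sequence[TissueClass] = CLASS_PRECEDENCE,
    tissue_extent: np.ndarray | None = None,
    fill_class: TissueClass = TissueClass.STROMA,
) -> LabelMap:
    """Rasterize polygon annotations to a label map.

    Unannotated pixels become ``fill_class`` (stroma — the "remaining
    tissue" rule) inside ``tissue_extent`` and BACKGROUND outside it; with no
    extent given, the whole canvas is treated as tissue. Overlaps resolve by
    ``precedence`` (vessels strongest). Polygons are clipped to the canvas by
    rasterization. Containment is evaluated at pixel centers.
    """
    h, w = meta.height_px, meta.width_px
    if tissue_extent is None:
        codes = np.full((h, w), int(fill_class), dtype=np.uint8)
    else:
        codes = np.where(tissue_extent, int(fill_class), int(TissueClass.BACKGROUND)).astype(np.uint8)
    rank = {cls: i for i, cls in enumerate(precedence)}
    # paint weakest first so stronger classes overwrite
    ordered = sorted(annotations.polygons, key=lambda pc: rank[pc[1]], reverse=True)
    for poly, cls in ordered:
        m = _rasterize_polygon(poly, (h, w))
        codes[m] = int(cls)
    return LabelMap(codes, meta)


def _rasterize_polygon(poly: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon
    (boundary-exclusive, i.e. half-open on pixel centers)."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(0, int(np.floor(minx)))
    c1 = min(w - 1, int(np.ceil(maxx)))
    r0 = max(0, int(np.floor(miny)))
    r1 = min(h - 1, int(np.ceil(maxy)))
    if c1 < c0 or r1 < r0:
        return mask
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    xx, yy = np.meshgrid(cols, rows)
    inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    return mask


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------


def mirror_pad(arr: np.ndarray, pad_h: int, pad_w: int) -> np.ndarray:
    """Reflect-pad the bottom/right edges, repeating when pads exceed dims."""
    while pad_h > 0 or pad_w > 0:
        step_h = min(pad_h, arr.shape[0] - 1)
        step_w = min(pad_w, arr.shape[1] - 1)
        pads = [(0, step_h), (0, step_w)] + [(0, 0)] * (arr.ndim - 2)
        arr = np.pad(arr, pads, mode="reflect")
        pad_h -= step_h
        pad_w -= step_w
    return arr


def extract_tiles(
    image: np.ndarray,
    labelmap: LabelMap | None,
    tile_px: int,
    stride_px: int,
) -> list[tuple[np.ndarray, np.ndarray | None]]:
    """Cut an image (and optional label map) into (rgb, one-hot mask) tiles.

    Images smaller than the tile grid are mirror-padded on the right/bottom.
    The grid covers the full image: the number of tiles per axis is
    ``ceil(max(dim - tile, 0) / stride) + 1``.
    """
    if tile_px <= 0 or stride_px <= 0:
        raise ValueError("tile and stride must be positive")
    h, w = image.shape[:2]
    pad_h = max(tile_px - h, (-(h - tile_px)) % stride_px if h > tile_px else 0)
    pad_w = max(tile_px - w, (-(w - tile_px)) % stride_px if w > tile_px else 0)
    if pad_h or pad_w:
        image = mirror_pad(image, pad_h, pad_w)
    codes = None
    if labelmap is not None:
        codes = labelmap.codes
        if pad_h or pad_w:
            codes = mirror_pad(codes, pad_h, pad_w)
    tiles = []
    hh, ww = image.shape[:2]
    for r0 in range(0, hh - tile_px + 1, stride_px):
        for c0 in range(0, ww - tile_px + 1, stride_px):
            rgb = image[r0 : r0 + tile_px, c0 : c0 + tile_px]
            mask = None
            if codes is not None:
                mask = one_hot(codes[r0 : r0 + tile_px, c0 : c0 + tile_px])
            tiles.append((rgb, mask))
    return tiles


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------


def write_measurements(records: Sequence[dict], path: str | Path, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Write one CSV row per vessel/region record; deterministic ordering."""
    df = pd.DataFrame(list(records), columns=columns)
    df.to_csv(path, index=False)
    return df


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
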