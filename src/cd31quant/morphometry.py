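"""Vessel instance extraction and vascular morphometry.

Five parameters per region of interest:

* **density** (#/mm²) — vessels per square millimetre of stroma (stroma
  plus lymphocyte pixels) within the region;
* **mean area** (µm²) — mean vessel surface area;
* **mean circularity** — ``4·π·Area / Perimeter²``, 1 for a perfect circle,
  decreasing towards 0 with shape complexity;
* **mean axis ratio** — long/short edge ratio of the minimum-area rotated
  bounding rectangle fitted over each vessel (elongation);
* **mean thickness** (µm) — maximal-inscribed-sphere fit: stamp, at every
  skeleton point, a disk with radius and value taken from the Euclidean
  distance map, keeping the maximum per pixel; thickness is the mean
  stamped value over the vessel (a trabecular-thickness style measure).

Vessels are 8-connected components of the vessel class; components smaller
than ``min_area_px`` (default 40 px, about 10 µm² at 0.5034 µm pixels) are
treated as noise and discarded. Perimeters use a sub-pixel (marching
squares) contour estimator: naive pixel-edge counting would give a disk a
circularity near 0.78 and break the circle anchor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure
from skimage.morphology import medial_axis

from .imageio import ImageMeta, LabelMap, TissueClass

MIN_VESSEL_AREA_PX = 40
_EIGHT = ndimage.generate_binary_structure(2, 2)


@dataclass
class VesselInstance:
    """One connected vessel component (local mask + bounding-box offset)."""

    mask: np.ndarray  # local boolean patch
    offset_rc: tuple[int, int]  # top-left of the patch in image coords
    area_px: int
    first_pixel_flat: int  # row-major index of the first pixel (ordering key)

    @property
    def centroid_rc(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return (float(rr.mean()) + self.offset_rc[0], float(cc.mean()) + self.offset_rc[1])

    def representative_rc(self) -> tuple[int, int]:
        """Centroid snapped to the nearest pixel of the instance."""
        rr, cc = np.nonzero(self.mask)
        cr = rr.mean()
        cc_m = cc.mean()
        k = int(np.argmin((rr - cr) ** 2 + (cc - cc_m) ** 2))
        return (int(rr[k]) + self.offset_rc[0], int(cc[k]) + self.offset_rc[1])


def circularity(area: float, perimeter: float) -> float:
    """``4·π·A / P²`` — exactly 1 for an analytic circle (A=πr², P=2πr)."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * math.pi * area / perimeter**2


def label_vessels(labelmap: LabelMap, min_area_px: int = MIN_VESSEL_AREA_PX) -> list[VesselInstance]:
    """8-connected vessel components, size-filtered, in scanline order."""
    mask = labelmap.mask(TissueClass.VESSEL)
    lab, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return []
    w = mask.shape[1]
    instances = []
    slices = ndimage.find_objects(lab)
    for i, sl in enumerate(slices, start=1):
        local = lab[sl] == i
        area = int(local.sum())
        if area < min_area_px:
            continue
        rr, cc = np.nonzero(local)
        flat = (rr + sl[0].start) * w + (cc + sl[1].start)
        instances.append(
            VesselInstance(
                mask=local,
                offset_rc=(sl[0].start, sl[1].start),
                area_px=area,
                first_pixel_flat=int(flat.min()),
            )
        )
    instances.sort(key=lambda v: v.first_pixel_flat)
    return instances


def measure_area(instance: VesselInstance, meta: ImageMeta) -> float:
    """Surface area in µm² (pixel count × pixel area)."""
    return meta.px_to_um2(instance.area_px)


def measure_perimeter_px(instance: VesselInstance) -> float:
    """Sub-pixel contour length: marching squares on the half-level set of a
    lightly smoothed mask.

    Smoothing (sigma scaled to the object's inscribed radius, capped at
    2 px) removes the rasterization staircase that would otherwise inflate
    a disk's perimeter by ~6%; with it, a digital disk of radius 50 px
    measures within 0.1% of 2πr. Falls back to the unsmoothed contour for
    objects too thin to survive smoothing.
    """
    mask = instance.mask.astype(float)
    r_in = float(ndimage.distance_transform_edt(instance.mask).max())
    sigma = float(np.clip(r_in / 3.0, 0.5, 2.0))
    pad = int(np.ceil(3 * sigma)) + 1
    smoothed = ndimage.gaussian_filter(np.pad(mask, pad), sigma)
    total = _contour_length(smoothed)
    if total == 0.0:
        total = _contour_length(np.pad(mask, 1))
    return total


def _contour_length(image: np.ndarray) -> float:
    total = 0.0
    for contour in measure.find_contours(image, 0.5):
        total += float(np.sqrt((np.diff(contour, axis=0) ** 2).sum(axis=1)).sum())
    return total


def measure_circularity(instance: VesselInstance, clip: bool = True) -> float:
    """``4πA/P²`` from the pixel area and estimated perimeter, clipped to 1."""
    c = circularity(instance.area_px, measure_perimeter_px(instance))
    return min(c, 1.0) if clip else c


def _min_area_rect_edges(points: np.ndarray) -> tuple[float, float]:
    """Edge lengths (long, short) of the minimum-area rotated rectangle
    enclosing the points (rotating calipers over convex-hull edges)."""
    try:
        hull = ConvexHull(points)
    except QhullError:  # collinear points
        span = points.max(axis=0) - points.min(axis=0)
        long = float(max(span))
        return max(long, 1.0), 1.0
    pts = points[hull.vertices]
    edges = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    angles = np.unique(np.mod(np.arctan2(edges[:, 1], edges[:, 0]), np.pi / 2))
    best = None
    for theta in angles:
        c, s = np.cos(theta), np.sin(theta)
        rot = pts @ np.array([[c, -s], [s, c]])
        ext = rot.max(axis=0) - rot.min(axis=0)
        area = ext[0] * ext[1]
        if best is None or area < best[0]:
            best = (area, float(max(ext)), float(min(ext)))
    return best[1], best[2]


def measure_axis_ratio(instance: VesselInstance) -> float:
    """Long/short edge ratio (≥ 1) of the minimum-area bounding rectangle.

    The rectangle is fitted over the pixel *corners* so an axis-aligned
    n×m pixel block measures exactly n×m.
    """
    rr, cc = np.nonzero(instance.mask)
    centers = np.column_stack([rr, cc]).astype(float)
    corners = np.concatenate([centers + [dr, dc] for dr in (-0.5, 0.5) for dc in (-0.5, 0.5)])
    long, short = _min_area_rect_edges(corners)
    return long / max(short, 1e-9)


def thickness_map_px(mask: np.ndarray, centers: np.ndarray | None = None) -> np.ndarray:
    """Sphere-stamped local thickness map (pixel radii).

    Compute the Euclidean distance map of ``mask``; at every center pixel
    (default: the medial-axis skeleton) stamp a disk of radius equal to the
    distance value, carrying that value; keep per-pixel maxima.
    """
    dist = ndimage.distance_transform_edt(mask)
    if centers is None:
        # medial axis plus distance-ridge maxima: discrete medial axes can
        # miss the deepest pixel of round components, which would truncate
        # the largest inscribed sphere
        maxima = mask & (dist == ndimage.maximum_filter(dist, size=3))
        centers = medial_axis(mask) | maxima
    out = np.zeros_like(dist)
    h, w = mask.shape
    rr, cc = np.nonzero(centers)
    radii = dist[rr, cc]
    for r0, c0, rad in sorted(zip(rr, cc, radii), key=lambda t: t[2]):
        ri = int(np.ceil(rad))
        r1, r2 = max(0, r0 - ri), min(h, r0 + ri + 1)
        c1, c2 = max(0, c0 - ri), min(w, c0 + ri + 1)
        yy, xx = np.ogrid[r1:r2, c1:c2]
        disk = ((yy - r0) ** 2 + (xx - c0) ** 2) <= rad**2
        patch = out[r1:r2, c1:c2]
        np.maximum(patch, np.where(disk, rad, 0.0), out=patch)
    return np.where(mask, out, 0.0)


def measure_thickness(instance: VesselInstance, meta: ImageMeta, scale: str = "radius") -> float:
    """Mean fitted-sphere thickness in µm.

    ``scale="radius"`` reports the stamped distance-map value itself;
    ``scale="diameter"`` doubles it (the trabecular-thickness convention).
    """
    if scale not in {"radius", "diameter"}:
        raise ValueError("scale must be 'radius' or 'diameter'")
    tmap = thickness_map_px(instance.mask)
    mean_px = float(tmap[instance.mask].mean())
    factor = 2.0 if scale == "diameter" else 1.0
    return mean_px * factor * meta.pixel_size_um


def stromal_area_mm2(region_mask: np.ndarray, labelmap: LabelMap) -> float:
    """Area (mm²) of stroma-plus-lymphocyte pixels inside a region."""
    stroma = labelmap.mask(TissueClass.STROMA) | labelmap.mask(TissueClass.LYMPHOCYTE)
    return labelmap.meta.px_to_mm2(int((stroma & region_mask).sum()))


def vessels_in_region(vessels: list[VesselInstance], region_mask: np.ndarray) -> list[VesselInstance]:
    """Vessels whose snapped centroid lies inside the region (each vessel is
    assigned to exactly one region even if it straddles a boundary)."""
    return [v for v in vessels if region_mask[v.representative_rc()]]


def measure_density(
    vessels: list[VesselInstance],
    region_mask: np.ndarray,
    labelmap: LabelMap,
) -> float:
    """Vessels per mm² of stroma within the region; NaN when no stroma."""
    area = stromal_area_mm2(region_mask, labelmap)
    if area == 0:
        return float("nan")
    return len(vessels_in_region(vessels, region_mask)) / area


@dataclass
class VascularParams:
    """Summary of the five vascular parameters over one region."""

    region: str
    n_vessels: int
    density_per_mm2: float
    mean_area_um2: float
    mean_circularity: float
    mean_axis_ratio: float
    mean_thickness_um: float

    def as_dict(self) -> dict:
        return {
            "region": self.region,
            "n_vessels": self.n_vessels,
            "density_per_mm2": self.density_per_mm2,
            "mean_area_um2": self.mean_area_um2,
            "mean_circularity": self.mean_circularity,
            "mean_axis_ratio": self.mean_axis_ratio,
            "mean_thickness_um": self.mean_thickness_um,
        }


def summarize(
    vessels: list[VesselInstance],
    region_mask: np.ndarray,
    labelmap: LabelMap,
    region: str = "all",
    thickness_scale: str = "radius",
) -> VascularParams:
    """Unweighted means of the per-vessel parameters over a region."""
    meta = labelmap.meta
    inside = vessels_in_region(vessels, region_mask)
    nan = float("nan")
    if not inside:
        density = measure_density(vessels, region_mask, labelmap)
        return VascularParams(region, 0, density, nan, nan, nan, nan)
    return VascularParams(
        region=region,
        n_vessels=len(inside),
        density_per_mm2=measure_density(vessels, region_mask, labelmap),
        mean_area_um2=float(np.mean([measure_area(v, meta) for v in inside])),
        mean_circularity=float(np.mean([measure_circularity(v) for v in inside])),
        mean_axis_ratio=float(np.mean([measure_axis_ratio(v) for v in inside])),
        mean_thickness_um=float(np.mean([measure_thickness(v, meta, thickness_scale) for v in inside])),
    )


def vessel_table(vessels: list[VesselInstance], meta: ImageMeta, thickness_scale: str = "radius") -> list[dict]:
    """One record per vessel, ready for ``imageio.write_measurements``."""
    records = []
    for i, v in enumerate(vessels):
        r, c = v.centroid_rc
        records.append(
            {
                "vessel_id": i,
                "centroid_row": r,
                "centroid_col": c,
                "area_px": v.area_px,
                "area_um2": measure_area(v, meta),
                "perimeter_um": measure_perimeter_px(v) * meta.pixel_size_um,
                "circularity": measure_circularity(v),
                "axis_ratio": measure_axis_ratio(v),
                "thickness_um": measure_thickness(v, meta, thickness_scale),
            }
        )
    return records
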