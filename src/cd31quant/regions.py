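"""Regional micro-environment analyses.

* Partition the tissue into tumour / adipose / stroma regions by dilating
  the tumour and adipose segmentations 150 µm outwards in small alternating
  increments, neither ever claiming the other's pixels, with everything
  left over (lymphocyte clusters included) forming the stroma region.
* Distance-ring analyses: consecutive 25 µm rings around a seed structure
  (vessels or tumour) carrying lymphocyte percentage or vessel
  density/size as a function of distance.
* Composition metrics: lymphocyte percentage (lymphocyte area over
  combined stroma-plus-lymphocyte area), tumour-stroma ratio and a
  tumour-infiltrating-lymphocyte percentage within the tumour region.
* Group statistics: two-tailed t-tests (paired for consecutive rings)
  with Benjamini-Hochberg correction, and Pearson correlation of predicted
  against ground-truth vascular parameters.

Micron-calibrated dilations are computed by thresholding the Euclidean
distance transform (equivalent to a disk dilation but less anisotropic at
small radii).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .imageio import ImageMeta, LabelMap, TissueClass
from .morphometry import VesselInstance, measure_area, measure_density, vessels_in_region

_EIGHT = ndimage.generate_binary_structure(2, 2)

MIN_REGION_PX = 1000  # tumour/adipose specks below this are artefacts (~250 µm²)


@dataclass
class RegionPartition:
    """Disjoint tumour/adipose/stroma masks covering the tissue extent."""

    tumour_region: np.ndarray
    adipose_region: np.ndarray
    stroma_region: np.ndarray
    meta: ImageMeta
    dilation_um: float = 150.0

    def region(self, name: str) -> np.ndarray:
        return getattr(self, f"{name}_region")


@dataclass
class RingSet:
    """Ordered disjoint rings of equal physical width around a seed mask."""

    rings: list[np.ndarray]
    ring_width_um: float
    meta: ImageMeta

    def __len__(self) -> int:
        return len(self.rings)


@dataclass
class CompositionMetrics:
    lymphocyte_percentage: float  # over the whole tissue extent
    tumour_stroma_ratio: float  # within the tumour region
    til_percentage: float  # lymphocyte % within the tumour region


def _filter_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[lab]


def _ball(dist: np.ndarray, radius_px: float) -> np.ndarray:
    """Euclidean dilation of the seed whose distance map is ``dist``."""
    return dist <= radius_px


def partition_regions(
    labelmap: LabelMap,
    dilation_um: float = 150.0,
    min_region_px: int = MIN_REGION_PX,
    step_um: float = 5.0,
) -> RegionPartition:
    """Tumour/adipose/stroma partition by alternating calibrated dilation.

    Tumour and adipose components below ``min_region_px`` are excluded
    first. The two regions then grow alternately in ``step_um`` increments
    up to ``dilation_um`` total, each increment clipped to tissue and
    forbidden from claiming the other's pixels, so the meeting front ends
    near the midline when the structures are close.
    """
    if step_um <= 0 or step_um > dilation_um:
        raise ValueError("step_um must be in (0, dilation_um]")
    meta = labelmap.meta
    tissue = ~labelmap.mask(TissueClass.BACKGROUND)
    tum0 = _filter_small(labelmap.mask(TissueClass.TUMOUR), min_region_px)
    adi0 = _filter_small(labelmap.mask(TissueClass.ADIPOSE), min_region_px)
    tum, adi = tum0.copy(), adi0.copy()
    d_tum = ndimage.distance_transform_edt(~tum0) if tum0.any() else None
    d_adi = ndimage.distance_transform_edt(~adi0) if adi0.any() else None
    n_steps = int(round(dilation_um / step_um))
    for k in range(1, n_steps + 1):
        r_px = meta.um_to_px(k * step_um)
        if d_tum is not None:
            tum |= _ball(d_tum, r_px) & tissue & ~adi
        if d_adi is not None:
            adi |= _ball(d_adi, r_px) & tissue & ~tum
    stroma = tissue & ~tum & ~adi
    return RegionPartition(tum, adi, stroma, meta, dilation_um)


def distance_rings(
    seed_mask: np.ndarray,
    meta: ImageMeta,
    ring_width_um: float = 25.0,
    n_rings: int = 8,
    tissue_mask: np.ndarray | None = None,
) -> RingSet:
    """Consecutive rings: ring k holds pixels at Euclidean distance
    ``((k-1)·w, k·w]`` µm from the seed, clipped to the tissue extent and
    excluding the seed itself."""
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    d = ndimage.distance_transform_edt(~seed_mask) * meta.pixel_size_um
    rings = []
    for k in range(1, n_rings + 1):
        ring = (d > (k - 1) * ring_width_um) & (d <= k * ring_width_um) & ~seed_mask
        if tissue_mask is not None:
            ring = ring & tissue_mask
        rings.append(ring)
    return RingSet(rings, ring_width_um, meta)


def lymphocyte_percentage(mask: np.ndarray, labelmap: LabelMap) -> float:
    """100 · lymphocyte area / (stroma + lymphocyte) area within a mask."""
    lymph = int((labelmap.mask(TissueClass.LYMPHOCYTE) & mask).sum())
    stroma = int((labelmap.mask(TissueClass.STROMA) & mask).sum())
    denom = lymph + stroma
    if denom == 0:
        return float("nan")
    return 100.0 * lymph / denom


def lymphocytes_by_distance(rings: RingSet, labelmap: LabelMap) -> pd.DataFrame:
    rows = []
    for k, ring in enumerate(rings.rings, start=1):
        rows.append(
            {
                "ring": k,
                "distance_um": k * rings.ring_width_um,
                "lymphocyte_pct": lymphocyte_percentage(ring, labelmap),
                "ring_px": int(ring.sum()),
            }
        )
    return pd.DataFrame(rows)


def vessels_by_distance(
    vessels: list[VesselInstance],
    rings: RingSet,
    labelmap: LabelMap,
) -> pd.DataFrame:
    """Per-ring vessel density (#/mm² of stroma) and mean vessel size."""
    rows = []
    for k, ring in enumerate(rings.rings, start=1):
        inside = vessels_in_region(vessels, ring)
        mean_area = (
            float(np.mean([measure_area(v, labelmap.meta) for v in inside])) if inside else float("nan")
        )
        rows.append(
            {
                "ring": k,
                "distance_um": k * rings.ring_width_um,
                "n_vessels": len(inside),
                "density_per_mm2": measure_density(vessels, ring, labelmap),
                "mean_area_um2": mean_area,
            }
        )
    return pd.DataFrame(rows)


def composition(partition: RegionPartition, labelmap: LabelMap) -> CompositionMetrics:
    """Tumour-stroma ratio and TIL percentage within the tumour region,
    plus the global lymphocyte percentage."""
    tissue = ~labelmap.mask(TissueClass.BACKGROUND)
    region = partition.tumour_region
    t_px = int((labelmap.mask(TissueClass.TUMOUR) & region).sum())
    s_px = int(((labelmap.mask(TissueClass.STROMA) | labelmap.mask(TissueClass.LYMPHOCYTE)) & region).sum())
    tsr = t_px / s_px if s_px > 0 else float("nan")
    return CompositionMetrics(
        lymphocyte_percentage=lymphocyte_percentage(tissue, labelmap),
        tumour_stroma_ratio=tsr,
        til_percentage=lymphocyte_percentage(region, labelmap),
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def compare_groups(
    values_by_group: dict[str, np.ndarray],
    paired: bool = False,
    correct: bool = True,
    consecutive_only: bool = False,
) -> pd.DataFrame:
    """Two-tailed t-tests between groups, optionally BH-corrected.

    ``paired`` uses matched observations (e.g. per-patient values in
    consecutive rings); ``consecutive_only`` restricts comparisons to
    adjacent groups in insertion order, the layout of ring analyses.
    Groups with insufficient observations yield NaN with a warning.
    """
    names = list(values_by_group)
    pairs = list(zip(names[:-1], names[1:])) if consecutive_only else list(combinations(names, 2))
    rows = []
    for a, b in pairs:
        xa = np.asarray(values_by_group[a], dtype=float)
        xb = np.asarray(values_by_group[b], dtype=float)
        if paired:
            ok = np.isfinite(xa) & np.isfinite(xb)
            xa, xb = xa[ok], xb[ok]
        else:
            xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
        enough = (len(xa) >= 2 and len(xa) == len(xb)) if paired else (len(xa) >= 2 and len(xb) >= 2)
        if not enough:
            warnings.warn(f"insufficient observations for {a} vs {b}; reporting NaN", stacklevel=2)
            rows.append({"group1": a, "group2": b, "t": float("nan"), "p": float("nan")})
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            if paired:
                t, p = stats.ttest_rel(xa, xb)
            else:
                t, p = stats.ttest_ind(xa, xb)
        rows.append({"group1": a, "group2": b, "t": float(t), "p": float(p)})
    df = pd.DataFrame(rows)
    if correct and len(df):
        df["p_adj"] = benjamini_hochberg(df["p"].to_numpy())
    return df


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Step-up FDR-adjusted p-values; NaNs propagate."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = stats.false_discovery_control(p[ok], method="bh")
    return out


def correlate_parameters(pred: pd.DataFrame, true: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (and two-tailed p) per shared numeric parameter column."""
    rows = []
    for col in pred.columns:
        if col not in true.columns or not np.issubdtype(pred[col].dtype, np.number):
            continue
        x = pred[col].to_numpy(dtype=float)
        y = true[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            rows.append({"parameter": col, "r": float("nan"), "p": float("nan"), "n": len(x)})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"parameter": col, "r": float(r), "p": float(p), "n": len(x)})
    return pd.DataFrame(rows)
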