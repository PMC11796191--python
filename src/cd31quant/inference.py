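"""Whole-image prediction by sliding window with center-weighted blending.

Tiles of ``tile_px`` (default 512) are predicted with an overlap of
``overlap_px`` (default 128); per-tile probabilities are blended with a
weight that falls off linearly with the Chebyshev distance to the tile
center, ``w(x) = max(1 - d_inf(x)/d_max, 1e-3)``, floored so pixels covered
by a single tile keep their mass, then renormalised per pixel. Class labels
are obtained afterwards by per-pixel majority voting (argmax; exact ties go
to the lower class code, i.e. the higher-precedence tissue class).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .imageio import ImageMeta, LabelMap, N_CLASSES, mirror_pad

WEIGHT_FLOOR = 1e-3


@dataclass
class ProbabilityStack:
    """(H, W, C) per-class probabilities with physical metadata."""

    probs: np.ndarray
    meta: ImageMeta

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float32)
        if self.probs.ndim != 3:
            raise ValueError("probability stack must be (H, W, C)")

    @property
    def n_classes(self) -> int:
        return self.probs.shape[-1]


def tile_weight(tile_px: int) -> np.ndarray:
    """Blending weight map: linear ramp from 1 at the tile center to the
    floor at the border (Chebyshev distance)."""
    coords = np.arange(tile_px, dtype=np.float64)
    center = (tile_px - 1) / 2.0
    d = np.abs(coords - center)
    d_inf = np.maximum(d[:, None], d[None, :])
    w = 1.0 - d_inf / (tile_px / 2.0)
    return np.maximum(w, WEIGHT_FLOOR)


def _starts(dim: int, tile: int, stride: int) -> list[int]:
    starts = list(range(0, dim - tile + 1, stride))
    if starts[-1] + tile < dim:
        starts.append(dim - tile)  # last window shifted to end at the border
    return starts


def predict_slide(
    image: np.ndarray,
    network: Callable[[np.ndarray], np.ndarray],
    tile_px: int = 512,
    overlap_px: int = 128,
    meta: ImageMeta | None = None,
    pixel_size_um: float | None = None,
) -> ProbabilityStack:
    """Predict per-class probabilities for an arbitrarily sized image.

    ``network`` maps an (tile, tile, 3) image to (tile, tile, C)
    probabilities. Images smaller than one tile are mirror-padded for
    prediction and cropped back.
    """
    if overlap_px >= tile_px:
        raise ValueError(f"overlap ({overlap_px}) must be smaller than tile ({tile_px})")
    h, w = image.shape[:2]
    pad_h = max(0, tile_px - h)
    pad_w = max(0, tile_px - w)
    padded = mirror_pad(image, pad_h, pad_w) if (pad_h or pad_w) else image
    hh, ww = padded.shape[:2]
    stride = tile_px - overlap_px
    wmap = tile_weight(tile_px)

    acc: np.ndarray | None = None
    wsum = np.zeros((hh, ww), dtype=np.float64)
    for r0 in _starts(hh, tile_px, stride):
        for c0 in _starts(ww, tile_px, stride):
            probs = np.asarray(network(padded[r0 : r0 + tile_px, c0 : c0 + tile_px]), dtype=np.float64)
            if acc is None:
                acc = np.zeros((hh, ww, probs.shape[-1]), dtype=np.float64)
            acc[r0 : r0 + tile_px, c0 : c0 + tile_px] += probs * wmap[:, :, None]
            wsum[r0 : r0 + tile_px, c0 : c0 + tile_px] += wmap
    blended = acc / wsum[:, :, None]
    blended /= blended.sum(axis=-1, keepdims=True)
    blended = blended[:h, :w]

    if meta is None:
        size = pixel_size_um if pixel_size_um is not None else 1.0
        meta = ImageMeta(size, width_px=w, height_px=h)
    return ProbabilityStack(blended.astype(np.float32), meta)


def vote(stack: ProbabilityStack) -> LabelMap:
    """Per-pixel majority vote; ties break to the lower class code."""
    codes = np.argmax(stack.probs, axis=-1).astype(np.uint8)
    return LabelMap(codes, stack.meta)


def one_hot_stack(labelmap: LabelMap, n_classes: int = N_CLASSES) -> ProbabilityStack:
    """Lift a label map to a degenerate probability stack (vote round-trips)."""
    return ProbabilityStack(labelmap.one_hot()[..., :n_classes], labelmap.meta)
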