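"""Class-aware cleanup cascade applied after inference.

Probability smoothing (all classes except vessels and leukocytes, which
keep their fine detail) followed by four hole-filling rules applied in
order:

1. holes inside background components smaller than 10000 px become
   background (no class protection — matching the rule as stated);
2. holes inside stroma smaller than 1000 px become stroma, never
   overwriting vessel or leukocyte pixels;
3. holes inside adipose smaller than 10000 px become adipose, with the
   same protection;
4. holes inside vessel components become vessel, overwriting any class,
   with no size limit — this is what recovers filled lumina from annular
   staining.

A "hole" is a connected component of non-class pixels fully enclosed by the
class (not touching the image border); holes use 4-connectivity, foreground
8-connectivity (the standard duality). Size thresholds are strict
(``smaller than``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imageio import LabelMap, TissueClass
from .inference import ProbabilityStack, vote

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass(frozen=True)
class PostprocessConfig:
    smoothing_sigma: float = 2.0
    background_hole_px: int = 10000
    stroma_hole_px: int = 1000
    adipose_hole_px: int = 10000
    protected: tuple[TissueClass, ...] = (TissueClass.VESSEL, TissueClass.LEUKOCYTE)

    def __post_init__(self) -> None:
        if min(self.background_hole_px, self.stroma_hole_px, self.adipose_hole_px) <= 0:
            raise ValueError("hole thresholds must be positive")
        if self.smoothing_sigma < 0:
            raise ValueError("sigma must be >= 0")


def smooth_probabilities(stack: ProbabilityStack, sigma: float = 2.0,
                         exempt: tuple[TissueClass, ...] = (TissueClass.VESSEL, TissueClass.LEUKOCYTE)) -> ProbabilityStack:
    """Gaussian-smooth all class planes except the exempt ones; renormalise."""
    if sigma == 0:
        return ProbabilityStack(stack.probs.copy(), stack.meta)
    probs = stack.probs.astype(np.float64).copy()
    exempt_codes = {int(c) for c in exempt}
    for j in range(stack.n_classes):
        if j not in exempt_codes:
            probs[:, :, j] = ndimage.gaussian_filter(probs[:, :, j], sigma)
    probs /= probs.sum(axis=-1, keepdims=True)
    return ProbabilityStack(probs.astype(np.float32), stack.meta)


def _fill_holes(codes: np.ndarray, cls: TissueClass, max_px: int | None,
                protected: tuple[TissueClass, ...]) -> None:
    """Fill enclosed holes of ``cls`` in place, respecting protections."""
    mask = codes == int(cls)
    filled = ndimage.binary_fill_holes(mask, structure=_CROSS)
    holes = filled & ~mask
    if not holes.any():
        return
    lab, n = ndimage.label(holes, structure=_CROSS)
    if max_px is not None:
        sizes = np.bincount(lab.ravel())
        keep = sizes < max_px
        keep[0] = False
        holes = keep[lab]
    if protected:
        prot = np.isin(codes, [int(c) for c in protected])
        holes &= ~prot
    codes[holes] = int(cls)


def apply_cascade(labelmap: LabelMap, config: PostprocessConfig | None = None) -> LabelMap:
    """Run the four hole-filling rules in order on a copy of the label map."""
    config = config or PostprocessConfig()
    codes = labelmap.codes.copy()
    _fill_holes(codes, TissueClass.BACKGROUND, config.background_hole_px, ())
    _fill_holes(codes, TissueClass.STROMA, config.stroma_hole_px, config.protected)
    _fill_holes(codes, TissueClass.ADIPOSE, config.adipose_hole_px, config.protected)
    _fill_holes(codes, TissueClass.VESSEL, None, ())
    return LabelMap(codes, labelmap.meta)


def postprocess(stack: ProbabilityStack, config: PostprocessConfig | None = None) -> LabelMap:
    """Smooth, vote and run the cascade — the standard inference tail."""
    config = config or PostprocessConfig()
    smoothed = smooth_probabilities(stack, config.smoothing_sigma, exempt=config.protected)
    return apply_cascade(vote(smoothed), config)
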