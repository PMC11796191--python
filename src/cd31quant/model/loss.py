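"""Class-weighted soft Dice training objective.

For prediction probabilities ``p`` (per pixel i, class j) and one-hot ground
truth ``g``, the loss is::

    L(p, g) = 1 - sum_j  w_j / sum_l w_l  *  (2 sum_i p_ij g_ij + s)
                                            / (sum_i p_ij + sum_i g_ij + s)

with class weights ``w`` reflecting prevalence and importance (vessels
weighted highest) and an optional smoothing term ``s``. With ``s = 0`` a
class absent from both prediction and truth contributes a Dice term of 1
(a vacuously perfect class), so the loss stays in [0, 1], is 0 exactly at
perfect one-hot agreement and 1 at total hard disagreement. Training uses a
small positive ``s`` to keep gradients finite near empty classes.

Pixels flagged in an ignore mask (unannotated space on partially annotated
slides) are excluded from every sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..imageio import N_CLASSES, TissueClass

#: Default class weights: prevalent classes get 1, intermediate 2, rare 5,
#: vessels — the structure the model exists for — 10.
DEFAULT_CLASS_WEIGHTS: dict[TissueClass, float] = {
    TissueClass.VESSEL: 10.0,
    TissueClass.LEUKOCYTE: 5.0,
    TissueClass.NERVE: 5.0,
    TissueClass.TUMOUR: 2.0,
    TissueClass.BENIGN: 2.0,
    TissueClass.LYMPHOCYTE: 2.0,
    TissueClass.MUSCLE: 2.0,
    TissueClass.ADIPOSE: 1.0,
    TissueClass.STROMA: 1.0,
    TissueClass.BACKGROUND: 1.0,
}


@dataclass(frozen=True)
class ClassWeights:
    """Positive per-class weights, normalised inside the loss."""

    weights: dict[TissueClass, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("class weights must be positive")

    def as_array(self) -> np.ndarray:
        arr = np.ones(N_CLASSES, dtype=np.float64)
        for cls, w in self.weights.items():
            arr[int(cls)] = w
        return arr


def _flatten(p: np.ndarray, g: np.ndarray, ignore: np.ndarray | None):
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"p and g shapes differ: {p.shape} vs {g.shape}")
    if p.ndim == 1:  # single-class vector of pixels
        p = p[:, None]
        g = g[:, None]
    c = p.shape[-1]
    pf = p.reshape(-1, c)
    gf = g.reshape(-1, c)
    if ignore is not None:
        keep = ~np.asarray(ignore, dtype=bool).reshape(-1)
        pf = pf[keep]
        gf = gf[keep]
    return pf, gf, p.shape


def weighted_soft_dice_loss(
    p: np.ndarray,
    g: np.ndarray,
    weights: ClassWeights | np.ndarray | None = None,
    smooth: float = 0.0,
    ignore: np.ndarray | None = None,
) -> float:
    """Evaluate the loss; class axis is the last axis (any leading shape)."""
    loss, _ = weighted_soft_dice_loss_grad(p, g, weights, smooth=smooth, ignore=ignore)
    return loss


def weighted_soft_dice_loss_grad(
    p: np.ndarray,
    g: np.ndarray,
    weights: ClassWeights | np.ndarray | None = None,
    smooth: float = 0.0,
    ignore: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to ``p`` (same shape as ``p``)."""
    pf, gf, orig_shape = _flatten(p, g, ignore)
    c = pf.shape[1]
    if weights is None:
        w = np.ones(c)
    elif isinstance(weights, ClassWeights):
        w = weights.as_array()[:c]
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (c,):
            raise ValueError(f"expected {c} class weights, got shape {w.shape}")
    wn = w / w.sum()

    num = 2.0 * (pf * gf).sum(axis=0) + smooth
    den = pf.sum(axis=0) + gf.sum(axis=0) + smooth
    dice = np.ones(c)
    active = den > 0
    dice[active] = num[active] / den[active]
    loss = 1.0 - float((wn * dice).sum())

    # d dice_j / d p_ij = (2 g_ij * den_j - num_j) / den_j^2
    grad_flat = np.zeros_like(pf)
    if active.any():
        d2 = den[active] ** 2
        grad_flat[:, active] = -wn[active] * (2.0 * gf[:, active] * den[active] - num[active]) / d2
    grad = np.zeros(int(np.prod(orig_shape[:-1])) * c, dtype=np.float64).reshape(-1, c)
    if ignore is not None:
        keep = ~np.asarray(ignore, dtype=bool).reshape(-1)
        grad[keep] = grad_flat
    else:
        grad = grad_flat
    return loss, grad.reshape(orig_shape)
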