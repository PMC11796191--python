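"""Training-time data augmentation.

Geometric transforms (flips, quarter-turn and free-angle rotation with
mirror padding at the borders) are applied identically to the image and the
mask; photometric jitter (brightness, contrast, saturation, hue) touches the
image only. Masks travel as one-hot stacks and are resampled
nearest-neighbour via their label codes, so they remain exactly one-hot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..imageio import one_hot


@dataclass(frozen=True)
class AugmentConfig:
    flip_prob: float = 0.5
    rot90: bool = True
    rot_free_prob: float = 0.3
    rot_max_deg: float = 180.0
    brightness: float = 0.1
    contrast: float = 0.1
    saturation: float = 0.1
    hue: float = 0.02


def rotate_mirror(rgb: np.ndarray, mask: np.ndarray, angle_deg: float):
    """Rotate image and one-hot mask about the center, mirror-padded.

    Quarter turns are exact (pure pixel permutations); other angles use
    bilinear resampling for the image and nearest-neighbour for the labels.
    """
    angle_deg = angle_deg % 360.0
    if angle_deg % 90 == 0:
        k = int(angle_deg // 90)
        return np.rot90(rgb, k, axes=(0, 1)).copy(), np.rot90(mask, k, axes=(0, 1)).copy()
    codes = np.argmax(mask, axis=-1).astype(np.uint8)
    rgb_r = ndimage.rotate(rgb, angle_deg, reshape=False, order=1, mode="mirror")
    codes_r = ndimage.rotate(codes, angle_deg, reshape=False, order=0, mode="mirror")
    return rgb_r, one_hot(codes_r, n_classes=mask.shape[-1])


def color_jitter(rgb: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig) -> np.ndarray:
    """Random brightness/contrast/saturation/hue perturbation of an 8-bit image."""
    x = rgb.astype(np.float32) / 255.0
    x = x * (1 + rng.uniform(-cfg.contrast, cfg.contrast))
    x = x + rng.uniform(-cfg.brightness, cfg.brightness)
    gray = x.mean(axis=-1, keepdims=True)
    x = gray + (x - gray) * (1 + rng.uniform(-cfg.saturation, cfg.saturation))
    if cfg.hue > 0:
        # small-angle hue rotation about the gray axis
        theta = rng.uniform(-cfg.hue, cfg.hue) * 2 * np.pi
        u = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        k = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
        rot = np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)
        x = x @ rot.T
    return np.clip(x * 255.0, 0, 255).astype(rgb.dtype if rgb.dtype == np.uint8 else np.uint8)


def augment(rgb: np.ndarray, mask: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig | None = None):
    """One random augmentation draw; returns (rgb', one-hot mask')."""
    cfg = cfg or AugmentConfig()
    if rng.uniform() < cfg.flip_prob:
        rgb, mask = rgb[:, ::-1].copy(), mask[:, ::-1].copy()
    if rng.uniform() < cfg.flip_prob:
        rgb, mask = rgb[::-1].copy(), mask[::-1].copy()
    if cfg.rot90:
        k = int(rng.integers(0, 4))
        rgb = np.rot90(rgb, k, axes=(0, 1)).copy()
        mask = np.rot90(mask, k, axes=(0, 1)).copy()
    if rng.uniform() < cfg.rot_free_prob:
        angle = float(rng.uniform(-cfg.rot_max_deg, cfg.rot_max_deg))
        rgb, mask = rotate_mirror(rgb, mask, angle)
    rgb = color_jitter(rgb, rng, cfg)
    return rgb, mask
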