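"""Seeded generator of synthetic CD-31-like scenes with exact ground truth.

The generator emulates the gross appearance of DAB/hematoxylin-stained
breast tissue at 20x: brown annular vessel walls with unstained lumina
(optionally fragmented, as happens when the stain binds unevenly or the wall
is lost to sectioning), blue-purple nuclei in tumour nests, dense blue
lymphocyte clusters, white adipose vacuoles, pale nerve bundles, small brown
CD-31-positive leukocytes, pink stroma texture and a near-white slide
background.

Two deliberate asymmetries between the RGB image and the ground truth:

* Vessel ground truth is the *filled* vessel (wall plus lumen), while the
  RGB shows only the stained annulus — real annotations treat vessels as
  filled objects and the post-processing cascade fills lumina.
* Fragmentation deletes angular sectors of the annulus in RGB only, never
  in the ground truth, so the pipeline is tested on recovering complete
  vessels from incomplete staining.

Every scene is a pure function of the configuration (same seed, bit-identical
output).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imageio import DEFAULT_PIXEL_SIZE_UM, ImageMeta, LabelMap, TissueClass, write_image, write_labelmap

# fixed stain-like colour means (RGB); jitter is applied per structure
COLORS: dict[str, tuple[float, float, float]] = {
    "stroma": (232, 180, 196),  # eosinophilic pink
    "background": (248, 248, 246),
    "vessel_wall": (133, 80, 38),  # DAB brown
    "lumen": (246, 243, 240),  # unstained
    "nucleus": (72, 52, 130),  # hematoxylin blue-purple
    "lymphocyte": (58, 48, 120),
    "adipose": (250, 248, 248),
    "adipose_rim": (210, 190, 198),
    "nerve": (225, 195, 205),
    "leukocyte": (120, 75, 45),
}


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of a synthetic scene; all randomness flows from ``seed``."""

    seed: int = 0
    canvas_px: int = 512
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_vessels: int = 6
    n_tumour_nests: int = 1
    n_adipose: int = 4
    n_lymphocyte_clusters: int = 2
    n_nerves: int = 0
    n_leukocytes: int = 3
    vessel_outer_radius_px: tuple[float, float] = (8.0, 22.0)
    vessel_wall_px: tuple[float, float] = (3.0, 6.0)
    vessel_elongation: tuple[float, float] = (1.0, 2.5)
    wall_gap_prob: float = 0.25
    wall_gap_deg: tuple[float, float] = (20.0, 60.0)
    tumour_radius_px: tuple[float, float] = (40.0, 70.0)
    adipose_radius_px: tuple[float, float] = (10.0, 22.0)
    lymph_radius_px: tuple[float, float] = (14.0, 26.0)
    nerve_radius_px: tuple[float, float] = (12.0, 20.0)
    leukocyte_radius_px: tuple[float, float] = (2.0, 4.0)
    color_jitter: float = 8.0
    noise_sigma: float = 5.0
    blur_sigma: float = 0.6
    background_margin_px: int = 0
    max_place_attempts: int = 300

    def __post_init__(self) -> None:
        for name in ("n_vessels", "n_tumour_nests", "n_adipose", "n_lymphocyte_clusters", "n_nerves", "n_leukocytes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.vessel_outer_radius_px[0] <= 0:
            raise ValueError("vessel radii must be positive")
        if self.canvas_px < 8:
            raise ValueError("canvas too small")


def _ellipse_mask(shape, center, a, b, angle):
    """Pixels whose centers lie inside a rotated ellipse (semi-axes a >= b)."""
    rr, cc = np.indices(shape)
    dy = rr - center[0]
    dx = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _blob_mask(shape, center, radius, rng, roughness=0.25, n_harm=5):
    """Irregular star-convex blob: radius perturbed by random harmonics."""
    rr, cc = np.indices(shape)
    dy = rr - center[0]
    dx = cc - center[1]
    theta = np.arctan2(dy, dx)
    r = np.sqrt(dy**2 + dx**2)
    mod = np.ones_like(theta)
    for k in range(1, n_harm + 1):
        amp = roughness * rng.uniform(0, 1) / k
        phase = rng.uniform(0, 2 * np.pi)
        mod += amp * np.cos(k * theta + phase)
    return r <= radius * mod


def _scatter_dots(rgb, inside, rng, color, dot_r, density, jitter):
    """Stipple nuclei-like dots of radius ~dot_r over the masked area."""
    idx = np.flatnonzero(inside.ravel())
    if idx.size == 0:
        return
    n = max(1, int(density * idx.size / (np.pi * dot_r**2)))
    picks = rng.choice(idx, size=min(n, idx.size), replace=False)
    h, w = inside.shape
    rr, cc = np.divmod(picks, w)
    base = np.asarray(color, float)
    for r0, c0 in zip(rr, cc):
        rad = dot_r * rng.uniform(0.7, 1.3)
        r1, r2 = max(0, int(r0 - rad)), min(h, int(r0 + rad) + 1)
        c1, c2 = max(0, int(c0 - rad)), min(w, int(c0 + rad) + 1)
        yy, xx = np.ogrid[r1:r2, c1:c2]
        dot = ((yy - r0) ** 2 + (xx - c0) ** 2) <= rad**2
        col = np.clip(base + rng.normal(0, jitter, 3), 0, 255)
        rgb[r1:r2, c1:c2][dot] = col


class PlacementError(ValueError):
    """Raised when the requested structures cannot be placed on the canvas."""


def generate_scene(config: SynthConfig, rng: np.random.Generator | None = None):
    """Draw one scene.

    Returns ``(rgb, labelmap, instances)`` where ``instances`` is a list of
    ground-truth vessel records (center, semi-axes, wall thickness, pixel
    area, axis ratio, fragmentation flag).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.canvas_px
    shape = (n, n)
    jit = config.color_jitter

    codes = np.full(shape, int(TissueClass.STROMA), dtype=np.uint8)
    rgb = np.empty((n, n, 3), dtype=np.float64)
    base = np.asarray(COLORS["stroma"], float)
    rgb[:] = base + rng.normal(0, jit, 3)
    # coarse stroma texture: low-frequency multiplicative field
    tex = ndimage.gaussian_filter(rng.normal(0, 1, shape), 12)
    tex = 1 + 0.08 * tex / (np.abs(tex).max() + 1e-9)
    rgb *= tex[..., None]

    if config.background_margin_px > 0:
        m = config.background_margin_px
        codes[:, :m] = int(TissueClass.BACKGROUND)
        rgb[:, :m] = np.asarray(COLORS["background"], float) + rng.normal(0, 2, 3)

    occupied = codes != int(TissueClass.STROMA)

    def place(radius_needed, margin=2.0):
        """Rejection-sample a center keeping the structure inside tissue and
        clear of previously placed structures."""
        if 2 * radius_needed >= n - config.background_margin_px:
            raise PlacementError(
                f"structure of radius {radius_needed:.0f}px cannot fit on a {n}px canvas"
            )
        for _ in range(config.max_place_attempts):
            r0 = rng.uniform(radius_needed, n - radius_needed)
            c0 = rng.uniform(radius_needed + config.background_margin_px, n - radius_needed)
            rr = int(round(r0))
            cc = int(round(c0))
            reach = int(np.ceil(radius_needed + margin))
            r1, r2 = max(0, rr - reach), min(n, rr + reach + 1)
            c1, c2 = max(0, cc - reach), min(n, cc + reach + 1)
            if not occupied[r1:r2, c1:c2].any():
                return (r0, c0)
        raise PlacementError(
            f"could not place a structure of radius {radius_needed:.0f}px on a "
            f"{n}px canvas with {int(occupied.sum())}px already occupied"
        )

    instances: list[dict] = []

    # --- tumour nests (placed first: largest) -----------------------------
    for _ in range(config.n_tumour_nests):
        rad = rng.uniform(*config.tumour_radius_px)
        center = place(rad * 1.25)
        mask = _blob_mask(shape, center, rad, rng) & ~occupied
        codes[mask] = int(TissueClass.TUMOUR)
        rgb[mask] = np.asarray(COLORS["stroma"], float) * 0.92 + rng.normal(0, jit, 3)
        _scatter_dots(rgb, mask, rng, COLORS["nucleus"], dot_r=3.0, density=0.55, jitter=jit)
        occupied |= mask

    # --- nerves -----------------------------------------------------------
    for _ in range(config.n_nerves):
        rad = rng.uniform(*config.nerve_radius_px)
        elong = rng.uniform(1.8, 3.0)
        center = place(rad * elong)
        mask = _ellipse_mask(shape, center, rad * elong, rad, rng.uniform(0, np.pi)) & ~occupied
        codes[mask] = int(TissueClass.NERVE)
        rgb[mask] = np.asarray(COLORS["nerve"], float) + rng.normal(0, jit, 3)
        _scatter_dots(rgb, mask, rng, COLORS["nucleus"], dot_r=1.5, density=0.08, jitter=jit)
        occupied |= mask

    # --- adipose vacuoles -------------------------------------------------
    for _ in range(config.n_adipose):
        rad = rng.uniform(*config.adipose_radius_px)
        center = place(rad)
        outer = _ellipse_mask(shape, center, rad, rad * rng.uniform(0.85, 1.0), rng.uniform(0, np.pi))
        mask = outer & ~occupied
        codes[mask] = int(TissueClass.ADIPOSE)
        rgb[mask] = np.asarray(COLORS["adipose"], float) + rng.normal(0, 2, 3)
        rim = outer & ~ndimage.binary_erosion(outer, iterations=2)
        rgb[rim & mask] = np.asarray(COLORS["adipose_rim"], float) + rng.normal(0, jit, 3)
        occupied |= mask

    # --- lymphocyte clusters ----------------------------------------------
    for _ in range(config.n_lymphocyte_clusters):
        rad = rng.uniform(*config.lymph_radius_px)
        center = place(rad * 1.25)
        mask = _blob_mask(shape, center, rad, rng, roughness=0.35) & ~occupied
        codes[mask] = int(TissueClass.LYMPHOCYTE)
        rgb[mask] = np.asarray(COLORS["stroma"], float) * 0.9 + rng.normal(0, jit, 3)
        _scatter_dots(rgb, mask, rng, COLORS["lymphocyte"], dot_r=2.0, density=0.85, jitter=jit)
        occupied |= mask

    # --- leukocytes (small brown singlets) ---------------------------------
    for _ in range(config.n_leukocytes):
        rad = rng.uniform(*config.leukocyte_radius_px)
        center = place(rad)
        mask = _ellipse_mask(shape, center, rad, rad, 0.0) & ~occupied
        codes[mask] = int(TissueClass.LEUKOCYTE)
        rgb[mask] = np.asarray(COLORS["leukocyte"], float) + rng.normal(0, jit, 3)
        occupied |= mask

    # --- vessels ------------------------------------------------------------
    for _ in range(config.n_vessels):
        r_out = rng.uniform(*config.vessel_outer_radius_px)
        elong = rng.uniform(*config.vessel_elongation)
        wall = rng.uniform(*config.vessel_wall_px)
        wall = min(wall, r_out - 1.0)
        a, b = r_out * np.sqrt(elong), r_out / np.sqrt(elong)
        b = max(b, wall + 1.5)
        angle = rng.uniform(0, np.pi)
        center = place(max(a, b))
        outer = _ellipse_mask(shape, center, a, b, angle)
        inner = _ellipse_mask(shape, center, max(a - wall, 0.5), max(b - wall, 0.5), angle)
        gt = outer & ~occupied  # GT: filled vessel (wall + lumen)
        codes[gt] = int(TissueClass.VESSEL)

        annulus = (outer & ~inner) & gt
        fragmented = bool(rng.uniform() < config.wall_gap_prob)
        if fragmented:
            rr_idx, cc_idx = np.indices(shape)
            theta = np.arctan2(rr_idx - center[0], cc_idx - center[1])
            for _g in range(rng.integers(1, 3)):
                g0 = rng.uniform(-np.pi, np.pi)
                width = np.deg2rad(rng.uniform(*config.wall_gap_deg))
                dtheta = np.angle(np.exp(1j * (theta - g0)))
                annulus &= ~(np.abs(dtheta) <= width / 2)
        rgb[inner & gt] = np.asarray(COLORS["lumen"], float) + rng.normal(0, 2, 3)
        rgb[(outer & ~inner & gt) & ~annulus] = base + rng.normal(0, jit, 3)  # missing wall
        rgb[annulus] = np.asarray(COLORS["vessel_wall"], float) + rng.normal(0, jit, 3)
        occupied |= gt

        instances.append(
            {
                "center_rc": [float(center[0]), float(center[1])],
                "semi_axis_major_px": float(max(a, b)),
                "semi_axis_minor_px": float(min(a, b)),
                "angle_rad": float(angle),
                "wall_px": float(wall),
                "area_px": int(gt.sum()),
                "axis_ratio": float(max(a, b) / min(a, b)),
                "fragmented": fragmented,
            }
        )

    if config.blur_sigma > 0:
        rgb = ndimage.gaussian_filter(rgb, (config.blur_sigma, config.blur_sigma, 0))
    rgb += rng.normal(0, config.noise_sigma, rgb.shape)
    rgb8 = np.clip(rgb, 0, 255).astype(np.uint8)

    meta = ImageMeta(config.pixel_size_um, width_px=n, height_px=n)
    return rgb8, LabelMap(codes, meta), instances


def uniform_marker_labelmap(
    seed: int,
    canvas_px: int = 512,
    pixel_size_um: float = 1.0,
    seed_disk_radius_px: float = 50.0,
    marker_fraction: float = 0.15,
    marker_dot_px: float = 6.0,
) -> LabelMap:
    """Calibration scene: a central tumour disk in stroma with lymphocyte
    dots scattered uniformly (spatially homogeneous marker).

    Used to verify that ring analyses report a flat profile for a marker
    with no true distance dependence. Marker dots may touch the tumour
    border, so no placement bias is introduced near the seed.
    """
    rng = np.random.default_rng(seed)
    shape = (canvas_px, canvas_px)
    codes = np.full(shape, int(TissueClass.STROMA), dtype=np.uint8)
    center = (canvas_px / 2, canvas_px / 2)
    tumour = _ellipse_mask(shape, center, seed_disk_radius_px, seed_disk_radius_px, 0.0)
    stroma_px = int((~tumour).sum())
    n_dots = int(marker_fraction * stroma_px / (np.pi * marker_dot_px**2))
    rad = int(np.ceil(marker_dot_px))
    for _ in range(n_dots):
        r0 = rng.uniform(0, canvas_px)
        c0 = rng.uniform(0, canvas_px)
        r1, r2 = max(0, int(r0 - rad)), min(canvas_px, int(r0 + rad) + 2)
        c1, c2 = max(0, int(c0 - rad)), min(canvas_px, int(c0 + rad) + 2)
        if r1 >= r2 or c1 >= c2:
            continue
        yy, xx = np.ogrid[r1:r2, c1:c2]
        dot = ((yy - r0) ** 2 + (xx - c0) ** 2) <= marker_dot_px**2
        patch = codes[r1:r2, c1:c2]
        patch[dot & ~tumour[r1:r2, c1:c2]] = int(TissueClass.LYMPHOCYTE)
    codes[tumour] = int(TissueClass.TUMOUR)
    meta = ImageMeta(pixel_size_um, width_px=canvas_px, height_px=canvas_px)
    return LabelMap(codes, meta)


def generate_dataset(config: SynthConfig, n_tiles: int, out_dir: str | Path) -> dict:
    """Write ``n_tiles`` (rgb, mask) pairs plus a JSON manifest to disk.

    Tile ``i`` is the scene for seed ``config.seed + i``. Returns the
    manifest (paths, per-tile ground-truth instances, class-balance summary).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    totals = np.zeros(len(TissueClass), dtype=np.int64)
    for i in range(n_tiles):
        cfg = replace(config, seed=config.seed + i)
        rgb, labelmap, instances = generate_scene(cfg)
        img_path = out / f"tile_{i:04d}.png"
        mask_path = out / f"mask_{i:04d}.png"
        write_image(img_path, rgb)
        write_labelmap(mask_path, labelmap)
        totals += np.bincount(labelmap.codes.ravel(), minlength=len(TissueClass))
        entries.append({"image": img_path.name, "mask": mask_path.name, "seed": cfg.seed, "instances": instances})
    manifest = {
        "config": asdict(config),
        "n_tiles": n_tiles,
        "class_pixels": {cls.name: int(totals[cls]) for cls in TissueClass},
        "tiles": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
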