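"""Synthetic leaf-image datasets with known ground truth.

Real light-box photographs of jujube leaves (single leaf, white A4
background, even LED illumination) are not redistributable, so this
generator emulates the acquisition conditions for testing the full
pipeline: an elliptical leaf with random eccentricity and rotation and
an optional darker midrib stripe, rendered over a near-white noisy
background.

SPAD values are drawn from a truncated normal matching the field
measurements being emulated (mean 42.05, SD 5.99, range 21.90–55.90).
The leaf color responds linearly to the standardised SPAD value s̃:

    mean RGB = (R0 − aR·s̃,  G0 + aG·s̃,  B0 + aB·s̃)

so greener/bluer leaves carry more chlorophyll while red dominance
falls — the sign structure seen in real leaf/color correlations (e.g.
(G+B−R)/2G rises with SPAD, R−B falls).  The exact mask and noise-free
mean color are returned with every image, giving segmentation and
feature extraction an absolute ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .imaging import LeafMask, MeanChannelColor

__all__ = ["SyntheticConfig", "sample_spad", "render_leaf", "generate_dataset", "generate_arrays"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults emulate the 520-leaf light-box study."""

    n_samples: int = 520
    spad_mean: float = 42.05
    spad_sd: float = 5.99
    spad_min: float = 21.90
    spad_max: float = 55.90
    image_size: tuple[int, int] = (256, 256)
    base_rgb: tuple[float, float, float] = (90.0, 130.0, 60.0)
    response: tuple[float, float, float] = (25.0, 10.0, 8.0)  # (aR, aG, aB)
    pixel_noise_sd: float = 4.0
    illumination_gradient: float = 0.0
    background_rgb: tuple[float, float, float] = (250.0, 250.0, 250.0)
    background_noise_sd: float = 3.0
    midrib: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spad_min > self.spad_max:
            raise ConfigError(f"SPAD bounds inverted: [{self.spad_min}, {self.spad_max}]")
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if min(self.image_size) < 16:
            raise ConfigError("image_size must be at least 16×16")

    def standardize(self, spad: float) -> float:
        return (spad - self.spad_mean) / self.spad_sd

    def leaf_mean_rgb(self, spad: float) -> tuple[float, float, float]:
        s = self.standardize(spad)
        r0, g0, b0 = self.base_rgb
        ar, ag, ab = self.response
        rgb = (r0 - ar * s, g0 + ag * s, b0 + ab * s)
        if not all(0.0 < c < 255.0 for c in rgb):
            raise ConfigError(f"color response leaves [0,255] at SPAD {spad}: {rgb}")
        return rgb


def sample_spad(cfg: SyntheticConfig, n: int, seed: int | None = None) -> np.ndarray:
    """i.i.d. truncated-normal SPAD draws within the configured bounds."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    if cfg.spad_min == cfg.spad_max:
        return np.full(n, cfg.spad_min)
    a = (cfg.spad_min - cfg.spad_mean) / cfg.spad_sd
    b = (cfg.spad_max - cfg.spad_mean) / cfg.spad_sd
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return stats.truncnorm.rvs(a, b, loc=cfg.spad_mean, scale=cfg.spad_sd,
                               size=n, random_state=rng)


def render_leaf(
    spad: float,
    cfg: SyntheticConfig,
    seed: int = 0,
) -> tuple[np.ndarray, LeafMask, MeanChannelColor]:
    """Render one leaf image; returns (image, true mask, noise-free mean color).

    The leaf is an ellipse with random semi-axes (30–42% of the short
    image side) and rotation; the optional midrib is a thin darker
    stripe along the major axis.  Per-pixel Gaussian noise is added to
    the leaf, milder noise to the near-white background.
    """
    rng = np.random.default_rng(seed)
    H, W = cfg.image_size
    short = min(H, W)
    cy = H / 2 + rng.uniform(-0.05, 0.05) * H
    cx = W / 2 + rng.uniform(-0.05, 0.05) * W
    a = rng.uniform(0.30, 0.42) * short          # semi-major
    b = a * rng.uniform(0.45, 0.75)              # semi-minor
    theta = rng.uniform(0, np.pi)

    yy, xx = np.mgrid[0:H, 0:W]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if not mask.any():
        raise ConfigError("leaf area is empty at the requested image size")

    mean_rgb = np.array(cfg.leaf_mean_rgb(spad))
    img = np.empty((H, W, 3))
    img[:] = np.array(cfg.background_rgb)
    if cfg.background_noise_sd > 0:
        img += rng.normal(0, cfg.background_noise_sd, size=img.shape)

    leaf = np.tile(mean_rgb, (int(mask.sum()), 1))
    if cfg.midrib:
        # thin darker stripe along the major axis (like a central vein)
        stripe = np.abs(v[mask]) <= max(1.0, 0.02 * short)
        leaf[stripe] *= 0.9
    if cfg.pixel_noise_sd > 0:
        leaf += rng.normal(0, cfg.pixel_noise_sd, size=leaf.shape)
    img[mask] = leaf
    if cfg.illumination_gradient > 0:
        ramp = 1.0 + cfg.illumination_gradient * (xx / max(W - 1, 1) - 0.5)
        img *= ramp[..., None]
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    from skimage import measure
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len) if contours else np.empty((0, 2))
    leaf_mask = LeafMask(mask=mask, contour=contour, area_px=int(mask.sum()))
    true_color = MeanChannelColor(mean_R=float(mean_rgb[0]), mean_G=float(mean_rgb[1]),
                                  mean_B=float(mean_rgb[2]), n_pixels=leaf_mask.area_px)
    return img, leaf_mask, true_color


def generate_arrays(
    cfg: SyntheticConfig,
) -> tuple[list[np.ndarray], list[LeafMask], list[MeanChannelColor], np.ndarray]:
    """In-memory dataset: images, true masks, true mean colors, SPAD vector."""
    spad = sample_spad(cfg, cfg.n_samples)
    # derive independent per-image render seeds from the master seed
    seeds = np.random.default_rng(cfg.seed).integers(0, 2**31 - 1, size=cfg.n_samples)
    imgs, masks, colors = [], [], []
    for s, rs in zip(spad, seeds):
        img, m, c = render_leaf(float(s), cfg, seed=int(rs))
        imgs.append(img)
        masks.append(m)
        colors.append(c)
    return imgs, masks, colors, spad


def generate_dataset(cfg: SyntheticConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write images, masks, and a manifest CSV; returns the manifest.

    Layout: ``images/leaf_0000.png``, ``masks/leaf_0000.png``, and
    ``manifest.csv`` with columns filename, spad, true mean color, mask
    path.  Fully reproducible from ``cfg.seed``.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    imgs, masks, colors, spad = generate_arrays(cfg)
    rows = []
    for i, (img, m, c, s) in enumerate(zip(imgs, masks, colors, spad)):
        name = f"leaf_{i:04d}.png"
        iio.imwrite(out / "images" / name, img)
        iio.imwrite(out / "masks" / name, m.mask.astype(np.uint8) * 255)
        rows.append({
            "filename": f"images/{name}", "spad": float(s),
            "true_mean_R": c.mean_R, "true_mean_G": c.mean_G, "true_mean_B": c.mean_B,
            "mask": f"masks/{name}",
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
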