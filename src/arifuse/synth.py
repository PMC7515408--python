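"""Deterministic synthetic image pairs for fusion-metric experiments.

Real fusion benchmarks come as (a) multi-focus pairs — two photographs of
one scene with complementary in-focus regions — and (b) multi-modal pairs
such as CT/MR, two nonlinear intensity renderings of shared anatomy with
modality-exclusive content.  This module emulates the statistical
structure those benchmarks contribute (complementary sharpness; shared
latent structure plus exclusive components) with fully procedural,
seed-reproducible scenes, so every metric property can be tested with no
external download.  No anatomical realism is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .image import GrayImage

__all__ = [
    "SynthSpec",
    "make_latent_scene",
    "make_multifocus_pair",
    "make_multimodal_pair",
    "make_degradation_ladder",
    "gaussian_blur",
    "mean_abs_laplacian",
]

_SCENES = ("texture", "shapes", "mixed")
_SPLITS = ("left-right", "quadrant", "mask")


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic experiment.

    Attributes
    ----------
    height, width
        Raster size in pixels (each >= 32).
    seed
        Seed for all randomness; same spec + seed is bit-reproducible.
    scene
        Latent-scene family: smooth filtered ``texture``, hard-edged
        ``shapes``, or their ``mixed`` overlay (default; widest gray-level
        coverage).
    blur_sigma
        Defocus strength for multi-focus pairs, in pixels of Gaussian
        sigma; 0 leaves the latent scene untouched.
    split
        Geometry of the out-of-focus region: ``left-right`` halves,
        ``quadrant`` checkerboard of image quadrants, or a smooth random
        ``mask`` thresholded at its median.
    modality_gamma
        Contrast exponent of the first modality's intensity remap; the
        second modality uses the reciprocal exponent.  1 makes both remaps
        the identity.
    exclusive_fraction
        Fraction of the image area per modality replaced by
        modality-exclusive content (smoothed independent noise).
    """

    height: int = 256
    width: int = 256
    seed: int = 0
    scene: str = "mixed"
    blur_sigma: float = 3.0
    split: str = "left-right"
    modality_gamma: float = 1.8
    exclusive_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("scene dimensions must be at least 32x32")
        if self.scene not in _SCENES:
            raise ValueError(f"scene must be one of {_SCENES}")
        if self.split not in _SPLITS:
            raise ValueError(f"split must be one of {_SPLITS}")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if not (self.modality_gamma > 0):
            raise ValueError("modality_gamma must be > 0")
        if not (0.0 <= self.exclusive_fraction <= 1.0):
            raise ValueError("exclusive_fraction must lie in [0, 1]")


def gaussian_blur(img: GrayImage, sigma: float) -> GrayImage:
    """Gaussian blur with reflection borders; sigma in pixels, 0 is identity."""
    if sigma == 0:
        return img
    out = ndimage.gaussian_filter(img.astype_float(), sigma, mode="reflect")
    return GrayImage(np.clip(np.rint(out), 0, img.max_level).astype(np.int64), img.depth)


def mean_abs_laplacian(img: GrayImage, region: np.ndarray | None = None) -> float:
    """Mean absolute Laplacian response — a simple sharpness score."""
    lap = np.abs(ndimage.laplace(img.astype_float(), mode="reflect"))
    if region is not None:
        lap = lap[region]
    return float(lap.mean())


# ---------------------------------------------------------------------------
# Latent scenes
# ---------------------------------------------------------------------------

def _texture_field(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Filtered noise plus a few sinusoidal gratings; values roughly [0, 1]."""
    field = ndimage.gaussian_filter(rng.standard_normal((h, w)), 3.0, mode="reflect")
    field += 0.5 * ndimage.gaussian_filter(rng.standard_normal((h, w)), 12.0, mode="reflect")
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    for _ in range(3):
        theta = rng.uniform(0, np.pi)
        freq = rng.uniform(0.02, 0.12)
        phase = rng.uniform(0, 2 * np.pi)
        field += 0.3 * np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)) + phase)
    lo, hi = field.min(), field.max()
    return (field - lo) / (hi - lo)


def _shape_field(rng: np.random.Generator, h: int, w: int, n_shapes: int = 24) -> np.ndarray:
    """Overlapping random rectangles, disks and oriented bars on a mid-gray canvas."""
    canvas = np.full((h, w), 0.5)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    for _ in range(n_shapes):
        kind = rng.integers(3)
        level = rng.uniform(0.0, 1.0)
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        if kind == 0:  # rectangle
            hh, ww = rng.uniform(0.05, 0.3) * h, rng.uniform(0.05, 0.3) * w
            mask = (np.abs(yy - cy) < hh / 2) & (np.abs(xx - cx) < ww / 2)
        elif kind == 1:  # disk
            r = rng.uniform(0.03, 0.18) * min(h, w)
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 < r * r
        else:  # oriented bar
            theta = rng.uniform(0, np.pi)
            t = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
            u = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
            mask = (np.abs(t) < rng.uniform(0.02, 0.08) * min(h, w)) & (
                np.abs(u) < rng.uniform(0.1, 0.45) * min(h, w)
            )
        canvas[mask] = level
    return canvas


def make_latent_scene(spec: SynthSpec) -> GrayImage:
    """Procedural full-range latent scene with edges at multiple scales.

    The ``mixed`` scene overlays hard-edged shapes on a continuous texture,
    giving both the sharp boundaries that defocus destroys and a dense
    gray-level population (the raster is affinely stretched to span the
    full [0, 255] range).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    if spec.scene == "texture":
        field = _texture_field(rng, h, w)
    elif spec.scene == "shapes":
        field = _shape_field(rng, h, w)
    else:
        field = 0.55 * _shape_field(rng, h, w) + 0.45 * _texture_field(rng, h, w)
    lo, hi = field.min(), field.max()
    field = (field - lo) / (hi - lo) * 255.0
    return GrayImage(np.rint(field).astype(np.int64), 8)


# ---------------------------------------------------------------------------
# Multi-focus pairs
# ---------------------------------------------------------------------------

def _split_mask(spec: SynthSpec) -> np.ndarray:
    """Boolean out-of-focus region R for source A (True = blurred in A)."""
    h, w = spec.height, spec.width
    if spec.split == "left-right":
        mask = np.zeros((h, w), dtype=bool)
        mask[:, : w // 2] = True
        return mask
    if spec.split == "quadrant":
        mask = np.zeros((h, w), dtype=bool)
        mask[: h // 2, : w // 2] = True
        mask[h // 2 :, w // 2 :] = True
        return mask
    # smooth random field thresholded at its median -> ~half the area
    rng = np.random.default_rng(spec.seed + 1_000_003)
    field = ndimage.gaussian_filter(rng.standard_normal((h, w)), min(h, w) / 8, mode="reflect")
    return field >= np.median(field)


def make_multifocus_pair(spec: SynthSpec) -> tuple[GrayImage, GrayImage, GrayImage]:
    """A complementary-defocus pair plus its all-in-focus ground truth.

    Source A is the latent scene Gaussian-blurred (sigma ``blur_sigma``)
    inside region R, source B blurred in the complement, so each source is
    sharper than the other on complementary regions.
    """
    truth = make_latent_scene(spec)
    if spec.blur_sigma == 0:
        return truth, truth, truth
    blurred = gaussian_blur(truth, spec.blur_sigma)
    mask = _split_mask(spec)
    a = GrayImage(np.where(mask, blurred.pixels, truth.pixels), truth.depth)
    b = GrayImage(np.where(mask, truth.pixels, blurred.pixels), truth.depth)
    return a, b, truth


# ---------------------------------------------------------------------------
# Multi-modal pairs
# ---------------------------------------------------------------------------

def _exclusive_mask(rng: np.random.Generator, h: int, w: int, fraction: float) -> np.ndarray:
    if fraction <= 0:
        return np.zeros((h, w), dtype=bool)
    if fraction >= 1:
        return np.ones((h, w), dtype=bool)
    field = ndimage.gaussian_filter(rng.standard_normal((h, w)), min(h, w) / 10, mode="reflect")
    return field >= np.quantile(field, 1.0 - fraction)


def make_multimodal_pair(spec: SynthSpec) -> tuple[GrayImage, GrayImage]:
    """Two modality renderings of one latent structure (CT/MR-like).

    Each modality applies a monotone gamma remap to the shared latent
    scene — exponent ``modality_gamma`` for A, its reciprocal for B — then
    replaces a fraction of its area (independent smooth random regions per
    modality) with modality-exclusive smoothed noise.  Shared structure
    keeps the joint histogram strongly dependent; exclusive regions dilute
    it, reaching independence at ``exclusive_fraction = 1``.
    """
    latent = make_latent_scene(spec).astype_float() / 255.0
    h, w = spec.height, spec.width
    rng_a = np.random.default_rng(spec.seed + 11)
    rng_b = np.random.default_rng(spec.seed + 23)

    def render(lat: np.ndarray, gamma: float, rng: np.random.Generator) -> GrayImage:
        img = lat ** gamma
        mask = _exclusive_mask(rng, h, w, spec.exclusive_fraction)
        if mask.any():
            noise = ndimage.gaussian_filter(rng.standard_normal((h, w)), 2.0, mode="reflect")
            nlo, nhi = noise.min(), noise.max()
            img = np.where(mask, (noise - nlo) / (nhi - nlo), img)
        return GrayImage(np.rint(np.clip(img, 0, 1) * 255).astype(np.int64), 8)

    a = render(latent, spec.modality_gamma, rng_a)
    b = render(latent, 1.0 / spec.modality_gamma, rng_b)
    return a, b


# ---------------------------------------------------------------------------
# Degradation ladders
# ---------------------------------------------------------------------------

def make_degradation_ladder(
    truth: GrayImage, sigmas: Sequence[float]
) -> list[tuple[str, GrayImage]]:
    """Progressively blurred copies of a reference, labelled by sigma.

    ``sigmas`` must be strictly increasing (the first may be 0, which
    reproduces the reference exactly); the returned list is ordered from
    sharpest to blurriest, i.e. from best to worst fusion quality.
    """
    sig = list(sigmas)
    if any(s2 <= s1 for s1, s2 in zip(sig, sig[1:])):
        raise ValueError("sigmas must be strictly increasing")
    if sig and sig[0] < 0:
        raise ValueError("sigmas must be nonnegative")
    return [(f"sigma={s:g}", gaussian_blur(truth, s)) for s in sig]
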