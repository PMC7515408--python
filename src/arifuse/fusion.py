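"""Classical image-fusion algorithms used as metric test stimuli.

Six standard methods turn a co-registered source pair (A, B) into a
candidate fused image: pixel averaging, PCA weighting, Laplacian-pyramid
(LP) and contrast-pyramid (CP) multiresolution fusion, blockwise DCT
fusion, and guided-filter (GF) two-scale fusion.  They exist here to
exercise the quality metrics — the point is a spread of fusion quality,
not bit-compatibility with any particular third-party implementation.

All methods share conventions: float64 internals, reflection border
handling, output rounded and clipped to the input bit depth.  Pyramid
methods use the 5-tap binomial kernel [1, 4, 6, 4, 1]/16 and 4 levels by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

from .image import GrayImage

__all__ = [
    "FusionSet",
    "fuse_average",
    "fuse_pca",
    "fuse_laplacian_pyramid",
    "fuse_contrast_pyramid",
    "fuse_dct",
    "fuse_guided_filter",
    "fuse",
    "FUSION_METHODS",
    "DEFAULT_LEVELS",
]

DEFAULT_LEVELS = 4
_MIN_SIZE = 8  # smallest raster the blockwise DCT path supports

_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass(frozen=True)
class FusionSet:
    """A source pair plus labelled fused candidates; the unit of ranking."""

    a: GrayImage
    b: GrayImage
    fused: tuple[tuple[str, GrayImage], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fused", tuple(self.fused))
        labels = [lab for lab, _ in self.fused]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in fused candidates")
        for lab, img in self.fused:
            if img.shape != self.a.shape:
                raise ValueError(f"candidate {lab!r} shape {img.shape} != {self.a.shape}")
        if self.a.shape != self.b.shape:
            raise ValueError(f"shape mismatch: {self.a.shape} vs {self.b.shape}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.fused)

    def with_candidate(self, label: str, img: GrayImage) -> "FusionSet":
        return FusionSet(self.a, self.b, self.fused + ((label, img),))


def _prep(a: GrayImage, b: GrayImage) -> tuple[np.ndarray, np.ndarray]:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.height, a.width) < _MIN_SIZE:
        raise ValueError(f"images must be at least {_MIN_SIZE}x{_MIN_SIZE} to fuse")
    return a.astype_float(), b.astype_float()


def _finish(x: np.ndarray, depth: int) -> GrayImage:
    x = np.clip(np.rint(x), 0, (1 << depth) - 1)
    return GrayImage(x.astype(np.int64), depth)


# ---------------------------------------------------------------------------
# Pixel-domain methods
# ---------------------------------------------------------------------------

def fuse_average(a: GrayImage, b: GrayImage) -> GrayImage:
    """Pixel-by-pixel average of the two sources."""
    fa, fb = _prep(a, b)
    return _finish((fa + fb) / 2.0, a.depth)


def fuse_pca(a: GrayImage, b: GrayImage) -> GrayImage:
    """Weighted sum with weights from the principal eigenvector of the
    2x2 covariance of the flattened sources, normalised to sum to 1.

    If the principal eigenvector has mixed signs (strong anti-correlation)
    the weights fall back to variance-proportional, keeping them
    nonnegative.
    """
    fa, fb = _prep(a, b)
    cov = np.cov(np.stack([fa.ravel(), fb.ravel()]))
    if np.allclose(cov, 0.0):
        raise ValueError("degenerate covariance: both images are constant")
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    if v[0] * v[1] < 0:
        v = np.array([cov[0, 0], cov[1, 1]])  # anti-correlated: variance weights
    v = np.abs(v)
    w = v / v.sum()
    return _finish(w[0] * fa + w[1] * fb, a.depth)


# ---------------------------------------------------------------------------
# Pyramid methods
# ---------------------------------------------------------------------------

def _blur(x: np.ndarray, scale: float = 1.0) -> np.ndarray:
    k = _KERNEL * scale
    x = ndimage.correlate1d(x, k, axis=0, mode="reflect")
    return ndimage.correlate1d(x, k, axis=1, mode="reflect")


def _reduce(x: np.ndarray) -> np.ndarray:
    return _blur(x)[::2, ::2]


def _expand(x: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    up = np.zeros(shape)
    up[::2, ::2] = x
    # kernel doubled per axis to conserve mean through the zero insertion
    return _blur(up, scale=2.0)


def _gaussian_pyramid(x: np.ndarray, levels: int) -> list[np.ndarray]:
    gp = [x]
    for _ in range(levels):
        if min(gp[-1].shape) < 4:
            raise ValueError(f"image too small for {levels} pyramid levels")
        gp.append(_reduce(gp[-1]))
    return gp


def fuse_laplacian_pyramid(a: GrayImage, b: GrayImage, levels: int = DEFAULT_LEVELS) -> GrayImage:
    """Laplacian-pyramid fusion: bandpass detail coefficients selected by
    max absolute value, the last-stage base averaged, then reconstructed."""
    if levels < 1:
        raise ValueError("levels must be >= 1")
    fa, fb = _prep(a, b)
    gpa = _gaussian_pyramid(fa, levels)
    gpb = _gaussian_pyramid(fb, levels)
    fused = (gpa[levels] + gpb[levels]) / 2.0
    for lvl in reversed(range(levels)):
        la = gpa[lvl] - _expand(gpa[lvl + 1], gpa[lvl].shape)
        lb = gpb[lvl] - _expand(gpb[lvl + 1], gpb[lvl].shape)
        # exact-magnitude ties average, keeping the rule symmetric in (a, b)
        detail = np.where(np.abs(la) > np.abs(lb), la,
                          np.where(np.abs(lb) > np.abs(la), lb, (la + lb) / 2.0))
        fused = _expand(fused, gpa[lvl].shape) + detail
    return _finish(fused, a.depth)


def fuse_contrast_pyramid(
    a: GrayImage, b: GrayImage, levels: int = DEFAULT_LEVELS, offset: float = 1.0
) -> GrayImage:
    """Contrast-pyramid fusion: per level the ratio-of-lowpass coefficient
    deviating most from 1 (the larger local contrast) is selected; the base
    is averaged and reconstruction is multiplicative.

    ``offset`` is added to all lowpass values before forming ratios so a
    zero background cannot divide out, and removed on reconstruction.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    fa, fb = _prep(a, b)
    gpa = _gaussian_pyramid(fa + offset, levels)
    gpb = _gaussian_pyramid(fb + offset, levels)
    fused = (gpa[levels] + gpb[levels]) / 2.0
    for lvl in reversed(range(levels)):
        ea = _expand(gpa[lvl + 1], gpa[lvl].shape)
        eb = _expand(gpb[lvl + 1], gpb[lvl].shape)
        ra = gpa[lvl] / ea
        rb = gpb[lvl] / eb
        da, db = np.abs(ra - 1.0), np.abs(rb - 1.0)
        ratio = np.where(da > db, ra, np.where(db > da, rb, (ra + rb) / 2.0))
        fused = ratio * _expand(fused, gpa[lvl].shape)
    return _finish(fused - offset, a.depth)


# ---------------------------------------------------------------------------
# Transform-domain method
# ---------------------------------------------------------------------------

def fuse_dct(a: GrayImage, b: GrayImage, block: int = 8) -> GrayImage:
    """Blockwise DCT fusion.

    Both sources are tiled into ``block x block`` blocks (edge-replicated
    to a multiple of the block size), transformed with the orthonormal 2D
    DCT, and fused per block: the AC coefficients of the block with the
    higher AC-coefficient variance win outright, DC coefficients are
    averaged.  The inverse transform is then cropped and clipped.
    """
    if block < 2:
        raise ValueError("block must be >= 2")
    fa, fb = _prep(a, b)
    h, w = fa.shape
    ph = (-h) % block
    pw = (-w) % block
    fa = np.pad(fa, ((0, ph), (0, pw)), mode="edge")
    fb = np.pad(fb, ((0, ph), (0, pw)), mode="edge")
    nh, nw = fa.shape[0] // block, fa.shape[1] // block

    def to_blocks(x: np.ndarray) -> np.ndarray:
        return x.reshape(nh, block, nw, block).transpose(0, 2, 1, 3)

    ca = sfft.dctn(to_blocks(fa), axes=(2, 3), norm="ortho")
    cb = sfft.dctn(to_blocks(fb), axes=(2, 3), norm="ortho")

    def ac_var(c: np.ndarray) -> np.ndarray:
        ac = c.reshape(nh, nw, -1)[:, :, 1:]
        return ac.var(axis=2)

    va, vb = ac_var(ca), ac_var(cb)
    fused = np.where((va > vb)[:, :, None, None], ca,
                     np.where((vb > va)[:, :, None, None], cb, (ca + cb) / 2.0))
    fused[:, :, 0, 0] = (ca[:, :, 0, 0] + cb[:, :, 0, 0]) / 2.0
    out = sfft.idctn(fused, axes=(2, 3), norm="ortho")
    out = out.transpose(0, 2, 1, 3).reshape(nh * block, nw * block)
    return _finish(out[:h, :w], a.depth)


# ---------------------------------------------------------------------------
# Guided-filter two-scale method
# ---------------------------------------------------------------------------

def _boxf(x: np.ndarray, radius: int) -> np.ndarray:
    return ndimage.uniform_filter(x, size=2 * radius + 1, mode="reflect")


def _guided_filter(guide: np.ndarray, src: np.ndarray, radius: int, eps: float) -> np.ndarray:
    """Edge-preserving smoothing of ``src`` steered by ``guide`` (box-filter form)."""
    mg = _boxf(guide, radius)
    ms = _boxf(src, radius)
    var_g = _boxf(guide * guide, radius) - mg * mg
    cov_gs = _boxf(guide * src, radius) - mg * ms
    a = cov_gs / (var_g + eps)
    b = ms - a * mg
    return _boxf(a, radius) * guide + _boxf(b, radius)


def fuse_guided_filter(
    a: GrayImage,
    b: GrayImage,
    base_radius: int = 31,
    base_eps_scale: float = 1e-3,
    detail_radius: int = 7,
    detail_eps_scale: float = 1e-6,
    saliency_sigma: float = 5.0,
) -> GrayImage:
    """Guided-filter two-scale fusion.

    Each source splits into a mean-filtered base layer (large-scale
    intensity) and the residual detail layer.  A per-pixel saliency map
    (Gaussian-smoothed absolute Laplacian) decides which source wins each
    pixel; the hard winner maps are softened by guided filtering with the
    source as guide — coarse settings for the base layer, fine for the
    detail layer — normalised to sum to 1, and used to blend each layer.

    Epsilon parameters are scales of the squared gray range so behaviour
    is depth-independent.
    """
    fa, fb = _prep(a, b)
    rng2 = float(a.max_level) ** 2
    base_a = _boxf(fa, base_radius)
    base_b = _boxf(fb, base_radius)
    det_a = fa - base_a
    det_b = fb - base_b
    sal_a = ndimage.gaussian_filter(np.abs(ndimage.laplace(fa, mode="reflect")), saliency_sigma)
    sal_b = ndimage.gaussian_filter(np.abs(ndimage.laplace(fb, mode="reflect")), saliency_sigma)
    pa = (sal_a >= sal_b).astype(np.float64)
    pb = 1.0 - pa

    def refine(p: np.ndarray, guide: np.ndarray, radius: int, eps_scale: float) -> np.ndarray:
        return np.clip(_guided_filter(guide, p, radius, eps_scale * rng2), 0.0, 1.0)

    wba = refine(pa, fa, base_radius, base_eps_scale)
    wbb = refine(pb, fb, base_radius, base_eps_scale)
    wda = refine(pa, fa, detail_radius, detail_eps_scale)
    wdb = refine(pb, fb, detail_radius, detail_eps_scale)
    sb = wba + wbb
    sd = wda + wdb
    wba = np.where(sb > 0, wba / np.where(sb > 0, sb, 1.0), 0.5)
    wbb = 1.0 - wba
    wda = np.where(sd > 0, wda / np.where(sd > 0, sd, 1.0), 0.5)
    wdb = 1.0 - wda
    fused = wba * base_a + wbb * base_b + wda * det_a + wdb * det_b
    return _finish(fused, a.depth)


FUSION_METHODS = {
    "average": fuse_average,
    "pca": fuse_pca,
    "lp": fuse_laplacian_pyramid,
    "cp": fuse_contrast_pyramid,
    "dct": fuse_dct,
    "gf": fuse_guided_filter,
}


def fuse(method: str, a: GrayImage, b: GrayImage, **kwargs) -> GrayImage:
    """Dispatch to one of :data:`FUSION_METHODS` by name."""
    try:
        fn = FUSION_METHODS[method.lower()]
    except KeyError:
        raise ValueError(f"unknown fusion method {method!r}; choose from {sorted(FUSION_METHODS)}")
    return fn(a, b, **kwargs)
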