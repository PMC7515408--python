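"""Gray-level probability models: marginal and joint histograms.

All the information-theoretic metrics in this package are plug-in
estimators: the marginal distribution p(x) of an image and the joint
distribution p(x, y) of a co-registered pair are estimated by plain
normalised histogram counting over a uniform binning of the gray range,
with no smoothing or partial-volume interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import GrayImage

__all__ = ["ProbDist", "JointDist", "marginal_hist", "joint_hist", "DEFAULT_BINS"]

#: Full 8-bit gray range; matches the bit depth of typical fusion test images.
DEFAULT_BINS = 256

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class ProbDist:
    """A discrete probability distribution over ``n`` gray-level bins."""

    p: np.ndarray
    n: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=np.float64)
        if p.ndim != 1 or p.size != self.n:
            raise ValueError("p must be a 1D vector of length n")
        if np.any(p < 0):
            raise ValueError("negative probability")
        if abs(p.sum() - 1.0) > _NORM_TOL:
            raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class JointDist:
    """A joint distribution over an ``n x n`` grid of gray-level bin pairs."""

    pj: np.ndarray
    n: int

    def __post_init__(self) -> None:
        pj = np.asarray(self.pj, dtype=np.float64)
        if pj.shape != (self.n, self.n):
            raise ValueError("pj must be an n x n matrix")
        if np.any(pj < 0):
            raise ValueError("negative probability")
        if abs(pj.sum() - 1.0) > _NORM_TOL:
            raise ValueError(f"probabilities sum to {pj.sum()!r}, not 1")
        object.__setattr__(self, "pj", pj)

    def marginal_first(self) -> ProbDist:
        """Row sums: the distribution of the first image."""
        return ProbDist(self.pj.sum(axis=1), self.n)

    def marginal_second(self) -> ProbDist:
        """Column sums: the distribution of the second image."""
        return ProbDist(self.pj.sum(axis=0), self.n)


def _bin_indices(img: GrayImage, bins: int) -> np.ndarray:
    """Map intensities to bin indices under uniform binning of [0, 2^depth - 1]."""
    levels = 1 << img.depth
    idx = (img.pixels.astype(np.int64) * bins) // levels
    return np.clip(idx, 0, bins - 1)


def marginal_hist(img: GrayImage, bins: int = DEFAULT_BINS) -> ProbDist:
    """Normalised gray-level histogram of one image.

    Bin ``b`` counts pixels whose intensity falls in the ``b``-th of
    ``bins`` equal-width intervals of ``[0, 2**depth - 1]``; counts are
    divided by the total pixel count.
    """
    if bins < 2:
        raise ValueError("invalid bins: need at least 2")
    idx = _bin_indices(img, bins)
    counts = np.bincount(idx.ravel(), minlength=bins).astype(np.float64)
    return ProbDist(counts / counts.sum(), bins)


def joint_hist(img1: GrayImage, img2: GrayImage, bins: int = DEFAULT_BINS) -> JointDist:
    """Normalised joint gray-level histogram of a co-registered pair.

    Cell ``(i, j)`` holds the fraction of pixel positions whose
    ``(img1, img2)`` intensities fall in bins ``(i, j)``.  Marginalising
    reproduces :func:`marginal_hist` of each image exactly.
    """
    if bins < 2:
        raise ValueError("invalid bins: need at least 2")
    if img1.shape != img2.shape:
        raise ValueError(f"shape mismatch: {img1.shape} vs {img2.shape}")
    i = _bin_indices(img1, bins).ravel()
    j = _bin_indices(img2, bins).ravel()
    counts = np.bincount(i * bins + j, minlength=bins * bins).astype(np.float64)
    pj = counts.reshape(bins, bins)
    return JointDist(pj / pj.sum(), bins)
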