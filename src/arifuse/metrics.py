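r"""No-reference fusion-quality metrics.

Given two co-registered source images :math:`A, B` and a candidate fused
image :math:`F`, each metric scores how much of the sources' information
:math:`F` retains — with no ideal reference image involved.  Four are
information-theoretic sums of per-source similarities,

.. math:: M(A, B; F) = I(F, A) + I(F, B),

with :math:`I` being Shannon MI (bits), normalised MI, Tsallis MI, or the
Arimoto mutual information :math:`I_\alpha` that defines the headline
metric

.. math:: M_\alpha(A, B; F) = I_\alpha(F, A) + I_\alpha(F, B),

with default order :math:`\alpha = 1.5`, the value at which the metric
separates fusion algorithms most consistently with visual inspection.
The fifth is the Petrovic/Xydeas edge-preservation score
:math:`Q^{AB/F} \in [0, 1]`, which measures how faithfully Sobel gradient
strength and orientation transfer from each source into the fusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import entropy
from .entropy import AlphaLike, AlphaParam
from .image import GrayImage
from .probmodel import DEFAULT_BINS, joint_hist, marginal_hist

__all__ = [
    "MetricResult",
    "PetrovicParams",
    "metric_mi",
    "metric_nmi",
    "metric_tsallis",
    "metric_arimoto",
    "metric_petrovic",
    "alpha_sweep",
    "compute_metric",
    "DEFAULT_ALPHA",
    "DEFAULT_TSALLIS_Q",
    "DEFAULT_ALPHA_GRID",
    "METRIC_NAMES",
]

#: Default Arimoto order for the headline metric.
DEFAULT_ALPHA = 1.5

#: Default Tsallis order; the convention of the comparison literature.
DEFAULT_TSALLIS_Q = 1.85

#: The standard 10-point grid for order-sensitivity sweeps.
DEFAULT_ALPHA_GRID = (0.2, 0.5, 0.9, 1.1, 1.2, 1.5, 1.6, 1.75, 1.9, 2.0)

METRIC_NAMES = ("mi", "nmi", "tsallis", "arimoto", "petrovic")


@dataclass(frozen=True)
class MetricResult:
    """One metric evaluation of a fused image against its two sources.

    For the additive metrics ``value == component_fa + component_fb``
    exactly; for the Petrovic score the components are the per-source
    weighted-preservation sums and the value is their normalised total.
    ``units`` records the scale ("bits", "nats", or "dimensionless") so
    Shannon-family and generalized-entropy values are never silently mixed.
    """

    metric_name: str
    value: float
    component_fa: float
    component_fb: float
    alpha: Optional[float] = None
    units: str = "nats"


def _check_shapes(a: GrayImage, b: GrayImage, f: GrayImage) -> None:
    if not (a.shape == b.shape == f.shape):
        raise ValueError(
            f"shape mismatch: A{a.shape}, B{b.shape}, F{f.shape} must be identical"
        )


def metric_mi(a: GrayImage, b: GrayImage, f: GrayImage, bins: int = DEFAULT_BINS) -> MetricResult:
    """Shannon-MI fusion metric ``I(F,A) + I(F,B)`` in bits."""
    _check_shapes(a, b, f)
    ifa = entropy.shannon_mi(joint_hist(f, a, bins))
    ifb = entropy.shannon_mi(joint_hist(f, b, bins))
    return MetricResult("mi", ifa + ifb, ifa, ifb, units="bits")


def metric_nmi(a: GrayImage, b: GrayImage, f: GrayImage, bins: int = DEFAULT_BINS) -> MetricResult:
    """Entropy-normalised MI metric ``2[I(F,A)/(H(F)+H(A)) + I(F,B)/(H(F)+H(B))]``.

    Each bracketed ratio lies in [0, 1] so the metric lies in [0, 2];
    a perfect self-fusion (F = A = B) scores 2.
    """
    _check_shapes(a, b, f)
    ha = entropy.shannon_entropy(marginal_hist(a, bins))
    hb = entropy.shannon_entropy(marginal_hist(b, bins))
    hf = entropy.shannon_entropy(marginal_hist(f, bins))
    if min(ha, hb, hf) <= 0.0:
        raise ValueError("degenerate entropy: constant image has zero entropy")
    ifa = 2.0 * entropy.shannon_mi(joint_hist(f, a, bins)) / (hf + ha)
    ifb = 2.0 * entropy.shannon_mi(joint_hist(f, b, bins)) / (hf + hb)
    return MetricResult("nmi", ifa + ifb, ifa, ifb, units="dimensionless")


def metric_tsallis(
    a: GrayImage,
    b: GrayImage,
    f: GrayImage,
    q: AlphaLike = DEFAULT_TSALLIS_Q,
    bins: int = DEFAULT_BINS,
) -> MetricResult:
    """Tsallis-MI fusion metric of order q (natural units)."""
    _check_shapes(a, b, f)
    qv = q.alpha if isinstance(q, AlphaParam) else float(q)
    ifa = entropy.tsallis_mi(joint_hist(f, a, bins), q)
    ifb = entropy.tsallis_mi(joint_hist(f, b, bins), q)
    return MetricResult("tsallis", ifa + ifb, ifa, ifb, alpha=qv)


def metric_arimoto(
    a: GrayImage,
    b: GrayImage,
    f: GrayImage,
    alpha: AlphaLike = DEFAULT_ALPHA,
    bins: int = DEFAULT_BINS,
) -> MetricResult:
    """The Arimoto fusion metric ``M_alpha = I_alpha(F,A) + I_alpha(F,B)``.

    Symmetric in A and B, nonnegative, and equal to the Shannon-MI metric
    in nats in the alpha -> 1 limit.
    """
    _check_shapes(a, b, f)
    av = alpha.alpha if isinstance(alpha, AlphaParam) else float(alpha)
    ifa = entropy.arimoto_mi(joint_hist(f, a, bins), alpha)
    ifb = entropy.arimoto_mi(joint_hist(f, b, bins), alpha)
    return MetricResult("arimoto", ifa + ifb, ifa, ifb, alpha=av)


# ---------------------------------------------------------------------------
# Petrovic / Xydeas edge-preservation metric
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PetrovicParams:
    """Sigmoid gains/offsets and the weighting exponent for Q^{AB/F}.

    The published constants of the edge-preservation literature.  The two
    sigmoids are rescaled so that perfect preservation (relative gradient
    strength and orientation agreement both 1) maps to exactly 1.
    """

    gamma_g: float = 0.9994
    kappa_g: float = -15.0
    sigma_g: float = 0.5
    gamma_a: float = 0.9879
    kappa_a: float = -22.0
    sigma_a: float = 0.8
    weight_exponent: float = 1.0


def _sobel_polar(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sx = ndimage.sobel(x, axis=1, mode="reflect")
    sy = ndimage.sobel(x, axis=0, mode="reflect")
    g = np.hypot(sx, sy)
    # orientation in (-pi/2, pi/2]; arctan of the slope, undefined-at-0 -> 0
    ang = np.arctan2(sy, np.where((sx == 0) & (sy == 0), 1.0, sx))
    ang = np.where(ang > np.pi / 2, ang - np.pi, ang)
    ang = np.where(ang <= -np.pi / 2, ang + np.pi, ang)
    return g, ang


def _edge_preservation(
    gs: np.ndarray, angs: np.ndarray, gf: np.ndarray, angf: np.ndarray, pp: PetrovicParams
) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(gs > gf, gf / gs, gs / gf)
    ratio = np.where((gs == 0) & (gf == 0), 1.0, ratio)  # no edge to lose
    ratio = np.nan_to_num(ratio, nan=0.0)
    aa = np.clip(1.0 - np.abs(angs - angf) / (np.pi / 2), 0.0, 1.0)

    def sig(x, gamma, kappa, sigma):
        return gamma / (1.0 + np.exp(kappa * (x - sigma)))

    qg = sig(ratio, pp.gamma_g, pp.kappa_g, pp.sigma_g) / sig(
        1.0, pp.gamma_g, pp.kappa_g, pp.sigma_g
    )
    qa = sig(aa, pp.gamma_a, pp.kappa_a, pp.sigma_a) / sig(
        1.0, pp.gamma_a, pp.kappa_a, pp.sigma_a
    )
    return qg * qa


def metric_petrovic(
    a: GrayImage,
    b: GrayImage,
    f: GrayImage,
    params: PetrovicParams = PetrovicParams(),
) -> MetricResult:
    """Edge-preservation score Q^{AB/F} in [0, 1].

    Per pixel, the relative Sobel gradient strength and the orientation
    agreement between each source and the fusion pass through sigmoids and
    multiply into a preservation score; scores are averaged over the image
    weighted by source gradient magnitude.  A pair of constant sources has
    no edges to preserve and scores 0 by convention.
    """
    _check_shapes(a, b, f)
    if min(a.height, a.width) < 3:
        raise ValueError("images must be at least 3x3 for Sobel gradients")
    ga, anga = _sobel_polar(a.astype_float())
    gb, angb = _sobel_polar(b.astype_float())
    gf, angf = _sobel_polar(f.astype_float())
    qaf = _edge_preservation(ga, anga, gf, angf, params)
    qbf = _edge_preservation(gb, angb, gf, angf, params)
    wa = ga ** params.weight_exponent
    wb = gb ** params.weight_exponent
    denom = float(np.sum(wa + wb))
    ca = float(np.sum(qaf * wa))
    cb = float(np.sum(qbf * wb))
    if denom == 0.0:
        return MetricResult("petrovic", 0.0, 0.0, 0.0, units="dimensionless")
    return MetricResult("petrovic", (ca + cb) / denom, ca / denom, cb / denom,
                        units="dimensionless")


# ---------------------------------------------------------------------------
# Dispatch and sweeps
# ---------------------------------------------------------------------------

def compute_metric(
    name: str,
    a: GrayImage,
    b: GrayImage,
    f: GrayImage,
    alpha: Optional[float] = None,
    q: Optional[float] = None,
    bins: int = DEFAULT_BINS,
) -> MetricResult:
    """Evaluate one metric by name (one of :data:`METRIC_NAMES`)."""
    if name == "mi":
        return metric_mi(a, b, f, bins)
    if name == "nmi":
        return metric_nmi(a, b, f, bins)
    if name == "tsallis":
        return metric_tsallis(a, b, f, q if q is not None else DEFAULT_TSALLIS_Q, bins)
    if name == "arimoto":
        return metric_arimoto(a, b, f, alpha if alpha is not None else DEFAULT_ALPHA, bins)
    if name == "petrovic":
        return metric_petrovic(a, b, f)
    raise ValueError(f"unknown metric {name!r}; choose from {METRIC_NAMES}")


def alpha_sweep(
    a: GrayImage,
    b: GrayImage,
    fused: Iterable[tuple[str, GrayImage]],
    alphas: Sequence[float] = DEFAULT_ALPHA_GRID,
    bins: int = DEFAULT_BINS,
) -> pd.DataFrame:
    """Evaluate M_alpha for every (order, candidate) combination.

    Returns a tidy DataFrame with columns ``alpha``, ``label``, ``value``,
    one row per pair, candidates in input order within each order.
    """
    fused = list(fused)
    rows = []
    for al in alphas:
        for label, img in fused:
            res = metric_arimoto(a, b, img, alpha=al, bins=bins)
            rows.append({"alpha": float(al), "label": label, "value": res.value})
    return pd.DataFrame(rows, columns=["alpha", "label", "value"])
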