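r"""Entropy, divergence and mutual-information functionals.

Shannon-family quantities (entropy, Kullback--Leibler divergence, mutual
information) are reported in bits by default.  The generalized-entropy
family is built on the Arimoto entropy of order :math:`\alpha > 0`,

.. math::

    A_\alpha(p) = \frac{\alpha}{\alpha - 1}
        \Bigl[1 - \bigl(\textstyle\sum_i p_i^\alpha\bigr)^{1/\alpha}\Bigr],

which recovers the Shannon entropy in nats as :math:`\alpha \to 1`
(L'Hopital).  It is nonnegative, concave, permutation-symmetric,
maximised by the uniform distribution, and pseudo-additive: for
independent variables

.. math::

    A_\alpha(X, Y) = A_\alpha(X) + A_\alpha(Y)
        - \frac{\alpha - 1}{\alpha} A_\alpha(X) A_\alpha(Y).

The Arimoto divergence between distributions :math:`p` and :math:`q` is

.. math::

    D_\alpha(p \,\|\, q) = \frac{\alpha}{1 - \alpha}
        \Bigl[1 - \bigl(\textstyle\sum_i p_i^\alpha q_i^{1-\alpha}\bigr)^{1/\alpha}\Bigr],

and the Arimoto mutual information of a joint distribution is the
divergence between the joint and the product of its marginals.  Note the
``1 - alpha`` exponent on :math:`q`: some statements of this divergence
carry :math:`q^{\alpha-1}` instead, but that form does not vanish at
:math:`p = q`, can go negative for :math:`\alpha > 1`, and does not reduce
to the KL divergence as :math:`\alpha \to 1`; the geometric-mean exponent
pair :math:`(\alpha, 1-\alpha)` restores all three properties.  The
uncorrected form stays available behind ``as_printed=True`` for audits.

Arimoto and Tsallis quantities are log-free and carry natural units by
construction; they are never mixed with bit-scaled Shannon values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np

from .probmodel import JointDist, ProbDist

__all__ = [
    "AlphaParam",
    "shannon_entropy",
    "kl_divergence",
    "shannon_mi",
    "arimoto_entropy",
    "arimoto_joint_entropy_independent",
    "arimoto_divergence",
    "arimoto_mi",
    "arimoto_mi_pseudoadditive",
    "tsallis_mi",
]

AlphaLike = Union[float, "AlphaParam"]


@dataclass(frozen=True)
class AlphaParam:
    """Order parameter for the Arimoto / Tsallis families.

    ``alpha`` must be positive.  Orders within ``shannon_tol`` of 1 route
    to the Shannon-limit code path (natural units) instead of evaluating
    the generalized formula at a removable singularity.
    """

    alpha: float
    shannon_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha}")

    @property
    def is_shannon_limit(self) -> bool:
        return abs(self.alpha - 1.0) < self.shannon_tol


def _as_alpha(a: AlphaLike) -> AlphaParam:
    return a if isinstance(a, AlphaParam) else AlphaParam(float(a))


def _as_prob(p) -> np.ndarray:
    if isinstance(p, ProbDist):
        return p.p
    return np.asarray(p, dtype=np.float64)


def _as_joint(j) -> np.ndarray:
    if isinstance(j, JointDist):
        return j.pj
    return np.asarray(j, dtype=np.float64)


# ---------------------------------------------------------------------------
# Shannon family
# ---------------------------------------------------------------------------

def shannon_entropy(p, log_base: float = 2.0) -> float:
    """Shannon entropy ``-sum p_i log p_i`` with the 0 log 0 := 0 convention."""
    pv = _as_prob(p)
    nz = pv[pv > 0]
    return float(-np.sum(nz * np.log(nz)) / math.log(log_base))

def kl_divergence(p, q, log_base: float = 2.0) -> float:
    """Kullback--Leibler divergence ``sum p_i log(p_i/q_i)``.

    Where ``p`` has mass outside the support of ``q`` the divergence is
    infinite; ``+inf`` is returned with a warning rather than raising.
    """
    pv, qv = _as_prob(p), _as_prob(q)
    mask = pv > 0
    if np.any(qv[mask] == 0):
        warnings.warn("support violation: p has mass where q is zero", RuntimeWarning)
        return math.inf
    return float(np.sum(pv[mask] * np.log(pv[mask] / qv[mask])) / math.log(log_base))

def shannon_mi(j, log_base: float = 2.0) -> float:
    """Mutual information of a joint distribution: KL(joint || product of marginals)."""
    pj = _as_joint(j)
    px = pj.sum(axis=1)
    py = pj.sum(axis=0)
    outer = np.outer(px, py)
    mask = pj > 0
    val = np.sum(pj[mask] * np.log(pj[mask] / outer[mask]))
    # clip tiny negative round-off; MI is nonnegative
    return float(max(val, 0.0) / math.log(log_base))


# ---------------------------------------------------------------------------
# Arimoto family
# ---------------------------------------------------------------------------

def arimoto_entropy(p, a: AlphaLike) -> float:
    """Arimoto entropy of order alpha; Shannon entropy in nats at the limit."""
    ap = _as_alpha(a)
    pv = _as_prob(p)
    if ap.is_shannon_limit:
        return shannon_entropy(pv, log_base=math.e)
    al = ap.alpha
    s = float(np.sum(pv[pv > 0] ** al))
    return al / (al - 1.0) * (1.0 - s ** (1.0 / al)) + 0.0

def arimoto_joint_entropy_independent(ax: float, ay: float, a: AlphaLike) -> float:
    """Pseudo-additive combination of the entropies of two independent variables."""
    al = _as_alpha(a).alpha
    return ax + ay - (al - 1.0) / al * ax * ay

def _power_sum(pv: np.ndarray, qv: np.ndarray, ea: float, eb: float) -> float:
    """``sum p^ea q^eb`` over the support of p, with support checking on q."""
    mask = pv > 0
    if np.any(qv[mask] == 0):
        warnings.warn("support violation: p has mass where q is zero", RuntimeWarning)
        return math.inf
    return float(np.sum(pv[mask] ** ea * qv[mask] ** eb))

def arimoto_divergence(p, q, a: AlphaLike, as_printed: bool = False) -> float:
    """Arimoto divergence of order alpha between two distributions.

    With the default (corrected) exponent pair the divergence is zero iff
    ``p == q`` on its support, is nonnegative, and tends to the KL
    divergence in nats as alpha -> 1.  ``as_printed=True`` evaluates the
    ``q**(alpha-1)`` variant found in some write-ups, which lacks those
    guarantees and exists purely for auditability.
    """
    ap = _as_alpha(a)
    pv, qv = _as_prob(p), _as_prob(q)
    if ap.is_shannon_limit and not as_printed:
        return kl_divergence(pv, qv, log_base=math.e)
    al = ap.alpha
    eb = (al - 1.0) if as_printed else (1.0 - al)
    s = _power_sum(pv, qv, al, eb)
    if math.isinf(s):
        return math.inf
    return al / (1.0 - al) * (1.0 - s ** (1.0 / al)) + 0.0

def arimoto_mi(j, a: AlphaLike, as_printed: bool = False) -> float:
    """Arimoto mutual information: D_alpha(joint || product of marginals).

    Evaluated over the nonzero support of the joint; zero for an
    outer-product (independent) joint, and equal to the Shannon MI in nats
    at alpha -> 1.
    """
    ap = _as_alpha(a)
    pj = _as_joint(j)
    if ap.is_shannon_limit and not as_printed:
        return shannon_mi(pj, log_base=math.e)
    px = pj.sum(axis=1)
    py = pj.sum(axis=0)
    outer = np.outer(px, py)
    mask = pj > 0
    al = ap.alpha
    eb = (al - 1.0) if as_printed else (1.0 - al)
    s = float(np.sum(pj[mask] ** al * outer[mask] ** eb))
    return al / (1.0 - al) * (1.0 - s ** (1.0 / al)) + 0.0

def arimoto_mi_pseudoadditive(j, a: AlphaLike) -> float:
    """Diagnostic entropy-difference form of Arimoto dependence.

    ``A(X) + A(Y) - ((alpha-1)/alpha) A(X) A(Y) - A(X,Y)``: the deficit of
    the observed joint entropy relative to the pseudo-additive value it
    would take under independence.  Coincides with :func:`arimoto_mi` at
    alpha -> 1 (both become Shannon MI in nats) but differs for general
    alpha; the divergence form drives the fusion metric.
    """
    ap = _as_alpha(a)
    pj = _as_joint(j)
    ax = arimoto_entropy(pj.sum(axis=1), ap)
    ay = arimoto_entropy(pj.sum(axis=0), ap)
    axy = arimoto_entropy(pj.ravel(), ap)
    if ap.is_shannon_limit:
        return ax + ay - axy
    return arimoto_joint_entropy_independent(ax, ay, ap) - axy


# ---------------------------------------------------------------------------
# Tsallis family
# ---------------------------------------------------------------------------

def tsallis_mi(j, q: AlphaLike) -> float:
    """Tsallis mutual information of order q (relative-entropy form).

    ``(1/(1-q)) [1 - sum p(x,y)^q (p(x) p(y))^(1-q)]`` over the nonzero
    support of the joint; zero for independent joints and equal to the
    Shannon MI in nats as q -> 1.
    """
    qp = _as_alpha(q)
    pj = _as_joint(j)
    if qp.is_shannon_limit:
        return shannon_mi(pj, log_base=math.e)
    px = pj.sum(axis=1)
    py = pj.sum(axis=0)
    outer = np.outer(px, py)
    mask = pj > 0
    qq = qp.alpha
    s = float(np.sum(pj[mask] ** qq * outer[mask] ** (1.0 - qq)))
    return (1.0 - s) / (1.0 - qq) + 0.0
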