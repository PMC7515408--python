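"""Ranking of fused candidates and agreement with a reference ordering.

Fusion-metric studies summarise results as a rank ordering of candidate
algorithms per metric (rank 1 = highest metric value = judged best) and
report rank-correlation statistics (Kendall tau, Spearman rho) between
the metric ordering and a reference — typically a subjective visual rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy import stats

__all__ = ["RankedRow", "RankingReport", "rank_candidates"]


@dataclass(frozen=True)
class RankedRow:
    label: str
    value: float
    rank: int
    tied: bool = False


@dataclass(frozen=True)
class RankingReport:
    """Metric-sorted ordering of candidates plus optional rank agreement.

    ``rows`` are sorted by descending metric value; ranks are 1-based with
    1 the largest value.  Exact value ties keep input order and are
    flagged ``tied`` rather than resolved silently.  When a reference
    ordering (best-first label list) is supplied, Kendall tau and
    Spearman rho between the two rankings are attached; tau = 1 iff the
    orders agree exactly.
    """

    metric_name: str
    rows: tuple[RankedRow, ...]
    reference_rank: Optional[tuple[str, ...]] = None
    kendall_tau: Optional[float] = None
    spearman_rho: Optional[float] = None

    @property
    def ordering(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.rows)

    def to_dict(self) -> dict:
        out: dict = {
            "metric": self.metric_name,
            "rows": [
                {"label": r.label, "value": r.value, "rank": r.rank, "tied": r.tied}
                for r in self.rows
            ],
        }
        if self.reference_rank is not None:
            out["reference_rank"] = list(self.reference_rank)
            out["kendall_tau"] = self.kendall_tau
            out["spearman_rho"] = self.spearman_rho
        return out


def rank_candidates(
    metric_name: str,
    scored: Sequence[tuple[str, float]],
    reference_rank: Optional[Sequence[str]] = None,
) -> RankingReport:
    """Rank labelled metric values (descending) and score agreement.

    Parameters
    ----------
    scored
        ``(label, value)`` pairs in input order; labels must be unique.
    reference_rank
        Optional best-first label list to compare against; must be a
        permutation of the scored labels.
    """
    labels = [lab for lab, _ in scored]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    if len(scored) < 1:
        raise ValueError("nothing to rank")

    # stable sort by descending value; ties keep input order
    order = sorted(range(len(scored)), key=lambda i: (-scored[i][1], i))
    values = [v for _, v in scored]
    rows = []
    for rank0, i in enumerate(order):
        lab, val = scored[i]
        tied = values.count(val) > 1
        rows.append(RankedRow(lab, float(val), rank0 + 1, tied))

    tau = rho = None
    ref: Optional[tuple[str, ...]] = None
    if reference_rank is not None:
        ref = tuple(reference_rank)
        if sorted(ref) != sorted(labels):
            raise ValueError("reference_rank must be a permutation of the candidate labels")
        rank_by_label = {r.label: r.rank for r in rows}
        ref_ranks = list(range(1, len(ref) + 1))
        got_ranks = [rank_by_label[lab] for lab in ref]
        if len(ref) >= 2:
            tau = float(stats.kendalltau(ref_ranks, got_ranks).statistic)
            rho = float(stats.spearmanr(ref_ranks, got_ranks).statistic)
        else:
            tau = rho = 1.0
    return RankingReport(metric_name, tuple(rows), ref, tau, rho)
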