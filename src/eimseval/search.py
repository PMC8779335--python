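"""Library search: rank a query spectrum's true compound and tabulate top-N rates.

A query is scored against every library entry, entries are sorted by
descending score, and the rank of the true compound is reported.  Compounds
may have several replicate entries in a library; by default the compound's
rank is that of its best-scoring replicate (an analyst accepts any replicate
hit), with ``strictest=True`` using the worst replicate instead.  Score ties
are broken conservatively: all tied entries share the worst tied position,
so reported top-N rates are lower bounds.  Ranks beyond ``search_depth``
(default 100) are flagged "out of range".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .similarity import DEFAULT_WEIGHTS, SimilarityWeights, _pair_from_vectors, _weighted_vector
from .spectral_io import Spectrum, SpectrumLibrary

__all__ = ["RankResult", "TopNSummary", "rank_query", "topn_summary", "round_half_up"]

DEFAULT_THRESHOLDS = (1, 2, 3, 4, 5, 10, 100)


@dataclass(frozen=True)
class RankResult:
    """Rank of a query's true compound within a searched library."""

    query_id: str
    true_target_id: str
    rank: int
    search_depth: int = 100
    top_hits: tuple[tuple[str, float], ...] = ()

    @property
    def out_of_range(self) -> bool:
        return self.rank > self.search_depth


def rank_query(
    query: Spectrum,
    library: SpectrumLibrary,
    true_id: str,
    metric: str = "wdot",
    w: SimilarityWeights = DEFAULT_WEIGHTS,
    search_depth: int = 100,
    strictest: bool = False,
) -> RankResult:
    """Score ``query`` against every library entry and rank the true compound.

    ``true_id`` matches an entry's id, or its name when replicates of one
    compound carry distinct ids.  Raises ``ValueError`` if no entry matches.
    """
    weighted = metric == "wdot"
    if metric not in ("wdot", "cosine"):
        raise ValueError(f"unknown metric {metric!r}")
    qv = _weighted_vector(query, w, weighted)
    scored: list[tuple[str, float]] = []
    true_scores: list[float] = []
    for entry in library:
        score = _pair_from_vectors(qv, _weighted_vector(entry, w, weighted), w.scale_a)
        scored.append((entry.id, score))
        if entry.id == true_id or entry.name == true_id:
            true_scores.append(score)
    if not true_scores:
        raise ValueError(f"true compound {true_id!r} not present in library")
    target = min(true_scores) if strictest else max(true_scores)
    # conservative tie handling: worst position among entries tied at `target`
    rank = sum(1 for _, s in scored if s >= target)
    scored.sort(key=lambda t: -t[1])
    return RankResult(
        query_id=query.id,
        true_target_id=true_id,
        rank=rank,
        search_depth=search_depth,
        top_hits=tuple(scored[:search_depth]),
    )


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class TopNSummary:
    """Cumulative identification counts/percentages at each rank threshold.

    Percentages are rounded half up.  ``wdot_averages`` holds, for each
    threshold, the mean Wdot of queries identified within it;
    ``out_of_range_avg``/``overall_avg`` cover the failures and all queries.
    """

    thresholds: tuple[int, ...]
    total: int
    cumulative_counts: tuple[int, ...]
    cumulative_pcts: tuple[int, ...]
    out_of_range: int
    out_of_range_pct: int
    wdot_averages: tuple[float | None, ...] = ()
    out_of_range_avg: float | None = None
    overall_avg: float | None = None

    def as_table(self) -> dict[str, list]:
        cols = [f"Top {t}" for t in self.thresholds] + ["Out of Range", "Total"]
        rows: dict[str, list] = {
            "": cols,
            "Cumulative Number of Molecules": list(self.cumulative_counts)
            + [self.out_of_range, self.total],
            "Cumulative Percentage": [f"{p}%" for p in self.cumulative_pcts]
            + [f"{self.out_of_range_pct}%", "100%"],
        }
        if self.wdot_averages:
            rows["Cumulative Wdot Average"] = [
                None if a is None else round(a) for a in self.wdot_averages
            ] + [
                None if self.out_of_range_avg is None else round(self.out_of_range_avg),
                None if self.overall_avg is None else round(self.overall_avg),
            ]
        return rows


def topn_summary(
    ranks: list[RankResult],
    wdot_scores: list[float] | None = None,
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS,
) -> TopNSummary:
    """Aggregate per-query ranks into cumulative top-N identification rates.

    ``wdot_scores`` (optional, aligned with ``ranks``) are the direct
    predicted-vs-experimental Wdot scores used for the per-threshold means.
    """
    if not ranks:
        raise ValueError("topn_summary needs at least one rank")
    if wdot_scores is not None and len(wdot_scores) != len(ranks):
        raise ValueError("wdot_scores must align with ranks")
    total = len(ranks)
    depth = max(thresholds)
    counts = tuple(sum(1 for r in ranks if r.rank <= t) for t in thresholds)
    out_of_range = sum(1 for r in ranks if r.rank > depth)
    pcts = tuple(round_half_up(100.0 * c / total) for c in counts)

    averages: tuple[float | None, ...] = ()
    oor_avg = overall_avg = None
    if wdot_scores is not None:
        def _mean(vals: list[float]) -> float | None:
            return sum(vals) / len(vals) if vals else None

        averages = tuple(
            _mean([s for r, s in zip(ranks, wdot_scores) if r.rank <= t])
            for t in thresholds
        )
        oor_avg = _mean([s for r, s in zip(ranks, wdot_scores) if r.rank > depth])
        overall_avg = _mean(list(wdot_scores))
    return TopNSummary(
        thresholds=tuple(thresholds),
        total=total,
        cumulative_counts=counts,
        cumulative_pcts=pcts,
        out_of_range=out_of_range,
        out_of_range_pct=round_half_up(100.0 * out_of_range / total),
        wdot_averages=averages,
        out_of_range_avg=oor_avg,
        overall_avg=overall_avg,
    )
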