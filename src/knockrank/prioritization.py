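"""PPI path ranking, Borda rank fusion, and the end-to-end pipeline.

Candidates are ranked by the unweighted hop count of the shortest
interaction path to the knockout gene on the score-thresholded PPI graph —
shorter paths mean tighter functional coupling. On a dense interactome
hop counts are small integers, so massive rank ties are expected and are
handled with competition ranking. The literature ranking and the path
ranking are then fused by unweighted Borda count: in each list a gene at
rank r among N earns N - r + 1 points (tied genes earn the full points of
their shared rank), the two criteria weigh equally, and the summed points
give the final ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .relevance import ScorerMode, rank_by_relevance, score_candidates
from .selection import SelectionConfig, snv_filter, tf_filter
from .types import (
    Context,
    ContractViolation,
    Corpus,
    DEGTable,
    InteractionNetwork,
    RankedGeneList,
    RegulatoryNetwork,
    SNVProfile,
    competition_rank,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathDistance:
    gene: str
    hops: float  # positive integer hop count, or math.inf when disconnected


def _graph(ppi: InteractionNetwork) -> nx.Graph:
    g = nx.Graph()
    for (a, b), score in ppi.scores.items():
        g.add_edge(a, b, score=score)
    return g


def shortest_hops(ppi: InteractionNetwork, ko: str, gene: str) -> PathDistance:
    """Unweighted shortest-path length (hops) from ``gene`` to the KO gene.

    Infinite when either endpoint is absent or no path exists. A distance-0
    query (gene == ko) is flagged: the knockout gene is never a candidate.
    """
    if gene == ko:
        logger.warning("distance queried for the knockout gene itself (%s)", ko)
        return PathDistance(gene=gene, hops=0.0)
    g = _graph(ppi)
    if ko not in g or gene not in g:
        return PathDistance(gene=gene, hops=math.inf)
    try:
        return PathDistance(gene=gene, hops=float(nx.shortest_path_length(g, gene, ko)))
    except nx.NetworkXNoPath:
        return PathDistance(gene=gene, hops=math.inf)


def path_distances(ppi: InteractionNetwork, ko: str, candidates: Iterable[str]) -> dict[str, float]:
    """Hop distances for many candidates with a single BFS from the KO gene."""
    g = _graph(ppi)
    lengths: dict[str, int] = {}
    if ko in g:
        lengths = nx.single_source_shortest_path_length(g, ko)
    return {c: float(lengths[c]) if c in lengths else math.inf for c in candidates}


def rank_by_path(candidates: Iterable[str], ppi: InteractionNetwork, ko: str) -> RankedGeneList:
    """Rank candidates by hop distance to the KO gene, ascending.

    Competition ranking: every direct interactor shares rank 1. Candidates
    unreachable on the thresholded graph share the last rank block, after
    all finite distances (kept and ranked last, not dropped).
    """
    cand = set(candidates)
    if ko in cand:
        raise ContractViolation("the knockout gene cannot be a candidate")
    dists = path_distances(ppi, ko, cand)
    n_inf = sum(1 for d in dists.values() if math.isinf(d))
    if n_inf:
        logger.info("%d of %d candidates unreachable in the PPI graph; ranked last", n_inf, len(cand))
    return competition_rank(dists, higher_is_better=False)


def borda_points(ranked: RankedGeneList) -> dict[str, float]:
    """Points awarded by one criterion: N - rank + 1, ties keep full points."""
    n = len(ranked)
    return {e.gene: float(n - e.rank + 1) for e in ranked.entries}


@dataclass(frozen=True)
class BordaTally:
    gene: str
    points: float
    source_ranks: tuple[tuple[str, int], ...]


def borda_combine(lists: Sequence[RankedGeneList], names: Sequence[str] | None = None) -> RankedGeneList:
    """Fuse rankings by unweighted Borda count.

    Every gene must appear in every list (genes rejected upstream are
    excluded from the universe before fusion); a gene missing from one
    criterion is a contract violation naming the gene.
    """
    if not lists:
        return RankedGeneList()
    universe = set(lists[0].genes())
    for i, lst in enumerate(lists[1:], start=2):
        missing = universe.symmetric_difference(lst.genes())
        if missing:
            raise ContractViolation(
                f"gene(s) missing from one ranking (list 1 vs list {i}): {sorted(missing)}"
            )
    totals: dict[str, float] = {g: 0.0 for g in universe}
    for lst in lists:
        for gene, pts in borda_points(lst).items():
            totals[gene] += pts
    return competition_rank(totals, higher_is_better=True)


def borda_tallies(lists: Sequence[RankedGeneList], names: Sequence[str]) -> list[BordaTally]:
    """Per-gene audit of the fusion: total points and the rank under each criterion."""
    combined = borda_combine(lists)
    rank_maps = [lst.rank_map() for lst in lists]
    return [
        BordaTally(
            gene=e.gene,
            points=e.score,
            source_ranks=tuple((name, rm[e.gene]) for name, rm in zip(names, rank_maps)),
        )
        for e in combined.entries
    ]


@dataclass
class PipelineDiagnostics:
    """Stage-by-stage audit of one pipeline run."""

    stage_sizes: dict[str, int] = field(default_factory=dict)
    config: dict[str, object] = field(default_factory=dict)
    empty_stage: str | None = None
    per_gene: dict[str, dict[str, object]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, object]:
        return {
            "stage_sizes": dict(self.stage_sizes),
            "config": dict(self.config),
            "empty_stage": self.empty_stage,
        }


def run_pipeline(
    degs: DEGTable,
    tf_network: RegulatoryNetwork,
    snv: SNVProfile,
    ppi: InteractionNetwork,
    corpus: Corpus,
    context: Context,
    ko: str,
    cfg: SelectionConfig = SelectionConfig(),
    scorer: ScorerMode = "cosine",
    reject_zero: bool = True,
) -> tuple[RankedGeneList, PipelineDiagnostics]:
    """Select candidates, rank by literature relevance and PPI path, fuse.

    Stages: TF-network filter -> SNV filter -> relevance scoring (zero
    rejection) -> PPI path ranking on the surviving set -> Borda fusion.
    An empty set after any stage yields a graceful empty output with the
    stage named in the diagnostics.
    """
    diag = PipelineDiagnostics(
        config={
            "tf_mode": cfg.tf_mode,
            "max_depth": cfg.max_depth,
            "max_snv_rate": cfg.max_snv_rate,
            "scorer": scorer,
            "reject_zero": reject_zero,
            "ko": ko,
            "context": list(context.keywords),
        }
    )
    diag.stage_sizes["input_degs"] = len(degs.deg_genes())

    after_tf = tf_filter(degs, tf_network, ko, cfg)
    diag.stage_sizes["after_tf_filter"] = len(after_tf)
    if not after_tf:
        diag.empty_stage = "tf_filter"
        return RankedGeneList(), diag

    after_snv = snv_filter(after_tf, snv, cfg)
    diag.stage_sizes["after_snv_filter"] = len(after_snv)
    if not after_snv:
        diag.empty_stage = "snv_filter"
        return RankedGeneList(), diag

    scores = score_candidates(corpus, context, ko, after_snv, scorer)
    rel_ranked = rank_by_relevance(scores, reject_zero=reject_zero)
    diag.stage_sizes["after_relevance"] = len(rel_ranked)
    score_map = {s.gene: s for s in scores}
    if not len(rel_ranked):
        diag.empty_stage = "relevance"
        return RankedGeneList(), diag

    survivors = set(rel_ranked.genes())
    ppi_ranked = rank_by_path(survivors, ppi, ko)
    final = borda_combine([rel_ranked, ppi_ranked])
    diag.stage_sizes["final"] = len(final)

    dists = path_distances(ppi, ko, survivors)
    rel_ranks = rel_ranked.rank_map()
    ppi_ranks = ppi_ranked.rank_map()
    for gene in survivors:
        diag.per_gene[gene] = {
            "relevance_score": score_map[gene].combined,
            "relevance_rank": rel_ranks[gene],
            "ppi_distance": dists[gene],
            "ppi_rank": ppi_ranks[gene],
        }
    return final, diag
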