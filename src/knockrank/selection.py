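"""Candidate gene selection from the DEG list.

Two filters run in sequence. The TF-network filter keeps DEGs that sit
downstream of the knocked-out gene in the directed regulatory network (and,
in the strict mode, that also regulate another DEG), discarding expression
changes with no regulatory route back to the knockout. The SNV filter then
discards candidates whose variant rate in the knockout animals is high
enough that the expression difference plausibly reflects genetic background
rather than the knockout itself.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import networkx as nx

from .types import DEGTable, RegulatoryNetwork, SNVProfile

logger = logging.getLogger(__name__)

TFMode = Literal["strict", "reachable", "regulator"]


@dataclass(frozen=True)
class SelectionConfig:
    """Selection-step knobs.

    tf_mode
        ``reachable`` (default) keeps DEGs reachable from the knockout gene
        by directed paths; ``strict`` additionally requires the DEG to have
        an outgoing regulatory edge to another DEG; ``regulator`` keeps DEGs
        that are either reachable from the knockout or regulate another DEG.
    max_depth
        Path-length cap for reachability; ``None`` means unlimited.
    max_snv_rate
        Variants per kilobase above which a candidate is discarded;
        ``None`` disables the SNV filter. Default 3.0/kb.
    """

    tf_mode: TFMode = "reachable"
    max_depth: int | None = None
    max_snv_rate: float | None = 3.0

    def __post_init__(self) -> None:
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1 when finite")
        if self.max_snv_rate is not None and self.max_snv_rate < 0:
            raise ValueError("max_snv_rate must be >= 0")


def _digraph(network: RegulatoryNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_edges_from(network.edges)
    return g


def reachable_from(
    network: RegulatoryNetwork, source: str, max_depth: int | None = None
) -> set[str]:
    """Nodes reachable from ``source`` by directed paths of length 1..max_depth.

    The source itself is excluded unless it lies on a cycle. A source absent
    from the network yields the empty set.
    """
    g = _digraph(network)
    if source not in g:
        return set()
    cutoff = max_depth if max_depth is not None else None
    lengths = nx.single_source_shortest_path_length(g, source, cutoff=cutoff)
    reached = {n for n, d in lengths.items() if d >= 1}
    # source reaches itself only through a cycle: some predecessor of source
    # must lie at distance <= max_depth - 1 (distance 0 covers a self-loop,
    # but self-loops are dropped at load).
    preds = set(g.predecessors(source))
    if any(p in lengths and (cutoff is None or lengths[p] <= cutoff - 1) for p in preds):
        reached.add(source)
    return reached


def tf_filter(
    degs: DEGTable,
    network: RegulatoryNetwork,
    ko: str,
    cfg: SelectionConfig = SelectionConfig(),
) -> set[str]:
    """Select candidate DEGs through the regulatory network.

    The knockout gene itself is never returned. An empty result is allowed
    (logged); it simply means no DEG is wired to the knockout under the
    chosen mode.
    """
    deg_set = degs.deg_genes()
    downstream = reachable_from(network, ko, cfg.max_depth)

    def regulates_other_deg(g: str) -> bool:
        return any(t in deg_set and t != g for t in network.targets_of(g))

    kept: set[str] = set()
    for g in deg_set:
        if g == ko:
            continue
        if cfg.tf_mode == "strict":
            ok = g in downstream and regulates_other_deg(g)
        elif cfg.tf_mode == "reachable":
            ok = g in downstream
        elif cfg.tf_mode == "regulator":
            ok = g in downstream or regulates_other_deg(g)
        else:  # pragma: no cover - guarded by SelectionConfig typing
            raise ValueError(f"unknown tf_mode {cfg.tf_mode!r}")
        if ok:
            kept.add(g)
    if not kept:
        logger.warning("TF filter (%s mode) removed every DEG", cfg.tf_mode)
    return kept


def snv_filter(
    candidates: set[str],
    profile: SNVProfile,
    cfg: SelectionConfig = SelectionConfig(),
) -> set[str]:
    """Discard candidates whose SNV rate exceeds the configured threshold.

    Genes absent from the profile are treated as rate 0 and pass: absence
    of evidence of genetic difference is not treated as contamination.
    """
    if cfg.max_snv_rate is None:
        return set(candidates)
    threshold = cfg.max_snv_rate
    kept = {g for g in candidates if profile.rate(g) <= threshold}
    removed = len(candidates) - len(kept)
    if removed:
        logger.info("SNV filter removed %d candidates above %.3g variants/kb", removed, threshold)
    return kept
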