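"""Deterministic synthetic benchmark generator.

Emulates the data bundle a TF-knockout prioritization run consumes — DEG
calls, a directed TF cascade rooted at the knockout gene, per-gene SNV
rates, a scale-free PPI graph, and a small literature corpus — with planted
ground truth, so every stage of the pipeline is testable without any
download. The construction guarantees, by wiring rather than by chance:

* true targets sit in the knockout cascade (within ``cascade_depth``),
  carry background-level SNV rates, lie within two PPI hops of the KO
  gene, and are co-mentioned with the context and the KO in planted
  abstracts;
* decoy DEGs are also downstream of the knockout and pass the SNV filter,
  but sit at least three PPI hops away and have no planted co-mentions,
  so only the literature criterion separates them from true targets;
* contaminated genes are downstream DEGs with SNV rates far above any
  sensible threshold (genetic-background artifacts);
* noise DEGs are regulatorily disconnected from the knockout.

Every quantity derives from one ``numpy`` generator seeded from the config,
so identical configs give byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as krio
from .types import (
    ConfigurationError,
    Context,
    Corpus,
    DEGRecord,
    DEGTable,
    InteractionNetwork,
    RegulatoryNetwork,
    SNVProfile,
)

CONTEXT_PHRASE = "stress response"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults describe a small but non-trivial knockout experiment: a
    300-gene universe, a 40-TF cascade of depth 3 fanning out from the
    knockout, 15 genuine downstream targets, 30 downstream decoys, 60
    disconnected noise DEGs, and 10% of the downstream candidates
    contaminated by genetic-background variants.
    """

    n_genes: int = 300
    n_tfs: int = 40
    ko_out_degree: int = 6
    cascade_depth: int = 3
    n_true_targets: int = 15
    n_decoy_degs: int = 30
    n_noise_degs: int = 60
    snv_contaminated_fraction: float = 0.1
    docs_per_planted_gene: int = 3
    n_background_docs: int = 60
    ppi_attachment: float = 2.0
    seed: int = 7

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "n_tfs", "ko_out_degree", "cascade_depth",
            "n_true_targets", "n_decoy_degs", "n_noise_degs",
            "docs_per_planted_gene", "n_background_docs",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.snv_contaminated_fraction <= 1.0:
            raise ConfigurationError("snv_contaminated_fraction must lie in [0, 1]")
        if self.cascade_depth < 1 or self.ko_out_degree < 1:
            raise ConfigurationError("cascade_depth and ko_out_degree must be >= 1")
        if self.n_true_targets + self.n_noise_degs > self.n_genes:
            raise ConfigurationError("more DEGs requested than genes in the universe")

    @property
    def n_contaminated(self) -> int:
        return round(self.snv_contaminated_fraction * (self.n_true_targets + self.n_decoy_degs))


@dataclass(frozen=True)
class GroundTruth:
    true_targets: frozenset[str]
    decoys: frozenset[str]
    contaminated: frozenset[str]


@dataclass
class SimulatedBundle:
    """Everything one pipeline run needs, plus the planted truth."""

    degs: DEGTable
    tf_network: RegulatoryNetwork
    snv: SNVProfile
    ppi: InteractionNetwork
    corpus: Corpus
    context: Context
    ko: str
    truth: GroundTruth
    config: SimulationConfig = field(default=SimulationConfig())

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write every standard-format file the pipeline reads."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "deg": out / "degs.tsv",
            "tf_network": out / "tf_network.tsv",
            "tf_list": out / "tf_list.txt",
            "snv": out / "snv_profile.tsv",
            "ppi": out / "ppi.tsv",
            "corpus": out / "corpus.jsonl",
            "lexicon": out / "lexicon.tsv",
            "truth": out / "validated_genes.txt",
        }
        krio.write_deg_table(self.degs, paths["deg"])
        krio.write_directed_edges(self.tf_network, paths["tf_network"])
        krio.write_tf_list(self.tf_network.tf_set, paths["tf_list"])
        krio.write_snv_tsv(self.snv, paths["snv"])
        krio.write_ppi(self.ppi, paths["ppi"])
        krio.write_corpus(self.corpus, paths["corpus"], paths["lexicon"])
        krio.write_gene_set(self.truth.true_targets, paths["truth"])
        return paths


def _names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(1, n + 1)]


def simulate(cfg: SimulationConfig = SimulationConfig()) -> SimulatedBundle:
    """Generate one coherent bundle; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)

    ko = "Knx1"
    tfs = _names("Tf", cfg.n_tfs)
    targets = _names("Tgt", cfg.n_true_targets)
    decoys = _names("Dcy", cfg.n_decoy_degs)
    contaminated = _names("Cnt", cfg.n_contaminated)
    noise = _names("Nse", cfg.n_noise_degs)
    named = 1 + len(tfs) + len(targets) + len(decoys) + len(contaminated) + len(noise)
    if named > cfg.n_genes:
        raise ConfigurationError(
            f"gene universe too small: {named} named genes > n_genes={cfg.n_genes}"
        )
    fillers = _names("Gen", cfg.n_genes - named)

    # --- directed TF cascade rooted at the KO gene -------------------------
    # Random out-tree over the TFs with bounded fan-out; TF depth is capped
    # at cascade_depth - 1 so targets hung off a TF stay within cascade_depth.
    edges: set[tuple[str, str]] = set()
    depth = {ko: 0}
    out_deg = {ko: 0}
    open_parents = [ko]
    for tf in tfs:
        candidates = [p for p in open_parents if out_deg[p] < cfg.ko_out_degree]
        if not candidates:
            raise ConfigurationError("TF cascade infeasible: no parent slot left")
        parent = candidates[int(rng.integers(len(candidates)))]
        edges.add((parent, tf))
        depth[tf] = depth[parent] + 1
        out_deg[parent] += 1
        out_deg[tf] = 0
        if depth[tf] < cfg.cascade_depth:
            open_parents.append(tf)

    attach_pool = [t for t in [ko, *tfs] if depth[t] <= cfg.cascade_depth - 1]
    if not attach_pool:
        raise ConfigurationError("TF cascade infeasible: no TF shallow enough to attach targets")
    for gene in [*targets, *decoys, *contaminated]:
        parent = attach_pool[int(rng.integers(len(attach_pool)))]
        edges.add((parent, gene))
    tf_network = RegulatoryNetwork(tf_set={ko, *tfs}, edges=edges)

    # --- DEG table ---------------------------------------------------------
    deg_genes = [*targets, *decoys, *contaminated, *noise]
    records = [
        DEGRecord(gene=g, is_deg=True, de_score=float(np.round(rng.uniform(2.0, 8.0), 3)))
        for g in sorted(deg_genes)
    ]
    degs = DEGTable(records=records)

    # --- SNV profile -------------------------------------------------------
    # Background genes: 0-2 variants over 1-4 kb (<= 2 variants/kb).
    # Contaminated genes: ~10 variants/kb, far above any plausible cutoff.
    snv = SNVProfile()
    for g in sorted([*targets, *decoys, *noise]):
        length = int(rng.integers(1000, 4001))
        snv.add(g, int(rng.integers(0, 3)), length)
    for g in contaminated:
        length = int(rng.integers(1000, 4001))
        snv.add(g, int(np.ceil(10.0 * length / 1000.0)), length)

    # --- PPI graph ---------------------------------------------------------
    # Scale-free backbone over everything except targets and decoys, then
    # targets wired within two hops of the KO and each decoy hung off a
    # backbone node at distance >= 2, forcing decoy distance >= 3.
    import networkx as nx

    backbone = [ko, *tfs, *contaminated, *noise, *fillers]
    m = max(1, int(round(cfg.ppi_attachment)))
    if len(backbone) <= m:
        raise ConfigurationError("PPI backbone too small for the attachment parameter")
    bb = nx.barabasi_albert_graph(len(backbone), m, seed=int(rng.integers(2**31)))
    relabel = {i: g for i, g in enumerate(backbone)}
    bb = nx.relabel_nodes(bb, relabel)

    ppi = InteractionNetwork()

    def escore() -> int:
        return int(rng.integers(400, 1000))

    for a, b in sorted(bb.edges()):
        ppi.add_edge(a, b, escore())

    ko_neighbors = sorted(bb[ko])
    for t in targets:
        if rng.random() < 0.5 or not ko_neighbors:
            ppi.add_edge(t, ko, escore())  # 1 hop
        else:
            via = ko_neighbors[int(rng.integers(len(ko_neighbors)))]
            ppi.add_edge(t, via, escore())  # 2 hops

    dist = nx.single_source_shortest_path_length(bb, ko)
    far_nodes = sorted(n for n, d in dist.items() if d >= 2)
    if decoys and not far_nodes:
        raise ConfigurationError("PPI infeasible: no backbone node at distance >= 2 from KO")
    for d in decoys:
        anchor = far_nodes[int(rng.integers(len(far_nodes)))]
        ppi.add_edge(d, anchor, escore())

    # --- corpus ------------------------------------------------------------
    lexicon = {g: {g} for g in [ko, *tfs, *targets, *decoys, *contaminated, *noise, *fillers]}
    documents: list[tuple[str, str]] = []
    doc_no = 0

    def add_doc(text: str) -> None:
        nonlocal doc_no
        doc_no += 1
        documents.append((f"DOC{doc_no:05d}", text))

    for t in targets:
        for _ in range(cfg.docs_per_planted_gene):
            add_doc(
                f"{t} acts downstream of {ko} in the {CONTEXT_PHRASE} of knockout mice."
            )
        # solo mentions (no context, no KO) spread the cosine denominators so
        # the relevance ranking is not one big tie
        for _ in range(int(rng.integers(0, 3))):
            add_doc(f"{t} expression was profiled in an unrelated screen.")
    mentionable = sorted([*decoys, *noise, *fillers]) or sorted(tfs)
    for _ in range(cfg.n_background_docs):
        g = mentionable[int(rng.integers(len(mentionable)))]
        add_doc(f"Expression of {g} was profiled in wild type tissue.")

    corpus = Corpus(documents=documents, lexicon=lexicon)
    context = Context(keywords=(CONTEXT_PHRASE,))

    truth = GroundTruth(
        true_targets=frozenset(targets),
        decoys=frozenset(decoys),
        contaminated=frozenset(contaminated),
    )
    return SimulatedBundle(
        degs=degs,
        tf_network=tf_network,
        snv=snv,
        ppi=ppi,
        corpus=corpus,
        context=context,
        ko=ko,
        truth=truth,
        config=cfg,
    )
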