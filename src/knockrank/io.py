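"""Readers and writers for every file format the pipeline touches.

All tabular files are TSV with a header row. Gene symbols are normalized on
the way in (see :func:`knockrank.types.normalize_symbol`); coordinates follow
the standard conventions: BED intervals are 0-based half-open, VCF POS is
1-based and converted at the boundary.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

from .types import (
    Corpus,
    DEGRecord,
    DEGTable,
    FormatError,
    ConfigurationError,
    InteractionNetwork,
    RankEntry,
    RankedGeneList,
    RegulatoryNetwork,
    SNVProfile,
    normalize_symbol,
)

logger = logging.getLogger(__name__)

_TRUE = {"1", "true", "yes", "y", "t", "deg"}
_FALSE = {"0", "false", "no", "n", "f", "nondeg", "non-deg"}


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty file: {path}") from None
    return df


def read_deg_table(
    path: str | Path,
    *,
    gene_col: str | None = None,
    deg_col: str | None = None,
    score_col: str | None = None,
) -> DEGTable:
    """Load a DEG call table.

    The gene column defaults to a column named ``gene`` (case-insensitive)
    or else the first column. A DE-status column (``is_deg``) is optional;
    without one every row is treated as a DEG. Duplicate genes keep the
    first occurrence with a logged warning.
    """
    df = _read_tsv(path)
    cols = {c.lower(): c for c in df.columns}
    if gene_col is None:
        gene_col = cols.get("gene", df.columns[0])
    if gene_col not in df.columns:
        raise FormatError(f"missing gene column {gene_col!r} in {path}")
    if deg_col is None:
        deg_col = cols.get("is_deg")
    if score_col is None:
        score_col = cols.get("de_score", cols.get("score"))

    records: list[DEGRecord] = []
    seen: set[str] = set()
    dropped = 0
    for _, row in df.iterrows():
        raw = row[gene_col]
        if not isinstance(raw, str) or not raw.strip():
            dropped += 1
            continue
        gene = normalize_symbol(raw)
        if gene in seen:
            logger.warning("duplicate gene %s in %s; keeping first occurrence", gene, path)
            continue
        seen.add(gene)
        is_deg = True
        if deg_col is not None:
            val = str(row[deg_col]).strip().lower()
            if val in _TRUE:
                is_deg = True
            elif val in _FALSE:
                is_deg = False
            else:
                raise FormatError(f"unparseable DE status {row[deg_col]!r} for {gene}")
        score = None
        if score_col is not None and isinstance(row[score_col], str) and row[score_col].strip():
            score = float(row[score_col])
        records.append(DEGRecord(gene=gene, is_deg=is_deg, de_score=score))
    if dropped:
        logger.warning("dropped %d malformed rows from %s", dropped, path)
    if not records:
        raise FormatError(f"no well-formed DEG rows in {path}")
    return DEGTable(records=records)


def read_tf_list(path: str | Path) -> set[str]:
    """One TF symbol per line; blank lines and ``#`` comments ignored."""
    tfs: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            tfs.add(normalize_symbol(line))
    if not tfs:
        raise ConfigurationError(f"empty TF list: {path}")
    return tfs


def read_directed_edges(path: str | Path, tf_list: str | Path | set[str]) -> RegulatoryNetwork:
    """Load a directed TF->target edge list, keeping only edges sourced at a TF.

    Self-loops are dropped with a warning; the count of non-TF-sourced edges
    is logged.
    """
    tfs = tf_list if isinstance(tf_list, set) else read_tf_list(tf_list)
    if not tfs:
        raise ConfigurationError("empty TF list")
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"expected two columns (source, target) in {path}")
    edges: set[tuple[str, str]] = set()
    non_tf = 0
    self_loops = 0
    for _, row in df.iterrows():
        src = normalize_symbol(str(row.iloc[0]))
        tgt = normalize_symbol(str(row.iloc[1]))
        if src == tgt:
            self_loops += 1
            continue
        if src not in tfs:
            non_tf += 1
            continue
        edges.add((src, tgt))
    if self_loops:
        logger.warning("dropped %d self-loop edges from %s", self_loops, path)
    if non_tf:
        logger.info("dropped %d edges with non-TF source from %s", non_tf, path)
    return RegulatoryNetwork(tf_set=set(tfs), edges=edges)


def read_ppi(path: str | Path, min_score: int = 400) -> InteractionNetwork:
    """Load a STRING-style PPI edge list (protein1, protein2, combined_score).

    Keeps edges with score >= ``min_score`` (STRING medium confidence by
    default); duplicate pairs collapse to the max score, self-loops dropped.
    """
    df = _read_tsv(path)
    if df.shape[1] < 3:
        raise FormatError(f"expected three columns (a, b, combined_score) in {path}")
    net = InteractionNetwork()
    for _, row in df.iterrows():
        a = normalize_symbol(str(row.iloc[0]))
        b = normalize_symbol(str(row.iloc[1]))
        try:
            score = int(float(row.iloc[2]))
        except ValueError:
            raise FormatError(f"non-numeric PPI score {row.iloc[2]!r} in {path}") from None
        if not 0 <= score <= 1000:
            raise FormatError(f"PPI score out of [0, 1000]: {score} in {path}")
        if score < min_score:
            continue
        net.add_edge(a, b, score)
    return net


def read_snv_tsv(path: str | Path) -> SNVProfile:
    """Precomputed per-gene SNV profile: columns gene, variant_count, length_bp."""
    df = _read_tsv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        gcol, ccol, lcol = cols["gene"], cols["variant_count"], cols["length_bp"]
    except KeyError as e:
        raise FormatError(f"missing column {e} in SNV profile {path}") from None
    profile = SNVProfile()
    for _, row in df.iterrows():
        gene = normalize_symbol(str(row[gcol]))
        length = int(row[lcol])
        if length <= 0:
            logger.warning("excluding %s: non-positive length %d", gene, length)
            continue
        profile.add(gene, int(row[ccol]), length)
    return profile


def read_bed_intervals(path: str | Path) -> dict[str, dict[str, IntervalTree]]:
    """BED4 gene intervals -> per-gene, per-chromosome interval trees (0-based half-open)."""
    genes: dict[str, dict[str, IntervalTree]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise FormatError(f"{path}:{ln}: BED line needs chrom, start, end, name")
        chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
        gene = normalize_symbol(name)
        if end <= start:
            logger.warning("excluding zero-length interval for %s at %s:%d-%d", gene, chrom, start, end)
            continue
        genes.setdefault(gene, {}).setdefault(chrom, IntervalTree()).addi(start, end)
    empty = [g for g, trees in genes.items() if not any(len(t) for t in trees.values())]
    for g in empty:
        del genes[g]
    return genes


def read_snv_profile(vcf_path: str | Path, bed_path: str | Path) -> SNVProfile:
    """Count VCF records per gene over BED gene intervals.

    A record counts for a gene when its 0-based position (POS - 1) falls in
    the gene's union of intervals; length_bp is the total merged interval
    length. Only PASS / unfiltered records are counted.
    """
    from cyvcf2 import VCF

    genes = read_bed_intervals(bed_path)
    profile = SNVProfile()
    counts = {g: 0 for g in genes}
    lengths: dict[str, int] = {}
    for gene, trees in genes.items():
        total = 0
        for tree in trees.values():
            merged = tree.copy()
            merged.merge_overlaps()
            total += sum(iv.end - iv.begin for iv in merged)
        lengths[gene] = total

    vcf = VCF(str(vcf_path))
    for rec in vcf:
        if rec.FILTER is not None and rec.FILTER not in ("PASS", "."):
            continue
        pos0 = rec.POS - 1
        for gene, trees in genes.items():
            tree = trees.get(rec.CHROM)
            if tree is not None and tree.overlaps_point(pos0):
                counts[gene] += 1
    for gene in genes:
        profile.add(gene, counts[gene], lengths[gene])
    return profile


def read_corpus(docs_path: str | Path, lexicon_path: str | Path | None = None) -> Corpus:
    """JSONL corpus ({"doc_id", "title", "abstract"}) plus an optional synonym lexicon.

    Document text is the title and abstract concatenated, mirroring
    abstract-level literature search.
    """
    documents: list[tuple[str, str]] = []
    seen: set[str] = set()
    for ln, line in enumerate(Path(docs_path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError:
            raise FormatError(f"{docs_path}:{ln}: invalid JSON") from None
        doc_id = str(obj.get("doc_id", "")).strip()
        if not doc_id:
            raise FormatError(f"{docs_path}:{ln}: missing doc_id")
        if doc_id in seen:
            raise FormatError(f"{docs_path}:{ln}: duplicate doc_id {doc_id}")
        seen.add(doc_id)
        text = " ".join(p for p in (obj.get("title", ""), obj.get("abstract", "")) if p)
        documents.append((doc_id, text))
    lexicon: dict[str, set[str]] = {}
    if lexicon_path is not None:
        lexicon = read_lexicon(lexicon_path)
    return Corpus(documents=documents, lexicon=lexicon)


def read_lexicon(path: str | Path) -> dict[str, set[str]]:
    """Synonym lexicon TSV: columns symbol, pipe-separated synonyms."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"expected columns symbol, synonyms in {path}")
    lexicon: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        gene = normalize_symbol(str(row.iloc[0]))
        raw = row.iloc[1]
        syns = {s.strip() for s in str(raw).split("|") if s.strip()} if isinstance(raw, str) else set()
        syns.add(gene)
        lexicon.setdefault(gene, set()).update(syns)
    return lexicon


_OUT_COLUMNS = [
    "rank",
    "gene",
    "relevance_score",
    "relevance_rank",
    "ppi_distance",
    "ppi_rank",
    "borda_points",
]


def write_ranked_list(
    ranked: RankedGeneList,
    diagnostics: Mapping[str, Mapping[str, object]] | None,
    path: str | Path,
) -> None:
    """Write the final ranking as TSV; bit-stable given identical input.

    ``diagnostics`` maps gene -> per-criterion detail (relevance_score,
    relevance_rank, ppi_distance, ppi_rank); missing details are blank.
    Infinite PPI distances serialize as ``inf``.
    """
    diagnostics = diagnostics or {}
    lines = ["\t".join(_OUT_COLUMNS)]
    for entry in ranked.entries:
        d = diagnostics.get(entry.gene, {})

        def fmt(key: str) -> str:
            v = d.get(key)
            if v is None:
                return ""
            if isinstance(v, float):
                if math.isinf(v):
                    return "inf"
                return repr(v)
            return str(v)

        lines.append(
            "\t".join(
                [
                    str(entry.rank),
                    entry.gene,
                    fmt("relevance_score"),
                    fmt("relevance_rank"),
                    fmt("ppi_distance"),
                    fmt("ppi_rank"),
                    repr(entry.score),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_ranked_list(path: str | Path) -> RankedGeneList:
    """Round-trip reader for :func:`write_ranked_list` output (rank, gene, score)."""
    df = _read_tsv(path)
    cols = {c.lower(): c for c in df.columns}
    for required in ("rank", "gene"):
        if required not in cols:
            raise FormatError(f"missing column {required!r} in {path}")
    entries = []
    for _, row in df.iterrows():
        score_col = cols.get("borda_points", cols.get("score"))
        score = float(row[score_col]) if score_col and isinstance(row[score_col], str) else 0.0
        entries.append(
            RankEntry(gene=normalize_symbol(str(row[cols["gene"]])), rank=int(row[cols["rank"]]), score=score)
        )
    return RankedGeneList(entries=entries)


def read_gene_set(path: str | Path) -> set[str]:
    """A plain gene list, one symbol per line (validated/truth sets)."""
    genes: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(normalize_symbol(line))
    return genes


# --- writers used by the simulator and round-trip tests ---------------------


def write_deg_table(table: DEGTable, path: str | Path) -> None:
    lines = ["gene\tis_deg\tde_score"]
    for r in table.records:
        score = "" if r.de_score is None else repr(r.de_score)
        lines.append(f"{r.gene}\t{int(r.is_deg)}\t{score}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_directed_edges(network: RegulatoryNetwork, path: str | Path) -> None:
    lines = ["source\ttarget"]
    for src, tgt in sorted(network.edges):
        lines.append(f"{src}\t{tgt}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_tf_list(tfs: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(tfs)) + "\n")


def write_ppi(network: InteractionNetwork, path: str | Path) -> None:
    lines = ["protein1\tprotein2\tcombined_score"]
    for (a, b), score in sorted(network.scores.items()):
        lines.append(f"{a}\t{b}\t{score}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_snv_tsv(profile: SNVProfile, path: str | Path) -> None:
    lines = ["gene\tvariant_count\tlength_bp"]
    for gene in sorted(profile.lengths):
        lines.append(f"{gene}\t{profile.counts[gene]}\t{profile.lengths[gene]}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_corpus(corpus: Corpus, docs_path: str | Path, lexicon_path: str | Path | None = None) -> None:
    lines = []
    for doc_id, text in corpus.documents:
        lines.append(json.dumps({"doc_id": doc_id, "title": "", "abstract": text}, sort_keys=True))
    Path(docs_path).write_text("\n".join(lines) + "\n")
    if lexicon_path is not None:
        write_lexicon(corpus.lexicon, lexicon_path)


def write_lexicon(lexicon: Mapping[str, set[str]], path: str | Path) -> None:
    lines = ["symbol\tsynonyms"]
    for gene in sorted(lexicon):
        lines.append(f"{gene}\t{'|'.join(sorted(lexicon[gene]))}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")
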