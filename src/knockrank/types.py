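"""Domain types shared across the pipeline.

Gene identity is a case-normalized symbol string: mouse gene symbols appear
in mixed case across DEG callers, network downloads and literature lexica,
so all comparisons happen after normalization to the conventional mouse
capitalization (first letter upper-case, remainder lower-case).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "normalize_symbol",
    "DEGRecord",
    "DEGTable",
    "RegulatoryNetwork",
    "SNVProfile",
    "InteractionNetwork",
    "Corpus",
    "Context",
    "RankEntry",
    "RankedGeneList",
    "FormatError",
    "ConfigurationError",
    "ContractViolation",
]


class FormatError(ValueError):
    """A file violated its expected format."""


class ConfigurationError(ValueError):
    """A run configuration is unusable (empty TF list, empty truth set, ...)."""


class ContractViolation(ValueError):
    """An internal pipeline contract was broken (e.g. a gene missing from a rank list)."""


def normalize_symbol(symbol: str) -> str:
    """Canonicalize a gene symbol for case-insensitive identity.

    ``"GATA3"``, ``"gata3"`` and ``"Gata3"`` all normalize to ``"Gata3"``.
    Raises :class:`FormatError` on empty/blank input.
    """
    s = symbol.strip()
    if not s:
        raise FormatError("empty gene symbol")
    return s[0].upper() + s[1:].lower()


@dataclass(frozen=True)
class DEGRecord:
    gene: str
    is_deg: bool = True
    de_score: float | None = None


@dataclass
class DEGTable:
    """The input differential-expression call set; the universe of initial candidates."""

    records: list[DEGRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def genes(self) -> set[str]:
        return {r.gene for r in self.records}

    def deg_genes(self) -> set[str]:
        return {r.gene for r in self.records if r.is_deg}


@dataclass
class RegulatoryNetwork:
    """Directed TF -> target regulatory graph; every edge source is a known TF."""

    tf_set: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)

    def targets_of(self, gene: str) -> set[str]:
        return {t for (s, t) in self.edges if s == gene}

    def nodes(self) -> set[str]:
        out = set()
        for s, t in self.edges:
            out.add(s)
            out.add(t)
        return out


@dataclass
class SNVProfile:
    """Per-gene variant counts over the gene model, from the knockout samples.

    ``rate(gene)`` is expressed in variants per kilobase; genes absent from
    the profile have rate 0 (no evidence of genetic difference).
    """

    counts: dict[str, int] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)

    def add(self, gene: str, variant_count: int, length_bp: int) -> None:
        if length_bp <= 0:
            raise FormatError(f"non-positive gene length for {gene}: {length_bp}")
        if variant_count < 0:
            raise FormatError(f"negative variant count for {gene}: {variant_count}")
        self.counts[gene] = variant_count
        self.lengths[gene] = length_bp

    def rate(self, gene: str) -> float:
        """Variants per kb; 0.0 for genes not in the profile."""
        if gene not in self.lengths:
            return 0.0
        return self.counts[gene] * 1000.0 / self.lengths[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.lengths

    def __len__(self) -> int:
        return len(self.lengths)


@dataclass
class InteractionNetwork:
    """Undirected PPI graph with STRING-style integer confidence scores in [0, 1000].

    Edges are stored under a sorted node pair; duplicate pairs collapse to
    the maximum score and self-loops are dropped at construction.
    """

    scores: dict[tuple[str, str], int] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add_edge(self, a: str, b: str, score: int) -> None:
        if not 0 <= score <= 1000:
            raise FormatError(f"PPI score out of [0, 1000]: {score} for {a}-{b}")
        if a == b:
            return
        k = self._key(a, b)
        prev = self.scores.get(k)
        if prev is None or score > prev:
            self.scores[k] = score

    def has_edge(self, a: str, b: str) -> bool:
        return self._key(a, b) in self.scores

    def neighbors(self, gene: str) -> set[str]:
        out = set()
        for (a, b) in self.scores:
            if a == gene:
                out.add(b)
            elif b == gene:
                out.add(a)
        return out

    def nodes(self) -> set[str]:
        out = set()
        for a, b in self.scores:
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class Corpus:
    """A local literature corpus: documents plus a gene-synonym lexicon.

    Each document's searchable text is the title and abstract concatenated.
    """

    documents: list[tuple[str, str]] = field(default_factory=list)  # (doc_id, text)
    lexicon: dict[str, set[str]] = field(default_factory=dict)  # gene -> synonyms

    def synonyms(self, gene: str) -> set[str]:
        return self.lexicon.get(gene, set())

    def __len__(self) -> int:
        return len(self.documents)


@dataclass(frozen=True)
class Context:
    """User hypothesis for the knockout experiment: an ordered set of keyword phrases."""

    keywords: tuple[str, ...]

    def __post_init__(self) -> None:
        cleaned = []
        seen = set()
        for kw in self.keywords:
            phrase = " ".join(kw.split())
            if not phrase:
                raise ConfigurationError("empty context keyword phrase")
            if phrase.lower() not in seen:
                seen.add(phrase.lower())
                cleaned.append(phrase)
        if not cleaned:
            raise ConfigurationError("context requires at least one keyword phrase")
        object.__setattr__(self, "keywords", tuple(cleaned))


@dataclass(frozen=True)
class RankEntry:
    gene: str
    rank: int
    score: float


@dataclass
class RankedGeneList:
    """Ordered candidates under competition ranking.

    Tied entries share the smallest rank of their block; the next distinct
    rank equals 1 + the number of strictly better entries. Entries are
    sorted by rank, then gene symbol (a cosmetic tie-break only).
    """

    entries: list[RankEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    def rank_of(self, gene: str) -> int | float:
        """Rank of ``gene``, or ``inf`` when the gene is not in the list."""
        for e in self.entries:
            if e.gene == gene:
                return e.rank
        return math.inf

    def rank_map(self) -> dict[str, int]:
        return {e.gene: e.rank for e in self.entries}


def competition_rank(
    scores: Mapping[str, float], *, higher_is_better: bool = True
) -> RankedGeneList:
    """Build a :class:`RankedGeneList` from per-gene scores.

    Ties on score share a rank (competition / "1224" ranking); presentation
    order within a tie block is lexicographic by gene symbol.
    """

    def sort_key(item: tuple[str, float]) -> tuple[float, str]:
        gene, score = item
        return ((-score if higher_is_better else score), gene)

    ordered = sorted(scores.items(), key=sort_key)
    entries: list[RankEntry] = []
    prev_score: float | None = None
    prev_rank = 1
    for i, (gene, score) in enumerate(ordered):
        if prev_score is not None and score == prev_score:
            rank = prev_rank
        else:
            rank = i + 1
        entries.append(RankEntry(gene=gene, rank=rank, score=float(score)))
        prev_score, prev_rank = score, rank
    return RankedGeneList(entries=entries)


def normalize_all(symbols: Iterable[str]) -> set[str]:
    return {normalize_symbol(s) for s in symbols}
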