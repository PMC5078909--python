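"""Literature relevance scoring and ranking of candidate genes.

Each candidate is scored twice over a local abstract corpus: once against
the user's context keywords and once against the knockout gene, and the
maximum of the two represents the candidate's relevance. Scoring is
document co-occurrence: the default ``cosine`` scorer is the overlap of the
two terms' document sets normalized by the geometric mean of their sizes
(bounded in [0, 1] and symmetric); a raw co-mention ``count`` scorer is
available for corpora too small for normalization to matter.

Candidates with zero relevance carry no literature evidence for either the
context or the knockout gene and are rejected outright by default: they do
not enter the final candidate set, so the prediction denominator shrinks
with the context's corpus coverage.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Literal

from .types import Context, Corpus, RankedGeneList, competition_rank

ScorerMode = Literal["cosine", "count"]


@dataclass(frozen=True)
class RelevanceScore:
    """Per-candidate relevance: context score, knockout score, and their max."""

    gene: str
    context_score: float
    ko_score: float

    @property
    def combined(self) -> float:
        return max(self.context_score, self.ko_score)


@lru_cache(maxsize=4096)
def _phrase_pattern(phrase: str) -> re.Pattern[str]:
    # Whole-phrase, case-insensitive, word-boundary match: "Il2" must not hit
    # "Il24" or "Il2ra". Internal whitespace matches any whitespace run.
    parts = [re.escape(p) for p in phrase.split()]
    body = r"\s+".join(parts)
    return re.compile(rf"(?<![0-9A-Za-z_]){body}(?![0-9A-Za-z_])", re.IGNORECASE)


def mention_docs(corpus: Corpus, term_set: Iterable[str]) -> set[str]:
    """IDs of documents mentioning at least one phrase from ``term_set``.

    Matching is case-insensitive on whole phrases at word boundaries.
    """
    patterns = [_phrase_pattern(" ".join(t.split())) for t in term_set if t.strip()]
    if not patterns:
        return set()
    hits: set[str] = set()
    for doc_id, text in corpus.documents:
        if any(p.search(text) for p in patterns):
            hits.add(doc_id)
    return hits


def cooccurrence_score(
    corpus: Corpus,
    query_terms: Iterable[str],
    gene: str,
    mode: ScorerMode = "cosine",
) -> float:
    """Relevance of one query entity (a keyword phrase, or a gene's synonyms)
    to ``gene`` by document co-occurrence.

    cosine: ``|D(q) ∩ D(g)| / sqrt(|D(q)| * |D(g)|)``, 0 when either set is
    empty. count: ``|D(q) ∩ D(g)|``. A gene with no lexicon entry scores 0.
    """
    synonyms = corpus.synonyms(gene)
    if not synonyms:
        return 0.0
    d_query = mention_docs(corpus, query_terms)
    d_gene = mention_docs(corpus, synonyms)
    overlap = len(d_query & d_gene)
    if mode == "count":
        return float(overlap)
    if not d_query or not d_gene:
        return 0.0
    return overlap / math.sqrt(len(d_query) * len(d_gene))


def relevance_score(
    corpus: Corpus,
    context: Context,
    gene: str,
    mode: ScorerMode = "cosine",
) -> float:
    """Context relevance of ``gene``: each keyword phrase scored separately,
    maximum taken (multi-word phrases match as whole phrases, never as bags
    of words)."""
    return max(cooccurrence_score(corpus, [kw], gene, mode) for kw in context.keywords)


def score_candidates(
    corpus: Corpus,
    context: Context,
    ko: str,
    candidates: Iterable[str],
    mode: ScorerMode = "cosine",
) -> list[RelevanceScore]:
    """Score every candidate against the context and the knockout gene.

    The knockout gene is treated as one entity (all its synonyms pooled).
    Output is ordered by gene symbol for determinism.
    """
    ko_terms = corpus.synonyms(ko) or {ko}
    scores = []
    for gene in sorted(set(candidates)):
        ctx = relevance_score(corpus, context, gene, mode)
        kos = cooccurrence_score(corpus, ko_terms, gene, mode)
        scores.append(RelevanceScore(gene=gene, context_score=ctx, ko_score=kos))
    return scores


def rank_by_relevance(
    scores: Iterable[RelevanceScore], reject_zero: bool = True
) -> RankedGeneList:
    """Rank candidates by combined relevance, descending, competition ranks.

    With ``reject_zero`` (default) genes with zero combined relevance are
    removed entirely — no literature ties the gene to either the context or
    the knockout, so it cannot be prioritized and is not predicted at all.
    """
    kept = {s.gene: s.combined for s in scores if not (reject_zero and s.combined == 0.0)}
    return competition_rank(kept, higher_is_better=True)
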