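"""Precision / recall / F-measure against a publication-validated gene set.

The prediction set is the post-rejection ranked list — candidates that
survived every filter and carried literature evidence — not the raw DEG
list. Recall is measured against the validated genes reported for the
knockout study, and the top-k protocol counts validated genes whose
competition rank is within k (every gene tied at a rank boundary counts).
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import ConfigurationError, RankedGeneList


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class EvaluationResult:
    tp: int
    predicted: int
    relevant: int
    top_k_hits: int
    k: int

    @property
    def precision(self) -> float:
        return self.tp / self.predicted if self.predicted else 0.0

    @property
    def recall(self) -> float:
        return self.tp / self.relevant if self.relevant else 0.0

    @property
    def f(self) -> float:
        return f_measure(self.precision, self.recall)

    def as_dict(self) -> dict[str, float | int]:
        return {
            "tp": self.tp,
            "predicted": self.predicted,
            "relevant": self.relevant,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f,
            "top_k_hits": self.top_k_hits,
            "k": self.k,
        }


def evaluate(ranked: RankedGeneList, validated: set[str], k: int = 10) -> EvaluationResult:
    """Score a ranking against the validated gene set.

    tp is the overlap between the ranked genes and the validated set;
    precision divides by the ranked-list size, recall by the validated-set
    size. ``top_k_hits`` counts validated genes with rank <= k.
    """
    if not validated:
        raise ConfigurationError("validated gene set is empty")
    if k < 1:
        raise ConfigurationError("top-k cutoff must be >= 1")
    genes = set(ranked.genes())
    tp = len(genes & validated)
    top_k = sum(1 for e in ranked.entries if e.rank <= k and e.gene in validated)
    return EvaluationResult(
        tp=tp, predicted=len(ranked), relevant=len(validated), top_k_hits=top_k, k=k
    )


def counts_result(tp: int, predicted: int, relevant: int) -> EvaluationResult:
    """Build a result directly from the three counts (no ranking available)."""
    if relevant <= 0:
        raise ConfigurationError("relevant must be positive")
    if tp > min(predicted, relevant):
        raise ValueError("tp cannot exceed predicted or relevant")
    return EvaluationResult(tp=tp, predicted=predicted, relevant=relevant, top_k_hits=0, k=10)
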