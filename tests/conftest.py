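from __future__ import annotations

import pytest

from knockrank import (
    Context,
    Corpus,
    DEGRecord,
    DEGTable,
    InteractionNetwork,
    RegulatoryNetwork,
    SNVProfile,
)


def make_corpus(docs: dict[str, str], lexicon: dict[str, set[str]]) -> Corpus:
    return Corpus(documents=sorted(docs.items()), lexicon=lexicon)


@pytest.fixture
def worked_instance():
    """Six-gene instance small enough to prioritize by hand.

    Ko knocks out a TF whose cascade reaches A, B, C, E, F (D is removed by
    the SNV filter, G is a disconnected noise DEG). The corpus gives
    relevance C=1.0 > A=2/sqrt(6) > B=1/sqrt(6), E and F have no literature
    evidence; the PPI places A at 1 hop, B at 2, C at 3. Hand Borda tally
    (N=3): A = 2+3 = 5, C = 3+1 = 4, B = 1+2 = 3.
    """
    degs = DEGTable(records=[DEGRecord(gene=g) for g in ["Gena", "Genb", "Genc", "Gend", "Gene", "Genf", "Geng"]])
    tf_net = RegulatoryNetwork(
        tf_set={"Ko"},
        edges={("Ko", g) for g in ["Gena", "Genb", "Genc", "Gend", "Gene", "Genf"]},
    )
    snv = SNVProfile()
    snv.add("Gend", 10, 1000)  # 10 variants/kb -> filtered
    for g in ["Gena", "Genb", "Genc", "Gene", "Genf"]:
        snv.add(g, 0, 1000)
    ppi = InteractionNetwork()
    ppi.add_edge("Ko", "Gena", 900)
    ppi.add_edge("Gena", "Genb", 900)
    ppi.add_edge("Ko", "Genx", 900)
    ppi.add_edge("Genx", "Geny", 900)
    ppi.add_edge("Geny", "Genc", 900)
    corpus = make_corpus(
        {
            "d1": "Gena is required for wing development",
            "d2": "Gena modulates wing development pathways",
            "d3": "Genb influences wing development",
            "d4": "Genb acts in an unrelated process",
            "d5": "Genc interacts with Ko in embryos",
            "d6": "Gene expression was profiled",
        },
        {g: {g} for g in ["Ko", "Gena", "Genb", "Genc", "Gend", "Gene", "Genf"]},
    )
    context = Context(keywords=("wing development",))
    return dict(degs=degs, tf_net=tf_net, snv=snv, ppi=ppi, corpus=corpus, context=context, ko="Ko")
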