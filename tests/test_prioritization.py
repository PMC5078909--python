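import itertools
import math

import numpy as np
import pytest

from knockrank import (
    InteractionNetwork,
    RankedGeneList,
    borda_combine,
    competition_rank,
    rank_by_path,
    run_pipeline,
    shortest_hops,
)
from knockrank.prioritization import borda_points, path_distances
from knockrank.types import ContractViolation, RankEntry


def ppi_from(edges):
    net = InteractionNetwork()
    for a, b in edges:
        net.add_edge(a, b, 900)
    return net


class TestShortestHops:
    def test_direct_edge_is_one_hop(self):
        net = ppi_from([("Ko", "Gg")])
        assert shortest_hops(net, "Ko", "Gg").hops == 1

    def test_absent_gene_is_infinite(self):
        net = ppi_from([("Ko", "Gg")])
        assert math.isinf(shortest_hops(net, "Ko", "Zz").hops)

    def test_ko_itself_is_zero_and_flagged(self, caplog):
        net = ppi_from([("Ko", "Gg")])
        assert shortest_hops(net, "Ko", "Ko").hops == 0
        assert any("knockout" in r.message for r in caplog.records)

    def test_matches_matrix_power_oracle_on_random_graphs(self):
        """Hop distance equals the smallest k with (A^k)[u,v] > 0."""
        rng = np.random.default_rng(13)
        for _ in range(5):
            n = 30
            adj = np.triu(rng.random((n, n)) < 0.08, k=1)
            adj = adj | adj.T
            names = [f"N{i:02d}" for i in range(n)]
            net = ppi_from(
                [(names[i], names[j]) for i in range(n) for j in range(i + 1, n) if adj[i, j]]
            )
            ko = names[0]
            reach = adj.astype(bool)
            power = adj.astype(bool)
            oracle = {}
            for k in range(1, n):
                for j in range(n):
                    if power[0, j] and names[j] not in oracle:
                        oracle[names[j]] = k
                power = (power @ adj) > 0
            for j in range(1, n):
                got = shortest_hops(net, ko, names[j]).hops
                expected = oracle.get(names[j], math.inf)
                if names[j] not in net.nodes():
                    expected = math.inf
                assert got == expected

    def test_adding_an_edge_never_increases_distance(self):
        rng = np.random.default_rng(29)
        names = [f"N{i}" for i in range(12)]
        edges = [("N0", "N1")]
        net = ppi_from(edges)
        prev = {g: shortest_hops(net, "N0", g).hops for g in names[1:]}
        for _ in range(20):
            a, b = rng.choice(names, size=2, replace=False)
            edges.append((str(a), str(b)))
            net = ppi_from(edges)
            cur = {g: shortest_hops(net, "N0", g).hops for g in names[1:]}
            for g in names[1:]:
                assert cur[g] <= prev[g]
            prev = cur


class TestRankByPath:
    def test_competition_ranks_on_tied_hops(self):
        net = ppi_from([("Ko", "Aa"), ("Ko", "Bb"), ("Aa", "Cc")])
        ranked = rank_by_path({"Aa", "Bb", "Cc"}, net, "Ko")
        assert ranked.rank_map() == {"Aa": 1, "Bb": 1, "Cc": 3}

    def test_all_disconnected_share_rank_one(self):
        net = ppi_from([("Ko", "Zz")])
        ranked = rank_by_path({"Aa", "Bb"}, net, "Ko")
        assert ranked.rank_map() == {"Aa": 1, "Bb": 1}

    def test_unreachable_genes_rank_after_all_finite(self):
        net = ppi_from([("Ko", "Aa"), ("Lost", "Alone")])
        ranked = rank_by_path({"Aa", "Lost"}, net, "Ko")
        assert ranked.rank_map() == {"Aa": 1, "Lost": 2}

    def test_ko_among_candidates_is_a_contract_violation(self):
        with pytest.raises(ContractViolation):
            rank_by_path({"Ko", "Aa"}, ppi_from([("Ko", "Aa")]), "Ko")

    def test_order_matches_sort_by_distance_oracle(self):
        rng = np.random.default_rng(37)
        names = [f"N{i:02d}" for i in range(40)]
        edges = [
            (names[int(rng.integers(40))], names[int(rng.integers(40))])
            for _ in range(70)
        ]
        net = ppi_from([(a, b) for a, b in edges if a != b])
        cands = set(names[1:])
        ranked = rank_by_path(cands, net, names[0])
        dists = path_distances(net, names[0], cands)
        expected = sorted(cands, key=lambda g: (dists[g], g))
        assert ranked.genes() == expected


def ranked_from_order(genes):
    return RankedGeneList(
        entries=[RankEntry(g, i + 1, float(len(genes) - i)) for i, g in enumerate(genes)]
    )


class TestBordaCombine:
    def test_identical_lists_reproduce_the_order(self):
        lst = ranked_from_order(["Aa", "Bb", "Cc"])
        for k in (1, 2, 4):
            combined = borda_combine([lst] * k)
            assert combined.genes() == ["Aa", "Bb", "Cc"]
        combined = borda_combine([lst, lst])
        assert [e.score for e in combined.entries] == [6.0, 4.0, 2.0]

    def test_hand_tally_with_swap(self):
        l1 = ranked_from_order(["Aa", "Bb", "Cc"])
        l2 = ranked_from_order(["Bb", "Aa", "Cc"])
        combined = borda_combine([l1, l2])
        assert {e.gene: e.score for e in combined.entries} == {"Aa": 5.0, "Bb": 5.0, "Cc": 2.0}
        assert combined.rank_map() == {"Aa": 1, "Bb": 1, "Cc": 3}

    def test_reversed_lists_tie_everything(self):
        l1 = ranked_from_order(["Aa", "Bb", "Cc"])
        l2 = ranked_from_order(["Cc", "Bb", "Aa"])
        combined = borda_combine([l1, l2])
        assert {e.score for e in combined.entries} == {4.0}
        assert all(e.rank == 1 for e in combined.entries)

    def test_missing_gene_is_a_contract_violation_naming_it(self):
        l1 = ranked_from_order(["Aa", "Bb"])
        l2 = ranked_from_order(["Aa"])
        with pytest.raises(ContractViolation, match="Bb"):
            borda_combine([l1, l2])

    def test_tied_genes_get_full_points_of_shared_rank(self):
        tied = RankedGeneList(
            entries=[RankEntry("Aa", 1, 1.0), RankEntry("Bb", 1, 1.0), RankEntry("Cc", 3, 0.0)]
        )
        pts = borda_points(tied)
        assert pts == {"Aa": 3.0, "Bb": 3.0, "Cc": 1.0}

    def test_unanimity(self):
        l1 = ranked_from_order(["Win", "Aa", "Bb"])
        l2 = ranked_from_order(["Win", "Bb", "Aa"])
        combined = borda_combine([l1, l2])
        assert combined.entries[0].gene == "Win" and combined.entries[0].rank == 1

    def test_exhaustive_points_table_oracle_small_instances(self):
        """Fusion agrees with an independent points table on <= 7-gene, 2-list instances."""
        rng = np.random.default_rng(43)
        genes_pool = ["Aa", "Bb", "Cc", "Dd", "Ee", "Ff", "Gg"]
        for trial in range(60):
            n = int(rng.integers(1, 8))
            genes = genes_pool[:n]
            lists = []
            for _ in range(2):
                scores = {g: float(rng.integers(0, 4)) for g in genes}
                lists.append(competition_rank(scores))
            combined = borda_combine(lists)
            # oracle: recompute ranks by counting strictly better, then points
            table = {g: 0.0 for g in genes}
            for lst in lists:
                score_of = {e.gene: e.score for e in lst.entries}
                for g in genes:
                    rank = 1 + sum(1 for h in genes if score_of[h] > score_of[g])
                    table[g] += n - rank + 1
            for e in combined.entries:
                assert e.score == table[e.gene]
                assert e.rank == 1 + sum(1 for h in genes if table[h] > table[e.gene])

    def test_candidate_input_order_is_irrelevant(self):
        scores1 = {"Aa": 3.0, "Bb": 2.0, "Cc": 2.0, "Dd": 0.0}
        l1a = competition_rank(scores1)
        l1b = competition_rank(dict(reversed(list(scores1.items()))))
        assert l1a.rank_map() == l1b.rank_map()


class TestRunPipeline:
    def test_dominant_gene_is_ranked_first(self, worked_instance):
        w = worked_instance
        # make Gena dominate both criteria: direct PPI edge and best relevance
        ppi = ppi_from([("Ko", "Gena"), ("Ko", "Genx"), ("Genx", "Genb"), ("Genx", "Geny"), ("Geny", "Genc")])
        docs = dict(w["corpus"].documents)
        docs["d9"] = "Gena is central to wing development and more"
        docs["d10"] = "Ko studied alone in another context"  # dilutes Genc's Ko score
        corpus = type(w["corpus"])(documents=sorted(docs.items()), lexicon=w["corpus"].lexicon)
        ranked, _ = run_pipeline(
            w["degs"], w["tf_net"], w["snv"], ppi, corpus, w["context"], w["ko"]
        )
        assert ranked.entries[0].gene == "Gena" and ranked.entries[0].rank == 1

    def test_end_to_end_matches_hand_computation(self, worked_instance):
        w = worked_instance
        ranked, diag = run_pipeline(
            w["degs"], w["tf_net"], w["snv"], w["ppi"], w["corpus"], w["context"], w["ko"]
        )
        # hand tally: relevance ranks C=1, A=2, B=3; PPI ranks A=1, B=2, C=3;
        # Borda points A=5, C=4, B=3
        assert ranked.genes() == ["Gena", "Genc", "Genb"]
        assert [e.score for e in ranked.entries] == [5.0, 4.0, 3.0]
        assert ranked.rank_map() == {"Gena": 1, "Genc": 2, "Genb": 3}
        assert diag.stage_sizes == {
            "input_degs": 7,
            "after_tf_filter": 6,
            "after_snv_filter": 5,
            "after_relevance": 3,
            "final": 3,
        }
        assert diag.per_gene["Gena"]["ppi_distance"] == 1.0
        assert diag.per_gene["Genc"]["relevance_rank"] == 1

    def test_stage_sizes_monotone_nonincreasing(self, worked_instance):
        w = worked_instance
        _, diag = run_pipeline(
            w["degs"], w["tf_net"], w["snv"], w["ppi"], w["corpus"], w["context"], w["ko"]
        )
        sizes = [
            diag.stage_sizes[k]
            for k in ["input_degs", "after_tf_filter", "after_snv_filter", "after_relevance", "final"]
        ]
        assert all(a >= b for a, b in itertools.pairwise(sizes[:-1]))
        assert sizes[-1] == sizes[-2]

    def test_empty_stage_yields_graceful_empty_output(self, worked_instance):
        w = worked_instance
        from knockrank import RegulatoryNetwork

        no_net = RegulatoryNetwork(tf_set={"Ko"}, edges=set())
        ranked, diag = run_pipeline(
            w["degs"], no_net, w["snv"], w["ppi"], w["corpus"], w["context"], w["ko"]
        )
        assert len(ranked) == 0
        assert diag.empty_stage == "tf_filter"
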