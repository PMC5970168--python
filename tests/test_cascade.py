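"""Tripartite graph assembly, module enumeration and annotation."""

import itertools

import numpy as np
import pytest

from cotton_mapk.cascade import (
    CascadeModule,
    InteractionEdge,
    ResponseProfile,
    annotate_shared_responses,
    build_graph,
    enumerate_modules,
    graph_summary,
    summarize_interactions,
)


def edge(up, down, tier):
    return InteractionEdge(upstream=up, downstream=down, tier=tier)


TOY_EDGES = [
    edge("MEKK1", "MKK9", "KKK-KK"),
    edge("RAF2", "MKK9", "KKK-KK"),
    edge("MKK9", "MPK1", "KK-K"),
    edge("MKK9", "MPK2", "KK-K"),
    edge("MKK9", "MPK3", "KK-K"),
]


class TestEdgeValidation:
    def test_tier_prefix_mismatch_rejected(self):
        with pytest.raises(ValueError, match="must end on an MKK"):
            edge("MEKK1", "MPK3", "KKK-KK")
        with pytest.raises(ValueError, match="must start from an MKK"):
            edge("MEKK1", "MPK3", "KK-K")
        with pytest.raises(ValueError):
            edge("NOTAKINASE1", "MKK1", "KKK-KK")

    def test_unknown_tier_rejected(self):
        with pytest.raises(ValueError, match="unknown tier"):
            edge("MEKK1", "MKK1", "K-KK")

    def test_alias_normalization(self):
        assert edge("MEKK3_2", "MKK2", "KKK-KK").downstream == "MKK2_2"

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_graph([TOY_EDGES[0], TOY_EDGES[0]])


class TestBuildGraph:
    def test_empty_edges_empty_graph(self):
        g = build_graph([])
        assert g.number_of_nodes() == 0

    def test_fixture_layer_counts(self, kkk_kk_edges):
        """18 published KKK-KK pairs involve 14 MAPKKKs and 6 MKKs."""
        g = build_graph(kkk_kk_edges)
        s = graph_summary(g)
        assert s.n_kkk == 14
        assert s.n_kk == 6
        assert g.number_of_edges() == 18

    def test_full_fixture_graph(self, y2h_edges):
        s = graph_summary(build_graph(y2h_edges))
        assert (s.n_kkk, s.n_kk, s.n_k) == (14, 6, 11)


class TestEnumerateModules:
    def test_toy_graph_two_by_three(self):
        mods = enumerate_modules(build_graph(TOY_EDGES))
        assert len(mods) == 6
        assert {(m.kkk, m.k) for m in mods} == set(
            itertools.product(["MEKK1", "RAF2"], ["MPK1", "MPK2", "MPK3"])
        )

    def test_fixture_modules_count(self, y2h_edges, exclusions):
        assert len(enumerate_modules(build_graph(y2h_edges), exclusions)) == 38

    def test_excluding_all_mkks_gives_none(self, y2h_edges):
        g = build_graph(y2h_edges)
        all_kks = [n for n in g if g.nodes[n]["tier"] == "KK"]
        assert enumerate_modules(g, all_kks) == []

    def test_no_module_contains_excluded_gene(self, y2h_edges, exclusions):
        mods = enumerate_modules(build_graph(y2h_edges), exclusions)
        for m in mods:
            assert not ({m.kkk, m.kk, m.k} & exclusions)

    def test_enumeration_deterministic_and_duplicate_free(self, y2h_edges, exclusions):
        g = build_graph(y2h_edges)
        a = enumerate_modules(g, exclusions)
        b = enumerate_modules(g, exclusions)
        assert a == b
        assert len({(m.kkk, m.kk, m.k) for m in a}) == len(a)

    @pytest.mark.parametrize("seed", range(5))
    def test_count_identity_against_brute_force(self, seed):
        """|modules| = sum over MKK nodes of in-degree x out-degree, checked
        against explicit triple enumeration on random tripartite graphs."""
        rng = np.random.default_rng(seed)
        # names chosen outside the display-alias table so normalization is identity
        kkks = [f"MEKK{i}" for i in range(21, 26)]
        kks = [f"MKK{i}" for i in range(11, 15)]
        ks = [f"MPK{i}" for i in range(1, 7)]
        edges = [
            edge(a, b, "KKK-KK") for a in kkks for b in kks if rng.random() < 0.4
        ] + [edge(b, c, "KK-K") for b in kks for c in ks if rng.random() < 0.4]
        exclusions = {g for g in kkks + kks + ks if rng.random() < 0.15}
        graph = build_graph(edges)
        mods = enumerate_modules(graph, exclusions)
        es = {(e.upstream, e.downstream) for e in edges}
        brute = [
            (a, b, c)
            for a in kkks
            for b in kks
            for c in ks
            if (a, b) in es and (b, c) in es and not ({a, b, c} & exclusions)
        ]
        assert len(mods) == len(brute)
        assert {(m.kkk, m.kk, m.k) for m in mods} == set(brute)

    def test_removing_edge_never_increases_count(self, y2h_edges, exclusions):
        full = len(enumerate_modules(build_graph(y2h_edges), exclusions))
        for drop in range(len(y2h_edges)):
            reduced = [e for i, e in enumerate(y2h_edges) if i != drop]
            assert len(enumerate_modules(build_graph(reduced), exclusions)) <= full


class TestAnnotation:
    PROFILES = [
        ResponseProfile("MEKK20", frozenset({"JA", "ABA", "H2O2", "SA", "NaCl", "wounding"}), "computed"),
        ResponseProfile("MPK8", frozenset({"JA", "ABA", "H2O2", "SA", "NaCl", "wounding"}), "fixture"),
        ResponseProfile("MPK20", frozenset({"JA", "ABA", "H2O2", "SA", "NaCl", "wounding"}), "fixture"),
    ]

    def test_shared_set_over_available_members(self):
        """MKK4 has no profile: the shared set is the intersection over the
        remaining members and keeps all six treatments."""
        module = CascadeModule(kkk="MEKK20", kk="MKK4", k="MPK20")
        (ann,) = annotate_shared_responses([module], self.PROFILES)
        shared = ann.shared_signal_responses | ann.shared_abiotic_responses
        assert shared == {"JA", "ABA", "H2O2", "SA", "NaCl", "wounding"}
        assert ann.profiled_members == ("MEKK20", "MPK20")
        assert not ann.low_support

    def test_disjoint_profiles_empty_shared_sets(self):
        profiles = [
            ResponseProfile("MEKK20", frozenset({"JA"}), "computed"),
            ResponseProfile("MPK8", frozenset({"NaCl"}), "fixture"),
        ]
        module = CascadeModule(kkk="MEKK20", kk="MKK4", k="MPK8")
        (ann,) = annotate_shared_responses([module], profiles)
        assert not ann.shared_signal_responses and not ann.shared_abiotic_responses

    def test_single_profile_flagged_low_support(self):
        module = CascadeModule(kkk="MEKK20", kk="MKK4", k="MPK99")
        (ann,) = annotate_shared_responses([module], self.PROFILES[:1])
        assert ann.low_support
        shared = ann.shared_signal_responses | ann.shared_abiotic_responses
        assert shared == self.PROFILES[0].induced_treatments

    def test_shared_sets_subset_of_every_profile(self, y2h_edges, exclusions):
        from cotton_mapk import datasets

        profiles = datasets.load_response_profiles()
        by_gene = {p.gene: p.induced_treatments for p in profiles}
        mods = annotate_shared_responses(
            enumerate_modules(build_graph(y2h_edges), exclusions), profiles
        )
        for m in mods:
            shared = m.shared_signal_responses | m.shared_abiotic_responses
            for gene in m.profiled_members:
                assert shared <= by_gene[gene]


class TestSummarize:
    def test_fixture_totals_and_split(self, kkk_kk_edges):
        s = summarize_interactions(kkk_kk_edges)
        assert s.total == 18
        assert s.by_subfamily == {"MEKK": 9, "Raf": 7, "ZIK": 2}
        assert s.n_kkk == 14
        assert s.n_kk == 6

    def test_single_edge(self):
        s = summarize_interactions([edge("MEKK4_2", "MKK1", "KKK-KK")])
        assert s.total == 1
        assert s.by_subfamily == {"MEKK": 1}
        assert s.partners_per_kk == {"MKK1": ("MEKK4_2",)}
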