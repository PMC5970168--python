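"""Tripartite MAPK cascade graph assembly and module enumeration.

A complete MAPK signaling module is a triple (MAPKKK, MKK, MAPK) whose two
tier interactions — MAPKKK->MKK and MKK->MAPK, both from yeast two-hybrid
evidence — are present in the interaction graph.  Genes with expression
too low to support a cascade are excluded by removing their nodes before
enumeration.  Each surviving module is annotated with the stress
treatments shared by all members with a known response profile, split into
the signal-molecule family {JA, H2O2, ABA, SA} and the abiotic family
{NaCl, PEG, cold_4C, heat_37C, wounding}.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import networkx as nx

from cotton_mapk.classify import subfamily_from_name
from cotton_mapk.expression import ABIOTIC_TREATMENTS, SIGNAL_TREATMENTS

TIER_KKK_KK = "KKK-KK"
TIER_KK_K = "KK-K"

#: Display aliases -> canonical gene ids (the MKK tier appears as MKK2 in
#: cascade figures but MKK2_2 in the interaction lists).
NAME_ALIASES: Mapping[str, str] = {"MKK2": "MKK2_2"}

_MKK_RE = re.compile(r"^MKK\d+(_\d+)?$", re.IGNORECASE)
_MPK_RE = re.compile(r"^MPK\d+(_\d+)?$", re.IGNORECASE)


def normalize_name(name: str) -> str:
    name = name.strip()
    return NAME_ALIASES.get(name.upper(), name)


@dataclass(frozen=True)
class InteractionEdge:
    """One directed kinase-tier interaction (KKK->KK or KK->K)."""

    upstream: str
    downstream: str
    tier: str
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "upstream", normalize_name(self.upstream))
        object.__setattr__(self, "downstream", normalize_name(self.downstream))
        if self.tier not in (TIER_KKK_KK, TIER_KK_K):
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.tier == TIER_KKK_KK:
            subfamily_from_name(self.upstream)  # raises on a non-MAPKKK prefix
            if not _MKK_RE.match(self.downstream):
                raise ValueError(
                    f"{self.upstream}->{self.downstream}: KKK-KK edge must end on an MKK"
                )
        else:
            if not _MKK_RE.match(self.upstream):
                raise ValueError(
                    f"{self.upstream}->{self.downstream}: KK-K edge must start from an MKK"
                )
            if not _MPK_RE.match(self.downstream):
                raise ValueError(
                    f"{self.upstream}->{self.downstream}: KK-K edge must end on an MPK"
                )


@dataclass(frozen=True)
class CascadeModule:
    """One (MAPKKK, MKK, MAPK) triple with shared-response annotation."""

    kkk: str
    kk: str
    k: str
    shared_signal_responses: frozenset[str] = field(default_factory=frozenset)
    shared_abiotic_responses: frozenset[str] = field(default_factory=frozenset)
    profiled_members: tuple[str, ...] = ()  # members whose profile informed the annotation
    low_support: bool = False  # fewer than 2 members had profiles


@dataclass(frozen=True)
class ResponseProfile:
    """Stress treatments under which a gene is induced."""

    gene: str
    induced_treatments: frozenset[str]
    provenance: str = "computed"  # computed | fixture


class GraphSummary(NamedTuple):
    n_kkk: int
    n_kk: int
    n_k: int
    degrees: dict[str, int]


def _natural_key(name: str) -> tuple:
    return tuple(int(p) if p.isdigit() else p for p in re.split(r"(\d+)", name))


def build_graph(edges: Iterable[InteractionEdge]) -> nx.DiGraph:
    """Build the tripartite cascade graph from validated interaction edges.

    Nodes carry a ``tier`` attribute in {KKK, KK, K}; name normalization
    (e.g. MKK2 -> MKK2_2) happens at edge construction.  Duplicate
    (upstream, downstream, tier) edges raise ``ValueError``.
    """
    graph = nx.DiGraph()
    seen: set[tuple[str, str, str]] = set()
    for edge in edges:
        key = (edge.upstream, edge.downstream, edge.tier)
        if key in seen:
            raise ValueError(f"duplicate edge {key}")
        seen.add(key)
        if edge.tier == TIER_KKK_KK:
            up_tier, down_tier = "KKK", "KK"
        else:
            up_tier, down_tier = "KK", "K"
        for node, tier in ((edge.upstream, up_tier), (edge.downstream, down_tier)):
            if graph.has_node(node) and graph.nodes[node]["tier"] != tier:
                raise ValueError(
                    f"{node}: appears in both tier {graph.nodes[node]['tier']} and {tier}"
                )
            graph.add_node(node, tier=tier)
        graph.add_edge(edge.upstream, edge.downstream, tier=edge.tier, source=edge.source)
    return graph


def graph_summary(graph: nx.DiGraph) -> GraphSummary:
    tiers = nx.get_node_attributes(graph, "tier")
    return GraphSummary(
        n_kkk=sum(1 for t in tiers.values() if t == "KKK"),
        n_kk=sum(1 for t in tiers.values() if t == "KK"),
        n_k=sum(1 for t in tiers.values() if t == "K"),
        degrees={n: graph.degree(n) for n in sorted(graph, key=_natural_key)},
    )


def enumerate_modules(graph: nx.DiGraph, exclusions: Iterable[str] = ()) -> list[CascadeModule]:
    """Enumerate all complete (KKK, KK, K) modules after node exclusion.

    Excluded genes are removed from the graph before enumeration, so the
    module count equals the sum over surviving MKK nodes of
    in-degree x out-degree.  Ordering is deterministic: lexicographic with
    numeric-aware comparison on (kkk, kk, k).
    """
    excluded = {normalize_name(g) for g in exclusions}
    pruned = graph.subgraph(n for n in graph if n not in excluded)
    modules = []
    for kk in pruned:
        if pruned.nodes[kk]["tier"] != "KK":
            continue
        for kkk in pruned.predecessors(kk):
            for k in pruned.successors(kk):
                modules.append(CascadeModule(kkk=kkk, kk=kk, k=k))
    modules.sort(key=lambda m: (_natural_key(m.kkk), _natural_key(m.kk), _natural_key(m.k)))
    return modules


def annotate_shared_responses(
    modules: Iterable[CascadeModule],
    profiles: Iterable[ResponseProfile],
) -> list[CascadeModule]:
    """Annotate modules with the treatments shared by all profiled members.

    The shared set is the intersection of ``induced_treatments`` over the
    module members that have a profile; members without a profile are
    skipped and the module flagged ``low_support`` when fewer than two
    members contributed.  The intersection is split into the signal and
    abiotic treatment families.
    """
    by_gene = {normalize_name(p.gene): p for p in profiles}
    annotated = []
    for module in modules:
        contributing = [g for g in (module.kkk, module.kk, module.k) if g in by_gene]
        if contributing:
            shared: frozenset[str] = frozenset(by_gene[contributing[0]].induced_treatments)
            for gene in contributing[1:]:
                shared &= by_gene[gene].induced_treatments
        else:
            shared = frozenset()
        annotated.append(
            CascadeModule(
                kkk=module.kkk,
                kk=module.kk,
                k=module.k,
                shared_signal_responses=shared & SIGNAL_TREATMENTS,
                shared_abiotic_responses=shared & ABIOTIC_TREATMENTS,
                profiled_members=tuple(contributing),
                low_support=len(contributing) < 2,
            )
        )
    return annotated


class InteractionReport(NamedTuple):
    total: int
    by_subfamily: dict[str, int]  # KKK-KK pairs per MAPKKK subfamily
    n_kkk: int
    n_kk: int
    n_k: int
    partners_per_kk: dict[str, tuple[str, ...]]  # MKK -> upstream MAPKKK partners


def summarize_interactions(edges: Iterable[InteractionEdge]) -> InteractionReport:
    """Summarise an interaction edge list: totals, subfamily split, node counts."""
    edges = list(edges)
    kkk_edges = [e for e in edges if e.tier == TIER_KKK_KK]
    kk_edges = [e for e in edges if e.tier == TIER_KK_K]
    by_subfamily = Counter(subfamily_from_name(e.upstream) for e in kkk_edges)
    partners: dict[str, list[str]] = {}
    for e in kkk_edges:
        partners.setdefault(e.downstream, []).append(e.upstream)
    return InteractionReport(
        total=len(edges),
        by_subfamily=dict(by_subfamily),
        n_kkk=len({e.upstream for e in kkk_edges}),
        n_kk=len({e.downstream for e in kkk_edges} | {e.upstream for e in kk_edges}),
        n_k=len({e.downstream for e in kk_edges}),
        partners_per_kk={
            kk: tuple(sorted(ps, key=_natural_key))
            for kk, ps in sorted(partners.items(), key=lambda kv: _natural_key(kv[0]))
        },
    )
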