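"""Assemble complete MAPK signaling modules from the cotton Y2H edge lists.

Loads the bundled interaction data (18 MAPKKK->MKK and 16 MKK->MAPK yeast
two-hybrid pairs), removes the three genes excluded for low expression,
enumerates all complete three-tier modules, and annotates each with the
stress responses shared across its profiled members.
"""

from cotton_mapk import (
    annotate_shared_responses,
    build_graph,
    datasets,
    enumerate_modules,
    summarize_interactions,
)

edges = datasets.load_interactions()
summary = summarize_interactions(edges)
print(f"{summary.total} interaction pairs "
      f"({summary.n_kkk} MAPKKKs, {summary.n_kk} MKKs, {summary.n_k} MAPKs)")
print(f"MAPKKK-MKK pairs by subfamily: {summary.by_subfamily}")

exclusions = datasets.load_exclusions()
modules = annotate_shared_responses(
    enumerate_modules(build_graph(edges), exclusions),
    datasets.load_response_profiles(),
)
print(f"excluding {sorted(exclusions)} -> {len(modules)} complete modules\n")

print(f"{'MAPKKK':<10}{'MKK':<8}{'MAPK':<8}shared responses")
for m in modules[:8]:
    shared = sorted(m.shared_signal_responses) + sorted(m.shared_abiotic_responses)
    print(f"{m.kkk:<10}{m.kk:<8}{m.k:<8}{','.join(shared) or '-'}")
print(f"... ({len(modules) - 8} more)")
print()
print("Each row is one candidate MAPKKK->MKK->MAPK relay; the shared set is")
print("the intersection of induced treatments over members with profiles and")
print("suggests which stresses the whole cascade responds to.")
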