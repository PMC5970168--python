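"""Classify kinase proteins into MEKK/Raf/ZIK subfamilies by signature.

Generates a small synthetic protein set with planted catalytic-domain
signatures, classifies each sequence, and prints per-protein calls plus
molecular weight and isoelectric point.
"""

from cotton_mapk import (
    SimulationConfig,
    classify_subfamily,
    count_by_subfamily,
    gen_proteins,
    protein_stats,
)

config = SimulationConfig(seed=1, n_per_subfamily=2)
records, truth = gen_proteins(config)

print(f"{'id':<14} {'called':<8} {'planted':<8} {'pos':>4} {'MW (kDa)':>9} {'pI':>6}")
calls = []
for record in records:
    call = classify_subfamily(record)
    stats = protein_stats(record)
    calls.append(call)
    print(
        f"{record.id:<14} {call.subfamily:<8} {truth.protein_labels[record.id]:<8} "
        f"{call.match_start:>4} {stats.molecular_weight / 1000:>9.2f} "
        f"{stats.isoelectric_point:>6.2f}"
    )

print()
print("counts per subfamily:", count_by_subfamily(calls))
print("Every call should equal its planted label: the classifier finds the")
print("planted signature (1-based position shown) and precedence resolves the")
print("overlap between the MEKK and the laxer Raf pattern.")
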