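"""Estimate Ka/Ks selection pressure on codon-aligned paralog pairs.

Generates codon pairs with controlled synonymous/nonsynonymous divergence
and runs the Nei-Gojobori estimator with Jukes-Cantor correction.  A
Ka/Ks ratio below 1 indicates purifying selection, as seen for the
segmentally duplicated cotton MAPKKK paralogs.
"""

from cotton_mapk import SimulationConfig, compute_kaks, gen_codon_pairs

config = SimulationConfig(
    seed=7,
    codon_pair_spec=(
        (300, 9, 2),   # strong purifying: mostly synonymous changes
        (300, 4, 4),   # mixed
        (300, 0, 0),   # identical pair
    ),
)
pairs, truth = gen_codon_pairs(config)

print(f"{'pair':<11} {'planted s/n':>11} {'Sd':>6} {'Nd':>6} {'Ka':>8} {'Ks':>8} {'Ka/Ks':>7}  selection")
for pair in pairs:
    r = compute_kaks(pair)
    syn, nonsyn = truth.codon_truth[pair.pair_id]
    ratio = f"{r.ratio:.4f}" if r.ratio == r.ratio else "undef"
    print(
        f"{pair.pair_id:<11} {f'{syn}/{nonsyn}':>11} {r.Sd:>6.2f} {r.Nd:>6.2f} "
        f"{r.Ka:>8.4f} {r.Ks:>8.4f} {ratio:>7}  {r.selection}"
    )

print()
print("Sd/Nd recover the planted change counts exactly (single-hit codons);")
print("identical pairs have zero rates and an undefined ratio.")
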