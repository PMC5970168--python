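# cotton-mapk

Assembly and stress-response profiling of plant MAPK signaling cascades,
built around the cotton (*Gossypium*) MAPKKK kinase family.

Plant mitogen-activated protein kinase (MAPK) cascades are three-tier
phosphorylation relays — MAPKKK → MKK → MAPK — that transduce hormone and
abiotic-stress signals. This package implements the computational chain
needed to go from kinase sequences and interaction screens to complete,
annotated signaling modules:

- **Subfamily classification** of MAPKKKs into MEKK, Raf and ZIK groups by
  their catalytic-domain signatures (`G(T/S)PX(W/Y/F)MAPEV`,
  `GTXX(W/Y)MAPE`, `GTPEFMAPE(L/V/M)(Y/F/L)`), plus gene-name mapping
  (CTR1/EDR1 → Raf; ANP/YDA → MEKK) and protein statistics (average MW;
  pI by bisection on the Henderson–Hasselbalch net charge).
- **Selection-pressure analysis** of paralog codon pairs with the
  Nei–Gojobori (1986) counting method: per-codon synonymous-site
  fractions, equal-weight mutational-pathway enumeration, Jukes–Cantor
  correction d = −(3/4)·ln(1 − 4p/3), and the Ka/Ks < 1 / = 1 / > 1
  purifying / neutral / positive classification. A brute-force
  enumeration oracle (`kaks_oracle`) cross-checks the estimator.
- **Expression profiling**: row z-scoring z = (x − μ)/σ of gene × tissue
  FPKM matrices; Livak 2^−ΔΔCt relative expression from replicate Ct
  tables; induction calling (fold ≥ 2 with Student's t-test P < 0.05 at
  some time point; "D" for significant reduction) with peak-time reporting.
- **Cascade assembly**: a tripartite interaction graph from yeast
  two-hybrid edge lists, enumeration of all complete (MAPKKK, MKK, MAPK)
  modules under low-expression exclusions, and annotation of each module
  with the stress responses shared across its members.
- **Synthetic data with planted truth** for every stage (signatures in
  random background, codon pairs with exact planted change counts, FPKM
  matrices, Ct time courses with planted fold changes), so the entire
  pipeline is testable without any downloads.

The package ships the published cotton yeast two-hybrid dataset as
fixtures: 18 MAPKKK–MKK pairs, 16 MKK–MAPK pairs, per-treatment
induced-gene lists for nine stress treatments, and the three-gene
low-expression exclusion set (`cotton_mapk.datasets`).

## Worked example

Enumerate the complete cotton MAPK modules from the bundled interaction
data (`examples/05_cascade_modules.py`):

```python
from cotton_mapk import build_graph, enumerate_modules, summarize_interactions, datasets

edges = datasets.load_interactions()
print(summarize_interactions(edges).by_subfamily)
modules = enumerate_modules(build_graph(edges), datasets.load_exclusions())
print(len(modules))
```

prints

```
{'MEKK': 9, 'Raf': 7, 'ZIK': 2}
38
```

i.e. the 18 MAPKKK–MKK interactions split into 9 MEKK-, 7 Raf- and
2 ZIK-subfamily pairs, and after excluding the three genes whose
expression is too low to support a cascade (MKK10_1, MEKK19, RAF17_2) the
two edge lists combine into exactly 38 complete MAPKKK→MKK→MAPK modules.
Each module can then be annotated with the treatments (out of JA, H₂O₂,
ABA, SA, NaCl, PEG, 4 °C, 37 °C, wounding) shared by all its profiled
members — see the example script for the annotated table.

The other `examples/` scripts walk through classification, Ka/Ks,
z-scoring and qPCR induction calling in the same style. A thin CLI mirrors
the library (`cotton-mapk simulate|classify|protstats|kaks|zscore|qpcr-call|assemble|run|validate`).

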