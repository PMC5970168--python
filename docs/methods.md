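# Methods

This note records the models, conventions and design choices behind
`cotton_mapk`, in the spirit of a statistical-software methods appendix.
Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Subfamily classification

MAPKKK subfamilies are detected by their catalytic-domain signatures,
expressed as ordered residue classes:

| subfamily | signature |
|---|---|
| MEKK | G (T/S) P x (W/Y/F) M A P E V |
| Raf  | G T x x (W/Y) M A P E |
| ZIK  | G T P E F M A P E (L/V/M) (Y/F/L) |

`x` matches any of the 20 standard residues only; gaps and ambiguity
codes are rejected at parse time with the offending position. The
literature prints the MEKK variable class both as (F/Y/W) and (W/Y/F);
these are the same set and are treated identically. For ZIK we adopt the
broader (L/V/M)(Y/F/L) tail variant, which contains the narrower (L/V)Y
variant, so no known example is lost.

The signature classes overlap: every MEKK match whose second position is
T and fifth is W/Y is also a Raf match, and a ZIK match whose tenth
position is V is also a full MEKK match. Classification therefore tests
patterns in the fixed precedence order **MEKK, ZIK, Raf** and returns the
first subfamily that matches anywhere (leftmost occurrence reported,
1-based). Raf is last because its pattern is the least specific. Note the
MEKK/ZIK overlap means the precedence order, not mutual exclusivity,
decides strings like `GTPEFMAPEVY`; the synthetic-protein generator
accordingly rejects planted draws whose classification under precedence
would differ from the planted label.

Gene names map to subfamilies by prefix (MEKK/ANP/YDA → MEKK,
RAF/CTR1/EDR1 → Raf, ZIK → ZIK); CTR1 and EDR1 are Raf-subfamily kinases
despite their historical names. Unknown prefixes are an error, not a
silent "unclassified" — name-based and sequence-based classification are
different operations with different failure modes.

**Protein statistics.** Molecular weight is the sum of average residue
masses plus one water (via Biopython). The isoelectric point solver does
bisection on the Henderson–Hasselbalch net charge over pH 0–14 to
|charge| < 1e-4, using an EMBOSS-style pKa table recorded verbatim in
`classify.PKA_TABLE` (N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5,
K 10.8, R 12.5, Y 10.1). Net charge is strictly decreasing in pH, so
bisection converges unconditionally. Published pI values computed with
other pKa sets (e.g. Bjellqvist) differ by a few tenths of a pH unit;
the table is fixed and public precisely so results are bit-reproducible.

## Ka/Ks estimation

The estimator is the classical Nei–Gojobori (1986) counting method with
equal pathway weights and the Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3). The source study does not name its Ka/Ks tool;
we adopt Nei–Gojobori as the classical default and document it
prominently because approximate-ML estimators give different values.

Conventions that affect the numbers:

- **Sites.** The synonymous-site fraction of a codon position is
  (synonymous changes at that position)/3. Changes that would create a
  stop codon are never synonymous, so they implicitly count toward
  nonsynonymous sites; the per-position denominator stays 3 and
  S + N = 3 × (compared codons) holds exactly. Site counts are averaged
  between the two sequences.
- **Differences.** Codons differing at 2–3 positions are resolved by
  enumerating all substitution orderings; orderings whose intermediates
  are stop codons are dropped and the survivors averaged with equal
  weights. If every ordering is blocked, the codon is masked and a
  warning logged.
- **Masking.** Codons containing `-` or `N` in either sequence are
  masked pairwise. Internal stop codons are rejected at construction;
  a terminal stop is tolerated.
- **Degenerate cases.** p ≥ 3/4 makes the correction undefined: the rate
  is NaN and the selection class "undetermined" (reported, not raised).
  The ratio is defined only when both corrections are finite and Ks > 0;
  neutrality is declared within |Ka/Ks − 1| ≤ 1e-9.
- Standard genetic code (table 1) only — appropriate for plant nuclear
  genes.

`kaks_oracle` recomputes S, N, Sd, Nd by brute force (explicit
permutation walks, site counting via Biopython translation of every
single-nucleotide mutant) and shares no counting code with
`compute_kaks`; the test battery requires agreement to 1e-9 on 200
random pairs. The published 0.0456–0.4588 Ka/Ks range for the 65 cotton
paralog pairs requires the cotton genome sequences and is out of scope;
correctness is instead established by oracle equivalence and exact
planted-count recovery.

## Expression profiling

**Z-scores.** z = (x − μ)/σ per gene row over tissues. The source
formula's σ is described as a "standard error", but the quantity
consistent with z-scoring across eight tissues is the standard
deviation; we use the sample (n−1) form. Constant rows map to all-zeros
and are flagged rather than producing NaNs.

**Relative expression.** Livak 2^−ΔΔCt with assumed amplification
efficiency 2: ΔCt = Ct_target − Ct_reference per replicate (reference
gene histone3 by convention), ΔΔCt = mean ΔCt(treated) − mean ΔCt(mock),
fold = 2^−ΔΔCt. Adding any constant to all Ct values cancels exactly.

**Induction calls.** Per time point, the fold change and a two-sided
pooled-variance Student's t-test on replicate ΔCt values (treated vs
mock). ΔCt rather than fold change is tested because ΔCt is
approximately normal — standard qPCR practice; the source does not
specify. Status is **up** if any time point has fold ≥ 2 and P < 0.05,
**down** ("D") if any has fold ≤ 1/2 and P < 0.05, else none; when both
rules fire, up wins. The peak time is the qualifying time point with
maximal (minimal, for down) fold, earliest on ties; significance is
upgraded to P < 0.01 when the peak time point clears 0.01. "Induced"
always means up at some time point; down-regulation never counts. No
multiple-testing correction is applied (the convention of the source
analyses); the summary output carries an explicit caveat flag. Zero
variance in both compared cells with equal means is treated as P = 1
(no evidence), avoiding 0/0 t-statistics on degenerate input.

## Cascade assembly

Interaction edges are validated against tier/name conventions (KKK-KK
edges run from a MAPKKK-prefixed gene to an MKK; KK-K edges from an MKK
to an MPK) and display aliases are normalized before graph joins
(MKK2 ≡ MKK2_2 — the MKK tier appears under both names in different
renderings of the same dataset). Exclusions (default: MKK10_1, MEKK19,
RAF17_2, the bundled low-expression set) remove nodes *before*
enumeration; this is equivalent to filtering modules afterwards but
cheaper, and makes the count identity |modules| = Σ_MKK in-degree ×
out-degree hold by construction (it is still verified against brute-force
triple enumeration on random graphs in the tests). Module order is
deterministic: numeric-aware lexicographic on (kkk, kk, k).

Shared-response annotation intersects the induced-treatment sets over
the module members that have a profile; members without one are skipped
and modules with fewer than two profiled members are flagged
`low_support`. The intersection is split into the signal-molecule family
{JA, H2O2, ABA, SA} and the abiotic family {NaCl, PEG, cold_4C,
heat_37C, wounding}. MKK-tier profiles are generally absent from the
bundled fixtures (their induction data come from separate family
studies), mirroring how the original cascade narrative cites MAPKKK- and
MAPK-tier inductions.

**Fixture caveats.** The bundled per-treatment induced-gene lists follow
the per-treatment prose enumerations. Two lists are flagged
`ambiguous: true` and excluded from all quantitative checks: ABA (the
source counts ten induced genes but enumerates only nine distinct names)
and SA (the nine genes are never enumerated; the shipped list is a
best-effort reconstruction from cross-treatment summary statements). The
per-gene response profiles used for module annotation come from the
cascade-narrative descriptions, which disagree with the per-treatment
lists for a few gene/treatment pairs; the two fixture families are kept
separate and each is used only for its own purpose.

## Synthetic data

All generators draw from `numpy` Generators seeded with (seed, stream-id)
`SeedSequence`s, so outputs are byte-identical across runs and
independent of call order.

- **Proteins** (default length 120): uniform background over the 20
  standard residues with one planted signature instance at a random
  position, rejection-sampled (bounded at 1000 tries) until (a) no
  signature of any subfamily matches anywhere except at the planted
  start and (b) precedence classification returns the planted label.
  This makes classifier recovery exact, not probabilistic.
- **Codon pairs**: a random stop-free codon sequence is copied and
  exactly the requested numbers of verified synonymous and
  nonsynonymous single-nucleotide changes are applied at *distinct*
  codons (single-hit design), so planted Sd/Nd are recovered exactly by
  the estimator. Unsatisfiable draws (e.g. Met/Trp codons lacking
  synonymous neighbours) are retried under the same bound.
- **FPKM**: log-normal draws — gene log-mean ~ N(2, 1.5), tissue scatter
  σ = 1 — over the eight standard cotton tissues (root, stem, leaf,
  petal, anther, ovule 0 dpa, fiber 10/20 dpa). Emulates the skew of
  real FPKM tables; does not emulate tissue–tissue correlation or
  count-level noise, which the z-score stage does not depend on.
- **qPCR**: ten sampling times (0, 0.5, 1, 2, 4, 6, 8, 10, 12, 24 h),
  paired treated/mock arms at every time point, reference Ct 15 and
  gene-specific target base Ct in 18–25, i.i.d. Gaussian Ct noise
  (default sd 0.1, 3 replicates). A planted fold f shifts the treated
  target Ct by −log2 f at its peak time and by half that (in log2 space)
  at the two adjacent sampling times — the source reports distinct peak
  times per gene, so the caller must be able to find them. Defaults
  (sd 0.1 Ct, n = 3, fold 4 for induced genes) reflect typical qPCR
  replicate noise and the ≥2-fold induction regime of the study design;
  with these settings the planted design matrix is recovered exactly,
  which is what the simulation is built to show. What passing these
  tests does **not** show: robustness to efficiency ≠ 2, correlated
  replicate noise, or reference-gene instability, none of which are
  simulated.

## Problem sizes

The test battery runs synthetic designs at the study's own scale (the
12-gene qPCR panel, 3 replicates, 10 time points; codon pairs of 50–300
codons; 200 oracle-comparison pairs) and completes in a few seconds. The
acceptance script uses the full bundled edge lists and the 12-gene NaCl
design.

## Known limitations

- No HMM/profile-based domain detection; classification is exact-motif
  only and will miss diverged signatures that genome-scale surveys find
  by HMMER.
- Nei–Gojobori with equal pathway weights; no transition/transversion
  weighting, no ML estimator.
- The Livak method assumes perfect doubling per cycle.
- Fixture response profiles inherit the internal inconsistencies of
  their source narrative (see Fixture caveats above).
- The "previously reported in Arabidopsis" status of individual
  interaction pairs is not annotated (not enumerated in the source);
  the edge `source` field is free text for user-supplied provenance.
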