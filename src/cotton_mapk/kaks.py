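"""Nei-Gojobori Ka/Ks estimation for codon-aligned paralog pairs.

Implements the counting method of Nei & Gojobori (1986) with equal-weight
mutational pathway enumeration and the Jukes-Cantor multiple-hit
correction d = -(3/4) ln(1 - 4p/3), classifying selection pressure as
purifying (Ka/Ks < 1), neutral (= 1) or positive (> 1).

Conventions (these matter — other tools make different choices and give
different numbers):

* Synonymous-site fraction per codon position = (synonymous single-nucleotide
  changes at that position) / 3; changes producing stop codons are never
  synonymous, so they count toward nonsynonymous sites.  This keeps
  S + N = 3 x (number of compared codons) exactly.
* Codons containing ``-`` or ``N`` in either sequence are masked pairwise.
* For codons differing at 2-3 positions, all substitution orderings are
  enumerated; pathways passing through a stop codon are excluded and the
  survivors weighted equally.  If every pathway is blocked the codon is
  masked and a warning logged.
* Standard genetic code (translation table 1) only.

``kaks_oracle`` re-derives the same quantities by brute force (explicit
permutation enumeration, independent site counting via Biopython
translation) and exists solely to cross-check ``compute_kaks``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
CODON_TO_AA = dict(_TABLE.forward_table)  # excludes stops
NUCLEOTIDES = "ACGT"


@dataclass(frozen=True)
class CodonAlignment:
    """A pair of codon-aligned nucleotide sequences (A/C/G/T, gap '-', 'N')."""

    pair_id: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError(f"{self.pair_id}: sequence lengths differ ({len(a)} vs {len(b)})")
        if len(a) % 3 != 0:
            raise ValueError(f"{self.pair_id}: length {len(a)} not divisible by 3")
        allowed = set("ACGTN-")
        for label, s in (("seq_a", a), ("seq_b", b)):
            bad = set(s) - allowed
            if bad:
                raise ValueError(f"{self.pair_id}.{label}: invalid characters {sorted(bad)}")
        for label, s in (("seq_a", a), ("seq_b", b)):
            for i in range(0, len(s), 3):
                codon = s[i : i + 3]
                if set(codon) <= set("ACGT") and codon in STOP_CODONS:
                    # terminal stop is tolerated, internal is not
                    if i + 3 < len(s):
                        raise ValueError(
                            f"{self.pair_id}.{label}: internal stop codon {codon} at codon {i // 3 + 1}"
                        )

    def codons(self) -> list[tuple[str, str]]:
        return [
            (self.seq_a[i : i + 3], self.seq_b[i : i + 3])
            for i in range(0, len(self.seq_a), 3)
        ]


@dataclass(frozen=True)
class KaKsResult:
    pair_id: str
    S: float  # synonymous sites (fractional)
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences (pathway-averaged)
    Nd: float  # nonsynonymous differences
    pS: float
    pN: float
    Ks: float  # Jukes-Cantor corrected; NaN if p >= 3/4
    Ka: float
    ratio: float  # Ka/Ks; NaN if undefined
    selection: str  # purifying | neutral | positive | undetermined
    n_codons: int  # comparable (unmasked) codons
    masked_codons: int


def _is_comparable(codon_a: str, codon_b: str) -> bool:
    return set(codon_a) <= set("ACGT") and set(codon_b) <= set("ACGT")


def _syn_sites(codon: str) -> float:
    """Fractional synonymous sites of one codon (Nei-Gojobori)."""
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == aa:
                syn += 1
        s += syn / 3.0
    return s


def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """Pathway-averaged (synonymous, nonsynonymous) differences for one codon pair.

    Enumerates all orderings of the differing positions, drops orderings
    whose intermediate codons are stops, and averages with equal weights.
    Returns ``None`` if every pathway is blocked.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    totals: list[tuple[int, int]] = []
    for order in permutations(diff_positions):
        current = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_TO_AA[current] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            totals.append((sd, nd))
    if not totals:
        return None
    sd_mean = sum(t[0] for t in totals) / len(totals)
    nd_mean = sum(t[1] for t in totals) / len(totals)
    return sd_mean, nd_mean


def _jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - 4p/3); NaN when p >= 3/4."""
    if p >= 0.75:
        return math.nan
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _classify_selection(ratio: float) -> str:
    if math.isnan(ratio):
        return "undetermined"
    if abs(ratio - 1.0) <= 1e-9:
        return "neutral"
    return "purifying" if ratio < 1.0 else "positive"


def _assemble(
    pair_id: str,
    S: float,
    N: float,
    Sd: float,
    Nd: float,
    n_codons: int,
    masked: int,
) -> KaKsResult:
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(pS)
    Ka = _jukes_cantor(pN)
    if math.isnan(Ks) or math.isnan(Ka) or Ks <= 0.0:
        ratio = math.nan
    else:
        ratio = Ka / Ks
    return KaKsResult(
        pair_id=pair_id,
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        Ks=Ks,
        Ka=Ka,
        ratio=ratio,
        selection=_classify_selection(ratio),
        n_codons=n_codons,
        masked_codons=masked,
    )


def compute_kaks(alignment: CodonAlignment) -> KaKsResult:
    """Nei-Gojobori Ka/Ks estimate for one codon-aligned pair.

    Raises ``ValueError`` if no comparable codon survives masking.  A
    saturated proportion (p >= 3/4) yields NaN for the corrected rate and
    ``selection="undetermined"`` rather than an exception.
    """
    S = N = Sd = Nd = 0.0
    n_codons = masked = 0
    for codon_a, codon_b in alignment.codons():
        if not _is_comparable(codon_a, codon_b):
            masked += 1
            continue
        diffs = _pathway_differences(codon_a, codon_b)
        if diffs is None:
            logger.warning(
                "%s: all mutational pathways between %s and %s pass through stop "
                "codons; codon masked",
                alignment.pair_id,
                codon_a,
                codon_b,
            )
            masked += 1
            continue
        sa, sb = _syn_sites(codon_a), _syn_sites(codon_b)
        S += 0.5 * (sa + sb)
        N += 3.0 - 0.5 * (sa + sb)
        Sd += diffs[0]
        Nd += diffs[1]
        n_codons += 1
    if n_codons == 0:
        raise ValueError(f"{alignment.pair_id}: no comparable codons after masking")
    return _assemble(alignment.pair_id, S, N, Sd, Nd, n_codons, masked)


# --------------------------------------------------------------------------
# Brute-force oracle: same quantities, independent derivation.
# --------------------------------------------------------------------------

_ORACLE_MAX_CODONS = 50


def _oracle_translate(codon: str) -> str:
    return str(Seq(codon).translate(table=1))  # '*' for stops


def _oracle_syn_sites(codon: str) -> float:
    count = 0
    for pos, nt in ((p, n) for p in range(3) for n in NUCLEOTIDES):
        mutant = codon[:pos] + nt + codon[pos + 1 :]
        if mutant == codon:
            continue
        if _oracle_translate(mutant) != "*" and _oracle_translate(mutant) == _oracle_translate(codon):
            count += 1
    return count / 3.0


def kaks_oracle(alignment: CodonAlignment) -> KaKsResult:
    """Exhaustive-enumeration reference implementation of ``compute_kaks``.

    Limited to <= 50 codons.  Shares no counting shortcuts with the main
    implementation: sites are recounted via Biopython translation of every
    single-nucleotide mutant, and pathway averaging walks explicit
    permutation lists.
    """
    codon_pairs = alignment.codons()
    if len(codon_pairs) > _ORACLE_MAX_CODONS:
        raise ValueError(f"oracle limited to {_ORACLE_MAX_CODONS} codons")
    S = N = Sd = Nd = 0.0
    n_codons = masked = 0
    for codon_a, codon_b in codon_pairs:
        if set(codon_a + codon_b) - set("ACGT"):
            masked += 1
            continue
        positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
        outcomes: list[tuple[float, float]] = []
        for order in permutations(positions):
            steps: list[str] = [codon_a]
            for pos in order:
                prev = steps[-1]
                steps.append(prev[:pos] + codon_b[pos] + prev[pos + 1 :])
            if any(_oracle_translate(c) == "*" for c in steps[1:]):
                continue
            sd = sum(
                1
                for prev, nxt in zip(steps, steps[1:])
                if _oracle_translate(prev) == _oracle_translate(nxt)
            )
            outcomes.append((float(sd), float(len(positions) - sd)))
        if positions and not outcomes:
            masked += 1
            continue
        if not positions:
            outcomes = [(0.0, 0.0)]
        Sd += sum(o[0] for o in outcomes) / len(outcomes)
        Nd += sum(o[1] for o in outcomes) / len(outcomes)
        half_sites = 0.5 * (_oracle_syn_sites(codon_a) + _oracle_syn_sites(codon_b))
        S += half_sites
        N += 3.0 - half_sites
        n_codons += 1
    if n_codons == 0:
        raise ValueError(f"{alignment.pair_id}: no comparable codons after masking")
    return _assemble(alignment.pair_id, S, N, Sd, Nd, n_codons, masked)
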