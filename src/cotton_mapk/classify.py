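"""Subfamily classification of MAPKKK protein kinases.

Plant MAPKKKs fall into three subfamilies distinguished by a conserved
signature inside the catalytic kinase domain:

* MEKK:  G (T/S) P x (W/Y/F) M A P E V
* Raf:   G T x x (W/Y) M A P E
* ZIK:   G T P E F M A P E (L/V/M) (Y/F/L)

where ``x`` is any standard residue.  The Raf signature is the least
specific of the three: every string matching the MEKK signature with T at
its second position and W/Y at its fifth also matches Raf.  Signatures are
therefore tested in precedence order MEKK, ZIK, Raf, and the first
subfamily with a match anywhere in the sequence wins.

The module also maps gene names to subfamilies (CTR1/EDR1 are Raf-subfamily
members; ANP and YDA are MEKK-subfamily members) and computes basic protein
statistics: average molecular weight and isoelectric point (bisection on
the Henderson-Hasselbalch net charge with an EMBOSS-style pKa table).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.SeqUtils import molecular_weight

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Signature patterns as ordered residue classes; ``None`` is the wildcard
#: (any standard residue).  Order of this mapping is the precedence order.
SUBFAMILY_SIGNATURES: Mapping[str, tuple[frozenset[str] | None, ...]] = {
    "MEKK": (
        frozenset("G"),
        frozenset("TS"),
        frozenset("P"),
        None,
        frozenset("WYF"),
        frozenset("M"),
        frozenset("A"),
        frozenset("P"),
        frozenset("E"),
        frozenset("V"),
    ),
    "ZIK": (
        frozenset("G"),
        frozenset("T"),
        frozenset("P"),
        frozenset("E"),
        frozenset("F"),
        frozenset("M"),
        frozenset("A"),
        frozenset("P"),
        frozenset("E"),
        frozenset("LVM"),
        frozenset("YFL"),
    ),
    "Raf": (
        frozenset("G"),
        frozenset("T"),
        None,
        None,
        frozenset("WY"),
        frozenset("M"),
        frozenset("A"),
        frozenset("P"),
        frozenset("E"),
    ),
}


def _signature_regex(pattern: tuple[frozenset[str] | None, ...]) -> re.Pattern[str]:
    parts = []
    for cls in pattern:
        if cls is None:
            parts.append(f"[{STANDARD_RESIDUES}]")
        elif len(cls) == 1:
            parts.append(next(iter(cls)))
        else:
            parts.append("[" + "".join(sorted(cls)) + "]")
    return re.compile("".join(parts))


_SIGNATURE_RE: dict[str, re.Pattern[str]] = {
    fam: _signature_regex(pat) for fam, pat in SUBFAMILY_SIGNATURES.items()
}

#: Gene-name prefix -> subfamily.  CTR1 and EDR1 are Raf-subfamily kinases
#: despite their historical names; ANP and YDA belong to the MEKK subfamily.
NAME_PREFIX_MAP: Mapping[str, str] = {
    "CTR1": "Raf",
    "EDR1": "Raf",
    "MEKK": "MEKK",
    "ANP": "MEKK",
    "YDA": "MEKK",
    "RAF": "Raf",
    "ZIK": "ZIK",
}

_NAME_SUFFIX_RE = re.compile(r"^\d*(?:_\d+)?$")


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence to classify."""

    id: str
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in STANDARD_RESIDUES:
                raise ValueError(
                    f"{self.id}: non-standard residue {aa!r} at position {pos}"
                )


@dataclass(frozen=True)
class SubfamilyCall:
    """Result of signature classification for one protein.

    ``match_start`` is 1-based; ``match_start`` and ``matched_text`` are
    ``None`` iff the protein is unclassified.
    """

    protein_id: str
    subfamily: str  # MEKK | Raf | ZIK | unclassified
    match_start: int | None = None
    matched_text: str | None = None


@dataclass(frozen=True)
class ProteinStats:
    protein_id: str
    molecular_weight: float  # Daltons, average isotopic
    isoelectric_point: float  # pH units


def classify_subfamily(record: ProteinRecord) -> SubfamilyCall:
    """Classify a kinase into MEKK/Raf/ZIK by catalytic signature.

    Signatures are tried in precedence order MEKK, ZIK, Raf; within a
    subfamily the leftmost match is reported.  No match in any signature
    yields ``subfamily="unclassified"``.
    """
    for family, regex in _SIGNATURE_RE.items():
        m = regex.search(record.sequence)
        if m is not None:
            return SubfamilyCall(
                protein_id=record.id,
                subfamily=family,
                match_start=m.start() + 1,
                matched_text=m.group(0),
            )
    return SubfamilyCall(protein_id=record.id, subfamily="unclassified")


def subfamily_from_name(name: str) -> str:
    """Map a gene name such as ``MEKK4_2``, ``CTR1_1`` or ``ZIK1`` to its subfamily.

    Names follow the convention <prefix><number>[_<variant>].  Raises
    ``ValueError`` on an unrecognised prefix or malformed suffix.
    """
    upper = name.strip().upper()
    for prefix, family in NAME_PREFIX_MAP.items():
        if upper.startswith(prefix):
            suffix = upper[len(prefix):]
            # CTR1_1 parses as prefix CTR1 + variant _1; MEKK4_2 as MEKK + 4_2
            if _NAME_SUFFIX_RE.match(suffix):
                return family
    raise ValueError(f"gene name {name!r} does not follow a known subfamily prefix")


def count_by_subfamily(calls: Iterable[SubfamilyCall]) -> dict[str, int]:
    """Count classified proteins per subfamily; unclassified counted separately."""
    counts = Counter(call.subfamily for call in calls)
    out = {fam: counts.get(fam, 0) for fam in ("MEKK", "Raf", "ZIK")}
    out["unclassified"] = counts.get("unclassified", 0)
    return out


# EMBOSS-style pKa values used by the isoelectric-point solver.  Recorded
# verbatim so pI results are reproducible bit-for-bit.
PKA_TABLE: Mapping[str, float] = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

_POSITIVE = ("H", "K", "R")
_NEGATIVE = ("C", "D", "E", "Y")


def net_charge(sequence: str, ph: float, pka: Mapping[str, float] = PKA_TABLE) -> float:
    """Net protein charge at a given pH from Henderson-Hasselbalch terms."""
    counts = Counter(sequence)
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - ph))
    for aa in _POSITIVE:
        if counts[aa]:
            charge += counts[aa] / (1.0 + 10.0 ** (ph - pka[aa]))
    for aa in _NEGATIVE:
        if counts[aa]:
            charge -= counts[aa] / (1.0 + 10.0 ** (pka[aa] - ph))
    return charge


def isoelectric_point(
    sequence: str,
    pka: Mapping[str, float] = PKA_TABLE,
    tolerance: float = 1e-4,
) -> float:
    """pH at which the net charge vanishes, by bisection to |charge| < tolerance.

    Net charge is strictly decreasing in pH, so bisection on [0, 14]
    converges unconditionally.
    """
    lo, hi = 0.0, 14.0
    ph = 7.0
    for _ in range(200):
        ph = 0.5 * (lo + hi)
        q = net_charge(sequence, ph, pka)
        if abs(q) < tolerance:
            break
        if q > 0:
            lo = ph
        else:
            hi = ph
    return ph


def protein_stats(record: ProteinRecord) -> ProteinStats:
    """Average molecular weight (Da) and isoelectric point of a protein."""
    mw = molecular_weight(record.sequence, seq_type="protein", monoisotopic=False)
    return ProteinStats(
        protein_id=record.id,
        molecular_weight=mw,
        isoelectric_point=isoelectric_point(record.sequence),
    )
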