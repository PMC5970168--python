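"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates the statistical structure the analysis assumes and
records the planted truth so recovery can be tested exactly:

* proteins: uniform random residues with exactly one planted subfamily
  signature, rejection-sampled so no spurious signature occurs elsewhere;
* codon pairs: a stop-free random codon sequence plus exact requested
  counts of verified synonymous / nonsynonymous single-nucleotide changes
  at distinct codons;
* FPKM matrices: log-normal draws over eight cotton tissues;
* qRT-PCR time courses: paired treated/mock arms at ten sampling times
  (0-24 h), reference-gene Ct constant up to noise, the planted fold
  applied fully (in -log2 Ct shift) at its peak time and at half strength
  at the two adjacent times, Gaussian Ct noise per replicate.

All randomness flows from one explicit seed; each generator draws from a
deterministically derived sub-stream, so identical configs give
byte-identical outputs regardless of call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cotton_mapk.classify import (
    STANDARD_RESIDUES,
    SUBFAMILY_SIGNATURES,
    _SIGNATURE_RE,
    ProteinRecord,
    classify_subfamily,
)
from cotton_mapk.expression import CT_COLUMNS, DEFAULT_TISSUES
from cotton_mapk.kaks import CODON_TO_AA, NUCLEOTIDES, STOP_CODONS, CodonAlignment

DEFAULT_TIMEPOINTS = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 24.0)

_MAX_RETRIES = 1000

# fixed sub-stream ids so each generator is independent of call order
_STREAM_PROTEINS = 1
_STREAM_CODONS = 2
_STREAM_FPKM = 3
_STREAM_QPCR = 4


@dataclass(frozen=True)
class PlantedEffect:
    """A planted qPCR induction effect: E/C fold change peaking at one time."""

    fold: float
    peak_time_h: float = 12.0

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("planted fold changes must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_per_subfamily: int = 5
    protein_length: int = 120
    codon_pair_spec: tuple[tuple[int, int, int], ...] = ((100, 3, 1),)
    n_tissues: int = 8
    qpcr_noise_sd: float = 0.1  # Ct units
    qpcr_replicates: int = 3
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS

    def __post_init__(self) -> None:
        if self.n_per_subfamily < 0:
            raise ValueError("n_per_subfamily must be >= 0")
        if self.n_tissues < 2:
            raise ValueError("n_tissues must be >= 2")
        if self.qpcr_replicates < 2:
            raise ValueError("qpcr_replicates must be >= 2")
        if self.qpcr_noise_sd < 0:
            raise ValueError("qpcr_noise_sd must be >= 0")
        if any(a >= b for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        min_len = max(len(p) for p in SUBFAMILY_SIGNATURES.values()) + 2
        if self.protein_length < min_len:
            raise ValueError(f"protein_length must be >= {min_len}")
        for n_codons, n_syn, n_nonsyn in self.codon_pair_spec:
            if n_syn + n_nonsyn > n_codons:
                raise ValueError("requested changes exceed available codons")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


@dataclass
class PlantedTruth:
    """Ground truth of a simulation run, keyed by generated record ids."""

    seed: int
    protein_labels: dict[str, str] = field(default_factory=dict)
    protein_positions: dict[str, int] = field(default_factory=dict)  # 1-based
    codon_truth: dict[str, tuple[int, int]] = field(default_factory=dict)
    induction_design: dict[tuple[str, str], PlantedEffect] = field(default_factory=dict)


class GenerationError(RuntimeError):
    """Bounded rejection sampling failed to satisfy a generator constraint."""


# ---------------------------------------------------------------------------
# proteins
# ---------------------------------------------------------------------------

def _instantiate_signature(subfamily: str, rng: np.random.Generator) -> str:
    chars = []
    for cls in SUBFAMILY_SIGNATURES[subfamily]:
        options = STANDARD_RESIDUES if cls is None else "".join(sorted(cls))
        chars.append(options[rng.integers(len(options))])
    return "".join(chars)


def _matches_only_at(sequence: str, plant_start: int) -> bool:
    for regex in _SIGNATURE_RE.values():
        for m in regex.finditer(sequence):
            if m.start() != plant_start:
                return False
    return True


def gen_proteins(config: SimulationConfig) -> tuple[list[ProteinRecord], PlantedTruth]:
    """Generate proteins with exactly one planted subfamily signature each.

    Background residues are uniform over the 20 standard amino acids;
    sequences are rejection-sampled until no signature of any subfamily
    matches anywhere except at the planted position.  Raises
    ``GenerationError`` if a sequence cannot be produced in 1000 attempts.
    """
    rng = config.rng(_STREAM_PROTEINS)
    truth = PlantedTruth(seed=config.seed)
    records: list[ProteinRecord] = []
    for subfamily in SUBFAMILY_SIGNATURES:  # MEKK, ZIK, Raf
        for i in range(config.n_per_subfamily):
            for _ in range(_MAX_RETRIES):
                signature = _instantiate_signature(subfamily, rng)
                max_start = config.protein_length - len(signature)
                start = int(rng.integers(max_start + 1))
                background = rng.choice(list(STANDARD_RESIDUES), size=config.protein_length)
                seq = "".join(background)
                seq = seq[:start] + signature + seq[start + len(signature):]
                # the position check alone is not enough: a ZIK instance
                # ending ...V also satisfies the MEKK pattern at the same
                # start, so the planted subfamily must win under precedence
                record = ProteinRecord(id="tmp", name="tmp", sequence=seq)
                if _matches_only_at(seq, start) and classify_subfamily(record).subfamily == subfamily:
                    break
            else:
                raise GenerationError(
                    f"could not generate a clean {subfamily} sequence in {_MAX_RETRIES} tries"
                )
            pid = f"SYN_{subfamily}_{i + 1}"
            records.append(ProteinRecord(id=pid, name=pid, sequence=seq))
            truth.protein_labels[pid] = subfamily
            truth.protein_positions[pid] = start + 1
    return records, truth


# ---------------------------------------------------------------------------
# codon pairs
# ---------------------------------------------------------------------------

def _random_stop_free_codons(n_codons: int, rng: np.random.Generator) -> list[str]:
    codons = []
    non_stop = sorted(CODON_TO_AA)
    for _ in range(n_codons):
        codons.append(non_stop[rng.integers(len(non_stop))])
    return codons


def _single_nt_variants(codon: str, synonymous: bool) -> list[str]:
    """Stop-free single-nucleotide neighbours, split by synonymy."""
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            if (CODON_TO_AA[mutant] == CODON_TO_AA[codon]) == synonymous:
                out.append(mutant)
    return out


def gen_codon_pairs(config: SimulationConfig) -> tuple[list[CodonAlignment], PlantedTruth]:
    """Generate codon-aligned pairs with exact planted change counts.

    For each (n_codons, n_syn, n_nonsyn) spec a stop-free random codon
    sequence is copied and exactly the requested numbers of verified
    synonymous and nonsynonymous single-nucleotide changes are applied at
    distinct codons (so no codon is hit twice and the planted counts are
    recoverable exactly).  Unsatisfiable draws are retried up to a bound.
    """
    rng = config.rng(_STREAM_CODONS)
    truth = PlantedTruth(seed=config.seed)
    pairs: list[CodonAlignment] = []
    for idx, (n_codons, n_syn, n_nonsyn) in enumerate(config.codon_pair_spec):
        for _ in range(_MAX_RETRIES):
            codons_a = _random_stop_free_codons(n_codons, rng)
            order = rng.permutation(n_codons)
            codons_b = list(codons_a)
            placed_syn = placed_nonsyn = 0
            for ci in order:
                if placed_syn < n_syn:
                    options = _single_nt_variants(codons_a[ci], synonymous=True)
                    if options:
                        codons_b[ci] = options[rng.integers(len(options))]
                        placed_syn += 1
                        continue
                if placed_nonsyn < n_nonsyn:
                    options = _single_nt_variants(codons_a[ci], synonymous=False)
                    if options:
                        codons_b[ci] = options[rng.integers(len(options))]
                        placed_nonsyn += 1
                if placed_syn == n_syn and placed_nonsyn == n_nonsyn:
                    break
            if placed_syn == n_syn and placed_nonsyn == n_nonsyn:
                break
        else:
            raise GenerationError(
                f"codon pair spec {(n_codons, n_syn, n_nonsyn)} unsatisfiable "
                f"in {_MAX_RETRIES} tries"
            )
        pair_id = f"SYNPAIR_{idx + 1}"
        pairs.append(
            CodonAlignment(pair_id=pair_id, seq_a="".join(codons_a), seq_b="".join(codons_b))
        )
        truth.codon_truth[pair_id] = (n_syn, n_nonsyn)
    return pairs, truth


# ---------------------------------------------------------------------------
# FPKM matrices
# ---------------------------------------------------------------------------

def gen_fpkm(config: SimulationConfig, n_genes: int) -> pd.DataFrame:
    """Log-normal FPKM matrix (genes x tissues), nonnegative, seed-determined.

    Gene base expression spans several orders of magnitude (log-mean drawn
    from N(2, 1.5) on the natural-log scale) with tissue-to-tissue scatter
    of sigma = 1, mimicking the skew of real FPKM tables.
    """
    rng = config.rng(_STREAM_FPKM)
    if config.n_tissues == len(DEFAULT_TISSUES):
        tissues = list(DEFAULT_TISSUES)
    else:
        tissues = [f"tissue_{i + 1}" for i in range(config.n_tissues)]
    base = rng.normal(2.0, 1.5, size=n_genes)
    values = np.exp(base[:, None] + rng.normal(0.0, 1.0, size=(n_genes, config.n_tissues)))
    genes = [f"GENE_{i + 1}" for i in range(n_genes)]
    df = pd.DataFrame(values, index=genes, columns=tissues)
    df.attrs["seed"] = config.seed
    return df


# ---------------------------------------------------------------------------
# qPCR time courses
# ---------------------------------------------------------------------------

def _log2_shift(effect: PlantedEffect, time_h: float, timepoints: Sequence[float]) -> float:
    """Planted -log2(fold) Ct shift at a time point: full at the peak, half at
    the immediately adjacent sampling times, zero elsewhere."""
    if effect.fold == 1.0:
        return 0.0
    times = list(timepoints)
    if effect.peak_time_h not in times:
        raise ValueError(f"peak time {effect.peak_time_h} h not in sampled timepoints")
    peak_idx = times.index(effect.peak_time_h)
    idx = times.index(time_h)
    if idx == peak_idx:
        return -math.log2(effect.fold)
    if abs(idx - peak_idx) == 1:
        return -math.log2(effect.fold) / 2.0
    return 0.0


def gen_qpcr(
    design: Mapping[tuple[str, str], PlantedEffect | float],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Simulate a tidy replicate Ct table for a planted induction design.

    ``design`` maps (gene, treatment) to a planted effect (a bare float is
    taken as a fold peaking at 12 h).  Reference-gene Ct is constant (15
    cycles) up to noise; target base Ct is gene-specific (18-25 cycles).
    Treated-arm target Ct is shifted by the planted -log2(fold) profile;
    mock arms are simulated at every time point.  Gaussian noise with
    sd = ``config.qpcr_noise_sd`` is added independently to every measured
    Ct value.
    """
    rng = config.rng(_STREAM_QPCR)
    effects: dict[tuple[str, str], PlantedEffect] = {}
    for key, value in design.items():
        effects[key] = value if isinstance(value, PlantedEffect) else PlantedEffect(float(value))
    genes = sorted({g for g, _ in effects})
    base_ct = {g: 18.0 + 7.0 * rng.random() for g in genes}
    ref_ct = 15.0
    rows = []
    for (gene, treatment), effect in sorted(effects.items()):
        for time_h in config.timepoints:
            shift = _log2_shift(effect, time_h, config.timepoints)
            for arm, arm_shift in (("treated", shift), ("mock", 0.0)):
                for rep in range(1, config.qpcr_replicates + 1):
                    noise = rng.normal(0.0, config.qpcr_noise_sd, size=2)
                    rows.append(
                        (
                            gene,
                            treatment,
                            time_h,
                            arm,
                            rep,
                            base_ct[gene] + arm_shift + noise[0],
                            ref_ct + noise[1],
                        )
                    )
    df = pd.DataFrame(rows, columns=list(CT_COLUMNS))
    df.attrs["seed"] = config.seed
    return df


def qpcr_truth(
    design: Mapping[tuple[str, str], PlantedEffect | float], seed: int
) -> PlantedTruth:
    """Wrap a qPCR design into a ``PlantedTruth`` record."""
    truth = PlantedTruth(seed=seed)
    for key, value in design.items():
        truth.induction_design[key] = (
            value if isinstance(value, PlantedEffect) else PlantedEffect(float(value))
        )
    return truth
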