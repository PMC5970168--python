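"""Expression profiling: z-scores, Livak relative expression, induction calls.

Three layers of expression evidence feed the cascade analysis:

1. Tissue FPKM matrices are row z-scored, z = (x - mean) / sd, with the
   sample (n-1) standard deviation, so profiles are comparable across
   genes of very different absolute expression.
2. qRT-PCR fold changes use the Livak 2^-ddCt method against a reference
   gene (histone3 by convention): dCt = Ct_target - Ct_reference per
   replicate, ddCt = mean dCt(treated) - mean dCt(mock), fold = 2^-ddCt.
3. A gene is called induced ("up") under a treatment when some time point
   shows fold >= 2 with a two-sided pooled-variance Student's t-test on
   replicate dCt values at P < 0.05 (significance upgraded to P < 0.01
   when the peak time point clears 0.01); significantly reduced ("down",
   the paper-style "D" code) when some time point shows fold <= 1/2 at
   P < 0.05.  No multiple-testing correction is applied (flagged in the
   summary output as a caveat).

Time courses are held in a tidy DataFrame with columns
``gene, treatment, time_h, arm ("treated"/"mock"), replicate, ct_target,
ct_reference``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TREATMENTS = ("JA", "H2O2", "ABA", "SA", "NaCl", "PEG", "cold_4C", "heat_37C", "wounding")
SIGNAL_TREATMENTS = frozenset({"JA", "H2O2", "ABA", "SA"})
ABIOTIC_TREATMENTS = frozenset({"NaCl", "PEG", "cold_4C", "heat_37C", "wounding"})

DEFAULT_TISSUES = (
    "root",
    "stem",
    "leaf",
    "petal",
    "anther",
    "ovule_0dpa",
    "fiber_10dpa",
    "fiber_20dpa",
)

CT_COLUMNS = ("gene", "treatment", "time_h", "arm", "replicate", "ct_target", "ct_reference")


class ZScoreResult(NamedTuple):
    values: pd.DataFrame
    degenerate_genes: tuple[str, ...]  # constant rows, mapped to all-zeros


@dataclass(frozen=True)
class InductionCall:
    gene: str
    treatment: str
    status: str  # up | down | none
    significance: str  # p<0.01 | p<0.05 | ns
    max_fold_change: float  # E/C at the peak time point
    peak_time_h: float | None  # absent when status == none


def zscore_normalize(matrix: pd.DataFrame) -> ZScoreResult:
    """Row z-score a gene x tissue FPKM matrix.

    Uses the sample standard deviation (n-1 divisor).  Constant rows are
    mapped to all-zeros and reported in ``degenerate_genes``.  Requires at
    least two tissue columns and no missing cells.
    """
    if matrix.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 tissues")
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing cells")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("FPKM values must be nonnegative")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    degenerate = sd[:, 0] == 0.0
    safe_sd = np.where(degenerate[:, None], 1.0, sd)
    z = (values - mean) / safe_sd
    z[degenerate, :] = 0.0
    degenerate_genes = tuple(matrix.index[degenerate].astype(str))
    if degenerate_genes:
        logger.warning("constant expression rows mapped to zeros: %s", degenerate_genes)
    return ZScoreResult(
        values=pd.DataFrame(z, index=matrix.index, columns=matrix.columns),
        degenerate_genes=degenerate_genes,
    )


def _delta_ct(ct_target: Sequence[float], ct_reference: Sequence[float]) -> np.ndarray:
    target = np.asarray(ct_target, dtype=float)
    reference = np.asarray(ct_reference, dtype=float)
    if target.shape != reference.shape:
        raise ValueError("target and reference Ct replicate counts differ")
    if np.isnan(reference).any():
        raise ValueError("missing reference Ct")
    if np.isnan(target).any():
        raise ValueError("missing target Ct")
    return target - reference


def relative_expression(
    treated_target: Sequence[float],
    treated_reference: Sequence[float],
    mock_target: Sequence[float],
    mock_reference: Sequence[float],
) -> float:
    """Livak 2^-ddCt fold change (E/C) of one treated cell vs its mock cell."""
    d_treated = _delta_ct(treated_target, treated_reference)
    d_mock = _delta_ct(mock_target, mock_reference)
    ddct = d_treated.mean() - d_mock.mean()
    return float(2.0 ** (-ddct))


def _course_cells(course: pd.DataFrame) -> dict[float, dict[str, pd.DataFrame]]:
    cells: dict[float, dict[str, pd.DataFrame]] = {}
    for (time_h, arm), cell in course.groupby(["time_h", "arm"], sort=True):
        cells.setdefault(float(time_h), {})[str(arm)] = cell
    return cells


def call_induction(
    course: pd.DataFrame,
    alpha1: float = 0.05,
    alpha2: float = 0.01,
    fold_threshold: float = 2.0,
) -> InductionCall:
    """Call induction status for one gene under one treatment.

    ``course`` is the tidy Ct sub-table for a single (gene, treatment):
    both arms at every time point, >= 2 replicates per cell.  Per time
    point the Livak fold change and a two-sided pooled-variance t-test on
    replicate dCt values (treated vs mock) are computed; see module
    docstring for the decision rule.  When both the up and the down rule
    fire at different time points, up wins (reductions are reported only
    for genes never significantly induced).
    """
    missing = [c for c in CT_COLUMNS if c not in course.columns and c not in ("gene", "treatment")]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    genes = course["gene"].unique() if "gene" in course.columns else ["?"]
    treatments = course["treatment"].unique() if "treatment" in course.columns else ["?"]
    if len(genes) != 1 or len(treatments) != 1:
        raise ValueError("call_induction expects exactly one (gene, treatment)")
    gene, treatment = str(genes[0]), str(treatments[0])

    rows = []  # (time_h, fold, p)
    for time_h, arms in sorted(_course_cells(course).items()):
        if "treated" not in arms or "mock" not in arms:
            raise ValueError(f"{gene}/{treatment}: time {time_h} h lacks a treated or mock arm")
        treated, mock = arms["treated"], arms["mock"]
        if len(treated) < 2 or len(mock) < 2:
            raise ValueError(f"{gene}/{treatment}: <2 replicates at {time_h} h")
        d_treated = _delta_ct(treated["ct_target"], treated["ct_reference"])
        d_mock = _delta_ct(mock["ct_target"], mock["ct_reference"])
        fold = float(2.0 ** (-(d_treated.mean() - d_mock.mean())))
        if np.allclose(d_treated, d_treated[0]) and np.allclose(d_mock, d_mock[0]) and np.isclose(
            d_treated[0], d_mock[0]
        ):
            p = 1.0  # identical, zero-variance cells: no evidence of change
        else:
            p = float(stats.ttest_ind(d_treated, d_mock, equal_var=True).pvalue)
            if math.isnan(p):
                p = 1.0
        rows.append((float(time_h), fold, p))

    up_hits = [r for r in rows if r[1] >= fold_threshold and r[2] < alpha1]
    down_hits = [r for r in rows if r[1] <= 1.0 / fold_threshold and r[2] < alpha1]
    if up_hits:
        # peak = maximal fold among qualifying time points, earliest on ties
        peak = max(up_hits, key=lambda r: (r[1], -r[0]))
        significance = "p<0.01" if peak[2] < alpha2 else "p<0.05"
        return InductionCall(gene, treatment, "up", significance, peak[1], peak[0])
    if down_hits:
        peak = min(down_hits, key=lambda r: (r[1], r[0]))
        significance = "p<0.01" if peak[2] < alpha2 else "p<0.05"
        return InductionCall(gene, treatment, "down", significance, peak[1], peak[0])
    return InductionCall(gene, treatment, "none", "ns", max(r[1] for r in rows), None)


def call_induction_table(
    ct_table: pd.DataFrame,
    alpha1: float = 0.05,
    alpha2: float = 0.01,
    fold_threshold: float = 2.0,
) -> list[InductionCall]:
    """Run ``call_induction`` over every (gene, treatment) in a tidy Ct table."""
    calls = []
    for (_, _), course in ct_table.groupby(["gene", "treatment"], sort=True):
        calls.append(call_induction(course, alpha1, alpha2, fold_threshold))
    return calls


STATUS_CODES = {
    ("up", "p<0.01"): "**",
    ("up", "p<0.05"): "*",
    ("down", "p<0.01"): "D",
    ("down", "p<0.05"): "D",
    ("none", "ns"): "-",
}


class InductionMatrix(NamedTuple):
    table: pd.DataFrame  # gene x treatment status codes (** / * / D / -)
    per_treatment_up: dict[str, int]
    per_gene_up: dict[str, int]
    caveat: str


def induction_matrix(calls: Iterable[InductionCall]) -> InductionMatrix:
    """Summarise induction calls as a status table plus up-regulation counts.

    Raises ``ValueError`` on duplicate (gene, treatment) calls.  "Induced"
    means status up at any time point; down-regulation never counts.
    """
    calls = list(calls)
    seen: set[tuple[str, str]] = set()
    for call in calls:
        key = (call.gene, call.treatment)
        if key in seen:
            raise ValueError(f"duplicate induction call for {key}")
        seen.add(key)
    genes = sorted({c.gene for c in calls})
    treatments = [t for t in TREATMENTS if any(c.treatment == t for c in calls)]
    treatments += sorted({c.treatment for c in calls} - set(TREATMENTS))
    table = pd.DataFrame("-", index=genes, columns=treatments)
    for call in calls:
        table.loc[call.gene, call.treatment] = STATUS_CODES[(call.status, call.significance)]
    per_treatment_up = {
        t: sum(1 for c in calls if c.treatment == t and c.status == "up") for t in treatments
    }
    per_gene_up = {
        g: sum(1 for c in calls if c.gene == g and c.status == "up") for g in genes
    }
    return InductionMatrix(
        table=table,
        per_treatment_up=per_treatment_up,
        per_gene_up=per_gene_up,
        caveat="per-time-point t-tests are uncorrected for multiple testing",
    )
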