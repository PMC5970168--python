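"""Readers and writers for the toolkit's file formats.

FASTA goes through Biopython; tables are tab-separated and read/written
with pandas.  Output writes are atomic (temp file + rename) so an
interrupted run never leaves a truncated table behind.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from cotton_mapk.cascade import CascadeModule, InteractionEdge
from cotton_mapk.classify import ProteinRecord, ProteinStats, SubfamilyCall
from cotton_mapk.expression import CT_COLUMNS, InductionCall
from cotton_mapk.kaks import CodonAlignment, KaKsResult


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_table(frame: pd.DataFrame, path: str | os.PathLike, header_comment: str = "") -> None:
    text = frame.to_csv(sep="\t", index=False)
    if header_comment:
        text = "".join(f"# {line}\n" for line in header_comment.splitlines()) + text
    atomic_write_text(path, text)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_protein_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read proteins; non-standard residues are rejected with their position."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(
                ProteinRecord(id=rec.id, name=rec.id, sequence=str(rec.seq).upper())
            )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from None
    return records


def write_protein_fasta(records: Iterable[ProteinRecord], path: str | os.PathLike) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        SeqIO.write(seqs, handle, "fasta")


def read_codon_pairs_fasta(path: str | os.PathLike) -> list[CodonAlignment]:
    """Read codon-aligned pairs: two consecutive records per pair."""
    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) % 2 != 0:
        raise ValueError(f"{path}: odd number of records ({len(recs)}); expected pairs")
    pairs = []
    for a, b in zip(recs[::2], recs[1::2]):
        pairs.append(
            CodonAlignment(pair_id=f"{a.id}|{b.id}", seq_a=str(a.seq), seq_b=str(b.seq))
        )
    return pairs


def write_codon_pairs_fasta(pairs: Iterable[CodonAlignment], path: str | os.PathLike) -> None:
    seqs = []
    for pair in pairs:
        seqs.append(SeqRecord(Seq(pair.seq_a), id=f"{pair.pair_id}_a", description=""))
        seqs.append(SeqRecord(Seq(pair.seq_b), id=f"{pair.pair_id}_b", description=""))
    with open(path, "w") as handle:
        SeqIO.write(seqs, handle, "fasta")


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_fpkm_table(path: str | os.PathLike) -> pd.DataFrame:
    """Gene x tissue FPKM table: first column gene id, rest tissue columns."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    frame = frame.set_index(frame.columns[0])
    for gene, row in frame.iterrows():
        for tissue, value in row.items():
            if pd.isna(value):
                raise ValueError(f"{path}: missing FPKM at ({gene}, {tissue})")
            if value < 0:
                raise ValueError(f"{path}: negative FPKM at ({gene}, {tissue}): {value}")
    return frame


def read_ct_table(path: str | os.PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in CT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: Ct table missing columns {missing}")
    bad_arms = set(frame["arm"].unique()) - {"treated", "mock"}
    if bad_arms:
        raise ValueError(f"{path}: unknown arm values {sorted(bad_arms)}")
    return frame


def write_ct_table(frame: pd.DataFrame, path: str | os.PathLike, header_comment: str = "") -> None:
    atomic_write_table(frame[list(CT_COLUMNS)], path, header_comment)


def read_edge_list(path: str | os.PathLike) -> list[InteractionEdge]:
    """TSV edge list with columns upstream, downstream, tier[, source]."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    for col in ("upstream", "downstream", "tier"):
        if col not in frame.columns:
            raise ValueError(f"{path}: edge list missing column {col!r}")
    edges = []
    for i, row in frame.iterrows():
        try:
            edges.append(
                InteractionEdge(
                    upstream=str(row["upstream"]),
                    downstream=str(row["downstream"]),
                    tier=str(row["tier"]),
                    source=str(row.get("source", "")),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from None
    return edges


def write_edge_list(edges: Iterable[InteractionEdge], path: str | os.PathLike) -> None:
    frame = pd.DataFrame(
        [(e.upstream, e.downstream, e.tier, e.source) for e in edges],
        columns=["upstream", "downstream", "tier", "source"],
    )
    atomic_write_table(frame, path)


def classification_table(
    calls: Sequence[SubfamilyCall], stats: Sequence[ProteinStats] | None = None
) -> pd.DataFrame:
    by_id = {s.protein_id: s for s in stats or ()}
    rows = []
    for call in calls:
        stat = by_id.get(call.protein_id)
        rows.append(
            {
                "id": call.protein_id,
                "subfamily": call.subfamily,
                "match_start": call.match_start if call.match_start is not None else "",
                "matched_text": call.matched_text or "",
                "mw_da": round(stat.molecular_weight, 2) if stat else "",
                "pi": round(stat.isoelectric_point, 2) if stat else "",
            }
        )
    return pd.DataFrame(rows)


def kaks_table(results: Sequence[KaKsResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair_id": r.pair_id,
                "S": r.S,
                "N": r.N,
                "Sd": r.Sd,
                "Nd": r.Nd,
                "pS": r.pS,
                "pN": r.pN,
                "Ka": r.Ka,
                "Ks": r.Ks,
                "ratio": r.ratio,
                "selection": r.selection,
            }
            for r in results
        ]
    )


def induction_table(calls: Sequence[InductionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "treatment": c.treatment,
                "status": c.status,
                "significance": c.significance,
                "max_fold_change": c.max_fold_change,
                "peak_time_h": c.peak_time_h if c.peak_time_h is not None else "",
            }
            for c in calls
        ]
    )


def module_table(modules: Sequence[CascadeModule]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "kkk": m.kkk,
                "kk": m.kk,
                "k": m.k,
                "shared_signal": ",".join(sorted(m.shared_signal_responses)),
                "shared_abiotic": ",".join(sorted(m.shared_abiotic_responses)),
                "profiled_members": ",".join(m.profiled_members),
                "low_support": m.low_support,
            }
            for m in modules
        ]
    )
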