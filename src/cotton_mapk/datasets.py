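"""Bundled cotton MAPK reference data.

Ships the published yeast two-hybrid interaction edge lists (18
MAPKKK->MKK pairs, 16 MKK->MAPK pairs), the per-treatment lists of
qRT-PCR-induced MAPKKK genes, the low-expression exclusion set used for
cascade assembly, and fixture stress-response profiles for the MAPK tier.

Two of the induced-gene lists (ABA and SA) are flagged ``ambiguous``: the
source text's gene enumerations are internally inconsistent for those
treatments, so they are shipped for completeness but kept out of
quantitative checks.

Every data file is verified against a recorded SHA-256 checksum at load
time; a mismatch raises ``CorruptedDataError``.
"""

from __future__ import annotations

import hashlib
import json
from functools import lru_cache
from importlib import resources
from typing import NamedTuple

import pandas as pd

from cotton_mapk.cascade import InteractionEdge, ResponseProfile

_DATA_DIR = "data"


class CorruptedDataError(RuntimeError):
    """A bundled data file does not match its recorded checksum."""


class InducedGeneList(NamedTuple):
    treatment: str
    genes: tuple[str, ...]
    ambiguous: bool
    note: str = ""


def _data_bytes(filename: str, verify: bool = True) -> bytes:
    payload = resources.files("cotton_mapk").joinpath(_DATA_DIR, filename).read_bytes()
    if verify:
        recorded = _checksums().get(filename)
        if recorded is None:
            raise CorruptedDataError(f"no recorded checksum for {filename}")
        digest = hashlib.sha256(payload).hexdigest()
        if digest != recorded:
            raise CorruptedDataError(
                f"{filename}: checksum mismatch (expected {recorded}, got {digest})"
            )
    return payload


@lru_cache(maxsize=1)
def _checksums() -> dict[str, str]:
    return json.loads(_data_bytes("checksums.json", verify=False))


@lru_cache(maxsize=1)
def load_interactions() -> tuple[InteractionEdge, ...]:
    """The 18 MAPKKK->MKK and 16 MKK->MAPK yeast two-hybrid edges."""
    from io import BytesIO

    table = pd.read_csv(BytesIO(_data_bytes("interactions.tsv")), sep="\t")
    return tuple(
        InteractionEdge(
            upstream=row.upstream,
            downstream=row.downstream,
            tier=row.tier,
            source=row.source,
        )
        for row in table.itertuples()
    )


@lru_cache(maxsize=1)
def load_induced_gene_lists() -> dict[str, InducedGeneList]:
    """Per-treatment lists of MAPKKK genes called induced by qRT-PCR."""
    raw = json.loads(_data_bytes("induced_genes.json"))
    return {
        treatment: InducedGeneList(
            treatment=treatment,
            genes=tuple(entry["genes"]),
            ambiguous=bool(entry["ambiguous"]),
            note=entry.get("note", ""),
        )
        for treatment, entry in raw.items()
    }


@lru_cache(maxsize=1)
def load_exclusions() -> frozenset[str]:
    """Genes excluded from cascade assembly for low expression."""
    return frozenset(json.loads(_data_bytes("exclusions.json"))["exclusions"])


@lru_cache(maxsize=1)
def load_response_profiles() -> tuple[ResponseProfile, ...]:
    """Fixture stress-response profiles for cascade annotation."""
    raw = json.loads(_data_bytes("response_profiles.json"))["profiles"]
    return tuple(
        ResponseProfile(
            gene=gene,
            induced_treatments=frozenset(entry["induced"]),
            provenance=entry["provenance"],
        )
        for gene, entry in raw.items()
    )


def interacting_mapkkks() -> tuple[str, ...]:
    """The 14 MAPKKKs with at least one MKK interaction partner."""
    names = {e.upstream for e in load_interactions() if e.tier == "KKK-KK"}
    return tuple(sorted(names))


def investigated_genes() -> tuple[str, ...]:
    """The 12-gene qRT-PCR panel: interacting MAPKKKs minus the two
    low-expression genes never called induced."""
    dropped = {"MEKK19", "RAF17_2"}
    return tuple(n for n in interacting_mapkkks() if n not in dropped)


def checksums() -> dict[str, str]:
    """Recorded SHA-256 checksums of the bundled data files."""
    return dict(_checksums())
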