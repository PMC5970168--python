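"""End-to-end pipeline: classify -> kaks -> zscore -> induction -> assemble.

Each stage is optional: a stage runs iff its input is configured (the
assembly stage falls back to the bundled interaction/exclusion/profile
fixtures when no files are given).  All outputs are written atomically
into one output directory, tables carry a provenance header (config hash
and seed), and a ``RunReport`` records per-stage record counts and
warnings.  Identical config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import cotton_mapk
from cotton_mapk import datasets
from cotton_mapk import io as cmio
from cotton_mapk.cascade import (
    annotate_shared_responses,
    build_graph,
    enumerate_modules,
    graph_summary,
    summarize_interactions,
)
from cotton_mapk.classify import classify_subfamily, protein_stats
from cotton_mapk.expression import call_induction_table, induction_matrix, zscore_normalize
from cotton_mapk.kaks import compute_kaks

logger = logging.getLogger(__name__)

STAGES = ("classify", "kaks", "zscore", "induction", "assemble")


@dataclass(frozen=True)
class PipelineConfig:
    output_dir: str
    seed: int = 0
    proteins_fasta: str | None = None
    codon_pairs_fasta: str | None = None
    fpkm_tsv: str | None = None
    ct_tsv: str | None = None
    edges_tsv: str | None = None  # None => bundled interaction fixtures
    profiles_json: str | None = None  # None => bundled response profiles
    exclusions: tuple[str, ...] | None = None  # None => bundled exclusion set
    fold_threshold: float = 2.0
    alpha1: float = 0.05
    alpha2: float = 0.01
    run_assembly: bool = True

    def __post_init__(self) -> None:
        if self.fold_threshold <= 0:
            raise ValueError("fold_threshold must be positive")
        if not (0 < self.alpha2 <= self.alpha1 < 1):
            raise ValueError("require 0 < alpha2 <= alpha1 < 1")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(raw.get("exclusions"), list):
            raw["exclusions"] = tuple(raw["exclusions"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config: dict
    version: str
    config_hash: str
    fixture_checksums: dict[str, str]
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Schema-check every configured input file, collecting located errors."""
    report = ValidationReport()
    checks = (
        ("proteins_fasta", cmio.read_protein_fasta),
        ("codon_pairs_fasta", cmio.read_codon_pairs_fasta),
        ("fpkm_tsv", cmio.read_fpkm_table),
        ("ct_tsv", cmio.read_ct_table),
        ("edges_tsv", cmio.read_edge_list),
    )
    for attr, reader in checks:
        path = getattr(config, attr)
        if path is None:
            continue
        if not Path(path).exists():
            report.errors.append(f"{attr}: file not found: {path}")
            continue
        try:
            reader(path)
        except ValueError as exc:
            report.errors.append(f"{attr}: {exc}")
    return report


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run all configured stages in order, writing outputs and a run report."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"cotton-mapk {cotton_mapk.__version__} config={config.config_hash()} seed={config.seed}"
    report = RunReport(
        config=dataclasses.asdict(config),
        version=cotton_mapk.__version__,
        config_hash=config.config_hash(),
        fixture_checksums=datasets.checksums(),
    )

    def record(stage: str, status: str, **counts) -> None:
        report.stages[stage] = {"status": status, **counts}

    # classify
    if config.proteins_fasta:
        try:
            records = cmio.read_protein_fasta(config.proteins_fasta)
            calls = [classify_subfamily(r) for r in records]
            stats = [protein_stats(r) for r in records]
            table = cmio.classification_table(calls, stats)
            cmio.atomic_write_table(table, outdir / "classification.tsv", header)
            record("classify", "ran", n_in=len(records), n_out=len(table))
        except Exception as exc:
            raise StageError("classify", exc) from exc
    else:
        record("classify", "skipped")

    # kaks
    if config.codon_pairs_fasta:
        try:
            pairs = cmio.read_codon_pairs_fasta(config.codon_pairs_fasta)
            results = [compute_kaks(p) for p in pairs]
            cmio.atomic_write_table(cmio.kaks_table(results), outdir / "kaks.tsv", header)
            record("kaks", "ran", n_in=len(pairs), n_out=len(results))
        except Exception as exc:
            raise StageError("kaks", exc) from exc
    else:
        record("kaks", "skipped")

    # zscore
    if config.fpkm_tsv:
        try:
            fpkm = cmio.read_fpkm_table(config.fpkm_tsv)
            z = zscore_normalize(fpkm)
            for gene in z.degenerate_genes:
                report.warnings.append(f"zscore: constant expression row {gene}")
            out = z.values.reset_index().rename(columns={"index": "gene"})
            cmio.atomic_write_table(out, outdir / "zscores.tsv", header)
            record("zscore", "ran", n_in=len(fpkm), n_out=len(z.values))
        except Exception as exc:
            raise StageError("zscore", exc) from exc
    else:
        record("zscore", "skipped")

    # induction
    profiles = None
    if config.ct_tsv:
        try:
            ct = cmio.read_ct_table(config.ct_tsv)
            calls = call_induction_table(
                ct, config.alpha1, config.alpha2, config.fold_threshold
            )
            matrix = induction_matrix(calls)
            report.warnings.append(f"induction: {matrix.caveat}")
            cmio.atomic_write_table(
                cmio.induction_table(calls), outdir / "induction_calls.tsv", header
            )
            status = matrix.table.reset_index().rename(columns={"index": "gene"})
            cmio.atomic_write_table(status, outdir / "induction_matrix.tsv", header)
            (outdir / "induction_summary.json").write_text(
                json.dumps(
                    {
                        "per_treatment_up": matrix.per_treatment_up,
                        "per_gene_up": matrix.per_gene_up,
                        "caveat": matrix.caveat,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            from cotton_mapk.cascade import ResponseProfile

            profiles = [
                ResponseProfile(
                    gene=g,
                    induced_treatments=frozenset(
                        c.treatment for c in calls if c.gene == g and c.status == "up"
                    ),
                    provenance="computed",
                )
                for g in sorted({c.gene for c in calls})
            ]
            record("induction", "ran", n_in=len(ct), n_out=len(calls))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("induction", exc) from exc
    else:
        record("induction", "skipped")

    # assemble
    if config.run_assembly:
        try:
            edges = (
                cmio.read_edge_list(config.edges_tsv)
                if config.edges_tsv
                else list(datasets.load_interactions())
            )
            exclusions = (
                frozenset(config.exclusions)
                if config.exclusions is not None
                else datasets.load_exclusions()
            )
            if config.profiles_json:
                from cotton_mapk.cascade import ResponseProfile

                raw = json.loads(Path(config.profiles_json).read_text())["profiles"]
                fixture_profiles = [
                    ResponseProfile(g, frozenset(e["induced"]), e.get("provenance", "fixture"))
                    for g, e in raw.items()
                ]
            else:
                fixture_profiles = list(datasets.load_response_profiles())
            # computed MAPKKK profiles (from the induction stage) override fixtures
            merged = {p.gene: p for p in fixture_profiles}
            for p in profiles or ():
                merged[p.gene] = p
            graph = build_graph(edges)
            modules = annotate_shared_responses(
                enumerate_modules(graph, exclusions), merged.values()
            )
            summary = summarize_interactions(edges)
            gsum = graph_summary(graph)
            cmio.atomic_write_table(cmio.module_table(modules), outdir / "modules.tsv", header)
            cmio.write_edge_list(edges, outdir / "edges.tsv")
            (outdir / "assembly_summary.json").write_text(
                json.dumps(
                    {
                        "n_edges": summary.total,
                        "kkk_kk_by_subfamily": summary.by_subfamily,
                        "n_kkk": gsum.n_kkk,
                        "n_kk": gsum.n_kk,
                        "n_k": gsum.n_k,
                        "n_modules": len(modules),
                        "exclusions": sorted(exclusions),
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            record("assemble", "ran", n_in=len(edges), n_out=len(modules))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("assemble", exc) from exc
    else:
        record("assemble", "skipped")

    cmio.atomic_write_text(outdir / "run_report.json", report.to_json() + "\n")
    return report
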