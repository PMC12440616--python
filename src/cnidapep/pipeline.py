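"""Pipeline orchestration: prefilter -> scan -> homology -> expression -> cluster.

Each stage is independently skippable (downstream users intervene between
stages, e.g. for manual curation), every stage writes a reasons table, and
the final candidate table carries per-stage pass flags. Re-running with the
same config and seed reproduces all payload outputs byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import clustering, expression, homology, prefilter, scanner
from .errors import UsageError
from .io import (
    EvidenceTable,
    ExpressionProfile,
    PrecursorRecord,
    parse_evidence,
    read_expression,
    read_fasta,
    warn_orphans,
    write_table,
)

log = logging.getLogger("cnidapep")

CONFIG_VERSION = 1


@dataclass
class PipelineConfig:
    """Paths, stage toggles and per-stage parameter blocks."""

    fasta: str = ""
    out_dir: str = "cnidapep_out"
    seed: int = 0
    signal_evidence: Optional[str] = None
    tm_evidence: Optional[str] = None
    domain_evidence: Optional[str] = None
    alignment_hits: Optional[str] = None
    expression_matrix: Optional[str] = None
    cluster_annotation: Optional[str] = None
    run_prefilter: bool = True
    run_homology: bool = True
    run_expression: bool = True
    run_cluster: bool = True
    prefilter: prefilter.PrefilterConfig = field(default_factory=prefilter.PrefilterConfig)
    scanner: scanner.ScannerConfig = field(default_factory=scanner.ScannerConfig)
    homology: homology.HomologyConfig = field(default_factory=homology.HomologyConfig)
    expression: expression.ExpressionConfig = field(default_factory=expression.ExpressionConfig)
    cluster: clustering.ClusterConfig = field(default_factory=clustering.ClusterConfig)

    def validate_paths(self) -> None:
        if not self.fasta:
            raise UsageError("config must set a fasta path")
        paths = [
            self.fasta, self.signal_evidence, self.tm_evidence,
            self.domain_evidence, self.alignment_hits,
            self.expression_matrix, self.cluster_annotation,
        ]
        for p in paths:
            if p and not Path(p).exists():
                raise UsageError(f"input path does not exist: {p}")
        if self.run_expression and bool(self.expression_matrix) != bool(self.cluster_annotation):
            raise UsageError("expression filtering needs both matrix and cluster annotation")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        version = raw.pop("config_version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise UsageError(f"unsupported config_version {version}")
        nested = {
            "prefilter": prefilter.PrefilterConfig,
            "scanner": scanner.ScannerConfig,
            "homology": homology.HomologyConfig,
            "expression": expression.ExpressionConfig,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in nested:
                if "cleavage_motifs" in value:
                    value["cleavage_motifs"] = tuple(value["cleavage_motifs"])
                if "allow_keywords" in value:
                    value["allow_keywords"] = tuple(value["allow_keywords"])
                kwargs[key] = nested[key](**value)
            elif key == "cluster":
                layout = value.pop("layout", {})
                kwargs[key] = clustering.ClusterConfig(
                    layout=clustering.LayoutConfig(**layout), **value
                )
            else:
                kwargs[key] = value
        config = cls(**kwargs)
        if "seed" in raw:
            config.cluster.layout.seed = config.seed
        return config


@dataclass
class PipelineResult:
    """In-memory result of one pipeline run."""

    records: list[PrecursorRecord]
    prefilter_report: pd.DataFrame
    scan_results: list[scanner.ScanResult]
    homology_report: Optional[pd.DataFrame]
    expression_report: Optional[pd.DataFrame]
    graph: Optional[clustering.SimilarityGraph]
    candidates: pd.DataFrame  # per-record stage flags and scores
    stage_counts: dict[str, int]

    @property
    def final_ids(self) -> list[str]:
        return list(self.candidates.loc[self.candidates["final"] == 1, "id"])

    @property
    def peptides(self) -> pd.DataFrame:
        return scanner.peptide_table(self.scan_results)


def run_stages(
    records: list[PrecursorRecord],
    evidence_tables: list[EvidenceTable] = (),
    hit_table: Optional[EvidenceTable] = None,
    profiles: Optional[list[ExpressionProfile]] = None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run the pipeline on in-memory objects (the CLI wraps this with I/O)."""
    config = config or PipelineConfig()
    stage_counts = {"input": len(records)}

    # stage 1: secretome prefilter
    if config.run_prefilter:
        kept_records, pre_report = prefilter.apply_prefilter(
            records, evidence_tables, config.prefilter
        )
    else:
        kept_records = records
        pre_report = pd.DataFrame(
            {"id": [r.id for r in records], "kept": 1, "reason": "pass"}
        )
    stage_counts["prefilter"] = len(kept_records)
    log.info("prefilter: %d -> %d", len(records), len(kept_records))

    # stage 2: cleavage-site scan
    scan_results = scanner.scan_records(kept_records, config.scanner)
    scan_pass = {res.record.id for res in scan_results if res.score.passes}
    stage_counts["scanner"] = len(scan_pass)
    log.info("scanner: %d -> %d", len(kept_records), len(scan_pass))

    surviving = sorted(scan_pass)

    # stage 3: homology filter
    homology_report = None
    if config.run_homology and hit_table is not None:
        surviving, homology_report = homology.filter_by_homology(
            surviving, hit_table, config.homology
        )
    stage_counts["homology"] = len(surviving)
    log.info("homology: -> %d", len(surviving))

    # stage 4: neuronal-expression filter
    expression_report = None
    if config.run_expression and profiles is not None:
        surviving, expression_report = expression.filter_by_expression(
            surviving, profiles, config.expression
        )
    stage_counts["expression"] = len(surviving)
    log.info("expression: -> %d", len(surviving))

    # stage 5: similarity clustering of the survivors
    graph = None
    if config.run_cluster and len(surviving) >= 2:
        survivor_seqs = {
            res.record.id: res.record.residues
            for res in scan_results
            if res.record.id in set(surviving)
        }
        config.cluster.layout.seed = config.seed
        graph = clustering.cluster_sequences(survivor_seqs, config.cluster)

    final = set(surviving)
    by_id = {res.record.id: res for res in scan_results}
    rows = []
    hom_kept = (
        dict(zip(homology_report["id"], homology_report["kept"]))
        if homology_report is not None
        else {}
    )
    expr_kept = (
        dict(zip(expression_report["id"], expression_report["kept"]))
        if expression_report is not None
        else {}
    )
    pre_kept = dict(zip(pre_report["id"], pre_report["kept"]))
    for record in records:
        rid = record.id
        res = by_id.get(rid)
        labels = graph.cluster_labels.get(rid, "") if graph else ""
        rows.append(
            {
                "id": rid,
                "prefilter_pass": int(pre_kept.get(rid, 0)),
                "scanner_pass": int(rid in scan_pass),
                "homology_pass": int(hom_kept.get(rid, rid in scan_pass)),
                "expression_pass": int(expr_kept.get(rid, rid in final)),
                "final": int(rid in final),
                "n_peptides": res.score.n_peptides if res else 0,
                "n_passing": res.score.n_passing if res else 0,
                "score": res.score.score if res else 0.0,
                "families": ";".join(
                    sorted({p.family for p in res.peptides if p.counts_toward_pass})
                ) if res else "",
                "cluster_label": labels,
            }
        )
    candidates = pd.DataFrame(rows)
    stage_counts["final"] = len(final)
    return PipelineResult(
        records=records,
        prefilter_report=pre_report,
        scan_results=scan_results,
        homology_report=homology_report,
        expression_report=expression_report,
        graph=graph,
        candidates=candidates,
        stage_counts=stage_counts,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: load inputs, run all stages, write artifacts."""
    config.validate_paths()
    records = read_fasta(config.fasta)

    evidence_tables = []
    for path, source in (
        (config.signal_evidence, "signal_caller"),
        (config.tm_evidence, "tm_caller"),
        (config.domain_evidence, "domain_scanner"),
    ):
        if path:
            table = parse_evidence(path, source)
            warn_orphans(table, records)
            evidence_tables.append(table)
    hit_table = (
        parse_evidence(config.alignment_hits, "alignment_hits")
        if config.alignment_hits
        else None
    )
    profiles = (
        read_expression(config.expression_matrix, config.cluster_annotation)
        if config.expression_matrix
        else None
    )

    result = run_stages(records, evidence_tables, hit_table, profiles, config)
    write_outputs(result, config)
    return result


def write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = [f"seed: {config.seed}"]
    write_table(result.prefilter_report, out / "prefilter_reasons.tsv", extra_header=header)
    scanner.write_peptide_table(result.scan_results, out / "peptides.tsv")
    scanner.write_peptide_fasta(result.scan_results, out / "peptides.fasta")
    if result.homology_report is not None:
        write_table(result.homology_report, out / "homology_reasons.tsv", extra_header=header)
    if result.expression_report is not None:
        write_table(result.expression_report, out / "expression_reasons.tsv", extra_header=header)
    if result.graph is not None:
        write_table(clustering.edge_table(result.graph), out / "edges.tsv", extra_header=header)
        write_table(clustering.coordinates_table(result.graph), out / "coordinates.tsv", extra_header=header)
        write_table(clustering.cluster_table(result.graph), out / "clusters.tsv", extra_header=header)
    write_table(result.candidates, out / "candidates.tsv", extra_header=header)
    summary = {"seed": config.seed, "stage_counts": result.stage_counts}
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
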