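"""End-to-end orchestration: alignments in, annotated isoform catalogue out.

``run_pipeline`` chains the stages — read-chain extraction, junction
snapping and tabulation, novel-exon discovery, full-length isoform assembly,
ORF/NMD annotation and domain mapping — writes every table alongside a
machine-readable summary, and records the resolved configuration so a run
can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from nanosplice.gene_model import GeneModel, load_gene_model, read_fasta
from nanosplice.isoforms import (
    assemble_variants,
    match_catalogue,
    variants_as_gene_model,
    write_catalogue_fasta,
    write_catalogue_tsv,
)
from nanosplice.junctions import (
    discover_novel_exons,
    extract_read_chains,
    junction_table_to_bed,
    novel_exons_to_exons,
    snap_junctions,
    tabulate_junctions,
)
from nanosplice.orf import classify_nmd, derive_anchors, domain_presence, predict_orf

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "summarize"]

log = logging.getLogger("nanosplice")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All paths and stage parameters of one pipeline run."""

    alignments: str = ""
    genome: str = ""
    annotation: str = ""
    output_dir: str = "nanosplice_out"
    catalogue: str = ""                 # optional reference chain TSV (name<TAB>chain)
    snap_window: int = 12
    min_support: int = 5
    min_fraction: float = 1e-4
    full_length_window: int = 30
    min_isoform_support: int = 3
    d_nmd: int = 50
    min_orf_aa: int = 50
    seed: int = 0

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a key-value mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    junction_table: pd.DataFrame
    novel_exons: pd.DataFrame
    catalogue: pd.DataFrame
    orf_report: pd.DataFrame
    domain_table: pd.DataFrame
    summary: dict[str, Any] = field(default_factory=dict)


def _load_reference_catalogue(path: str | Path) -> dict[str, list[str]]:
    ref: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("name\t"):
            continue
        name, chain = line.split("\t")[:2]
        ref[name] = chain.split(",")
    return ref


def run_pipeline(
    cfg: PipelineConfig,
    model: GeneModel | None = None,
    genome: Mapping[str, str] | None = None,
) -> PipelineResult:
    """Run every stage and write the report bundle to ``cfg.output_dir``.

    ``model`` and ``genome`` may be passed in memory; otherwise they are
    loaded from ``cfg.annotation`` and ``cfg.genome``.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(cfg, model, genome, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(
    cfg: PipelineConfig,
    model: GeneModel | None,
    genome: Mapping[str, str] | None,
    out: Path,
) -> PipelineResult:
    from nanosplice import __version__
    log.info("nanosplice %s, config %s", __version__, cfg.digest())
    cfg.to_yaml(out / "config.resolved.yaml")

    if model is None:
        model = load_gene_model(cfg.annotation)
    if genome is None:
        genome = read_fasta(cfg.genome)

    chains = extract_read_chains(cfg.alignments)
    log.info("stage extract: %d primary read chains", len(chains))

    chains = snap_junctions(chains, model, w=cfg.snap_window, genome=genome)
    table = tabulate_junctions(
        chains, model, min_support=cfg.min_support, min_fraction=cfg.min_fraction
    )
    log.info("stage junctions: %d rows", len(table))
    table.to_csv(out / "junctions.tsv", sep="\t", index=False)
    junction_table_to_bed(table, model.contig, out / "junctions.bed")

    calls = discover_novel_exons(chains, model, min_support=cfg.min_support, w=cfg.snap_window)
    novel_df = pd.DataFrame(
        [(c.exon_id, c.start, c.end, c.length, c.flank_left, c.flank_right, c.support)
         for c in calls],
        columns=["exon_id", "start", "end", "length", "flank_left", "flank_right", "support"],
    )
    log.info("stage novel exons: %d calls", len(calls))
    novel_df.to_csv(out / "novel_exons.tsv", sep="\t", index=False)

    variants = assemble_variants(
        chains, table, calls, model,
        full_length_window=cfg.full_length_window,
        min_isoform_support=cfg.min_isoform_support,
    )
    match = None
    if cfg.catalogue:
        match = match_catalogue(variants, _load_reference_catalogue(cfg.catalogue))
        for v in variants:
            if match.assignments.get(v.name, "unassigned") != "unassigned":
                v.name = match.assignments[v.name]
    log.info("stage assembly: %d variants", len(variants))
    write_catalogue_tsv(variants, out / "catalogue.tsv", match)
    cat_df = pd.read_csv(out / "catalogue.tsv", sep="\t")
    ext = model.with_novel_exons(novel_exons_to_exons(calls, model.contig))
    if variants:
        from nanosplice.gene_model import write_gene_model_bed12, write_gene_model_gtf

        as_model = variants_as_gene_model(variants, ext)
        write_gene_model_bed12(as_model, out / "catalogue.bed12")
        write_gene_model_gtf(as_model, out / "catalogue.gtf")
        write_catalogue_fasta(variants, ext, genome, out / "catalogue.fasta")

    anchors = derive_anchors(model, genome)
    ref_prot = predict_orf(
        model.chain_sequence(genome, next(iter(model.transcripts.values()))),
        anchors, variant="reference",
    ).protein
    orf_rows, dom_rows = [], []
    for v in variants:
        cdna = ext.chain_sequence(genome, v.chain)
        orf = predict_orf(cdna, anchors, variant=v.name, min_orf_aa=cfg.min_orf_aa)
        orf = classify_nmd(orf, v.chain, ext, d_nmd=cfg.d_nmd)
        orf_rows.append((
            v.name, orf.start_origin, orf.protein_length,
            int(orf.has_orf), int(orf.ptc), int(orf.nmd_candidate),
        ))
        dp = domain_presence(orf.protein, ref_prot, model.domain_defs, variant=v.name)
        dom_rows.append((v.name, *(int(dp.presence[d.name]) for d in model.domain_defs)))
    orf_df = pd.DataFrame(
        orf_rows, columns=["variant", "start_origin", "protein_aa", "has_orf", "ptc", "nmd_candidate"]
    )
    dom_df = pd.DataFrame(
        dom_rows, columns=["variant"] + [d.name for d in model.domain_defs]
    )
    log.info("stage orf/domains: %d variants annotated", len(orf_df))
    orf_df.to_csv(out / "orf_report.tsv", sep="\t", index=False)
    dom_df.to_csv(out / "domains.tsv", sep="\t", index=False)

    result = PipelineResult(
        junction_table=table, novel_exons=novel_df, catalogue=cat_df,
        orf_report=orf_df, domain_table=dom_df,
    )
    result.summary = summarize(result)
    result.summary["config_digest"] = cfg.digest()
    from nanosplice import __version__ as _v
    result.summary["version"] = _v
    (out / "summary.json").write_text(json.dumps(result.summary, indent=2) + "\n")
    log.info("summary: %s", result.summary)
    return result


def summarize(result: PipelineResult) -> dict[str, Any]:
    """Stable named counts, each recomputed from the underlying table."""
    table, cat, orf = result.junction_table, result.catalogue, result.orf_report
    return {
        "n_junctions": int(len(table)),
        "n_annotated_junctions": int((table["status"] == "annotated").sum()),
        "n_novel_junctions": int((table["status"] == "novel_combination").sum()),
        "n_cryptic_junctions": int((table["status"] == "cryptic").sum()),
        "n_novel_exons": int(len(result.novel_exons)),
        "n_variants": int(len(cat)),
        "novel_variant_count": (
            int((cat["category"] != "annotated").sum()) if len(cat) else 0
        ),
        "n_orf_bearing": int(orf["has_orf"].sum()) if len(orf) else 0,
        "n_nmd_candidates": int(orf["nmd_candidate"].sum()) if len(orf) else 0,
        "n_non_coding": (
            int(((orf["has_orf"] == 0) | (orf["nmd_candidate"] == 1)).sum())
            if len(orf) else 0
        ),
    }
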