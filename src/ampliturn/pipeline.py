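"""End-to-end orchestration: simulate/load -> prep -> otu -> rarefy -> turnover.

`run_synthetic_analysis` keeps everything in memory (used by tests and the
acceptance script); `run_all` drives the same stages from a
:class:`PipelineConfig`, writing every stage output plus a provenance
manifest so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .layout import ReadLayout
from .morphotype import ReferenceSet, affiliate_table, lineage_relative_abundance
from .otu import OtuTable, build_table, presence_profile
from .rarefaction import curves_to_tsv, plot_curves, rarefaction_curves
from .readprep import demultiplex_summary, prep_reads, read_fastq, write_inserts_fasta, write_summary_json
from .simulate import (
    CommunityDesign,
    ErrorModel,
    GroundTruth,
    simulate_community,
    simulate_reads,
    write_fastq,
)
from .turnover import (
    UndefinedStatisticError,
    occupancy_class_summary,
    occupancy_stats,
    slope_occupancy_correlation,
    slope_table,
    subsample_equal_depth,
)

logger = logging.getLogger("ampliturn")


@dataclass
class PipelineConfig:
    """Stage parameters; defaults are the analysis' canonical thresholds."""

    outdir: str = "out"
    reads: str | None = None  # FASTQ path; None -> simulate
    layout: str | None = None  # layout YAML; None -> default layout
    refs: str | None = None  # reference FASTA for morphotype affiliation
    simulate: dict = field(default_factory=dict)  # CommunityDesign overrides
    error_model: dict = field(default_factory=dict)  # ErrorModel overrides
    min_len: int = 200
    min_qual: float = 24.0
    min_copies: int = 2
    collapse_indels: bool = True
    max_subs: int = 1
    basis: str = "affiliated"
    min_total: int = 10
    log_base: float = 10.0
    depth: int | str = "auto"
    n_points: int = 50
    plot: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls(**raw)


@dataclass
class AnalysisResult:
    """In-memory bundle of every stage output."""

    truth: GroundTruth | None
    layout: ReadLayout
    accepted: list
    rejection_log: object
    per_sample_accepted: dict
    table: OtuTable
    subsampled: OtuTable
    depth: int
    curves: list
    occupancy: pd.DataFrame
    class_summary: pd.DataFrame
    anova: object
    slopes: pd.DataFrame
    correlation: object
    slope_by_class: pd.DataFrame | None


def _analyse(
    reads,
    layout: ReadLayout,
    config: PipelineConfig,
    truth: GroundTruth | None = None,
) -> AnalysisResult:
    accepted, log = prep_reads(
        reads, layout,
        min_qual=config.min_qual, min_len=config.min_len,
        min_copies=config.min_copies,
    )
    per_sample = demultiplex_summary(accepted, samples=layout.samples)
    logger.info("prep: %d/%d reads accepted", log.n_accepted, log.n_input)

    by_sample: dict[str, list[str]] = {s: [] for s in layout.samples}
    for read in accepted:
        by_sample[read.sample].append(read.insert)
    by_sample = {s: seqs for s, seqs in by_sample.items() if seqs}
    table = build_table(by_sample, collapse_indels=config.collapse_indels)
    logger.info("otu: %d OTUs across %d samples", table.n_otus, len(table.samples))

    curves = rarefaction_curves(table, n_points=config.n_points)

    depth = (
        int(table.sample_totals.min()) if config.depth == "auto" else int(config.depth)
    )
    subsampled = subsample_equal_depth(table, depth, seed=config.seed + 1)
    occupancy = occupancy_stats(subsampled)
    class_summary, anova = occupancy_class_summary(subsampled)
    slopes = slope_table(subsampled, min_total=config.min_total, log_base=config.log_base)
    try:
        correlation, slope_by_class = slope_occupancy_correlation(slopes)
    except UndefinedStatisticError as exc:
        logger.warning("slope-occupancy correlation undefined: %s", exc)
        correlation, slope_by_class = None, None

    return AnalysisResult(
        truth=truth, layout=layout, accepted=accepted, rejection_log=log,
        per_sample_accepted=per_sample, table=table, subsampled=subsampled,
        depth=depth, curves=curves, occupancy=occupancy,
        class_summary=class_summary, anova=anova, slopes=slopes,
        correlation=correlation, slope_by_class=slope_by_class,
    )


def run_synthetic_analysis(
    design: CommunityDesign | None = None,
    error: ErrorModel | None = None,
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    """Simulate a community and run the full analysis in memory."""
    design = design or CommunityDesign()
    error = error or ErrorModel()
    config = config or PipelineConfig(min_len=180, seed=design.seed)
    layout = ReadLayout.for_samples(design.sample_names)
    truth = simulate_community(design)
    reads = simulate_reads(truth, error, layout)
    return _analyse(reads, layout, config, truth=truth)


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every configured stage, write outputs + manifest under outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "ampliturn",
        "version": __version__,
        "parameters": asdict(config),
        "stages": {},
        "inputs": {},
    }

    truth = None
    if config.reads is None:
        design = CommunityDesign(**{"seed": config.seed, **config.simulate})
        error = ErrorModel(**config.error_model)
        layout = (
            ReadLayout.from_yaml(config.layout)
            if config.layout
            else ReadLayout.for_samples(design.sample_names)
        )
        truth = simulate_community(design)
        truth.to_tsv(outdir / "ground_truth.tsv")
        truth.templates_to_fasta(outdir / "templates.fasta")
        reads_path = outdir / "reads.fastq"
        n_reads = write_fastq(simulate_reads(truth, error, layout), reads_path)
        layout.to_yaml(outdir / "layout.yaml")
        manifest["stages"]["simulate"] = {
            "n_reads": n_reads, "n_otus": len(truth.otu_ids),
        }
        reads = read_fastq(reads_path)
    else:
        if config.layout is None:
            raise ValueError("a layout YAML is required when reads are supplied")
        layout = ReadLayout.from_yaml(config.layout)
        manifest["inputs"]["reads_sha256"] = _sha256(config.reads)
        reads = read_fastq(config.reads)

    result = _analyse(reads, layout, config, truth=truth)

    write_inserts_fasta(result.accepted, outdir / "inserts")
    result.rejection_log.to_tsv(outdir / "rejections.tsv")
    write_summary_json(result.rejection_log, result.per_sample_accepted,
                       outdir / "prep_summary.json")
    result.table.to_tsv(outdir / "otu_table.tsv")
    result.table.representatives_to_fasta(outdir / "otu_representatives.fasta")
    curves_to_tsv(result.curves, outdir / "rarefaction.tsv")
    if config.plot:
        plot_curves(result.curves, outdir / "rarefaction.png")
    result.subsampled.to_tsv(outdir / "otu_table_subsampled.tsv")
    result.occupancy.to_csv(outdir / "occupancy.tsv", sep="\t")
    result.class_summary.to_csv(outdir / "occupancy_classes.tsv", sep="\t")
    result.slopes.to_csv(outdir / "slopes.tsv", sep="\t")

    stats_json: dict = {"subsample_depth": result.depth}
    if result.anova is not None:
        stats_json["anova"] = {
            "F": result.anova.F,
            "df": [result.anova.df_between, result.anova.df_within],
            "p_value": result.anova.p_value,
        }
        result.anova.tukey.to_csv(outdir / "tukey.tsv", sep="\t", index=False)
    if result.correlation is not None:
        stats_json["slope_occupancy_pearson"] = {
            "r": result.correlation.r,
            "p_value": result.correlation.p_value,
            "n_pairs": result.correlation.n_pairs,
        }
        result.slope_by_class.to_csv(outdir / "slope_by_occupancy.tsv", sep="\t")
    with open(outdir / "turnover_stats.json", "w") as handle:
        json.dump(stats_json, handle, indent=2)
        handle.write("\n")

    if config.refs:
        refs = ReferenceSet.from_fasta(config.refs)
        affiliations = affiliate_table(result.table, refs, max_subs=config.max_subs)
        abundance = lineage_relative_abundance(
            result.table, affiliations, basis=config.basis
        )
        abundance.fractions.to_csv(outdir / "lineage_fractions.tsv", sep="\t",
                                   index_label="sample")
        abundance.detail.to_csv(outdir / "lineage_detail.tsv", sep="\t", index=False)
        manifest["stages"]["morphotype"] = {
            "n_references": len(refs.references),
            "n_affiliated": sum(
                1 for a in affiliations.values()
                if a.lineage not in ("unaffiliated", "ambiguous")
            ),
        }

    N, per_sample_i = presence_profile(result.subsampled)
    manifest["stages"]["prep"] = result.rejection_log.summary()
    manifest["stages"]["otu"] = {
        "n_otus": result.table.n_otus,
        "n_otus_subsampled": result.subsampled.n_otus,
        "distinct_otus_per_sample": {s: int(v) for s, v in per_sample_i.items()},
    }
    manifest["stages"]["turnover"] = stats_json
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, default=str)
        handle.write("\n")
    return manifest
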