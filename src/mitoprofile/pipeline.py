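"""Run configuration and report-bundle orchestration.

One YAML config governs all stages; unknown keys are rejected and defaults
fill any omitted key.  ``run_pipeline`` emits the full report bundle into an
output directory:

* arrangement.tsv      — gene-arrangement table with computed sizes/gaps
* composition.tsv      — per-class base composition and skews
* codon_usage.tsv      — wide codon-usage table (counts + RSCU)
* codon_usage_long.tsv — long-format codon table (count, rscu, cdspt)
* control_region.tsv   — detected control-region repeat features
* junctions.tsv        — junction-motif occurrence table (+ windows FASTA)
* trna_structures.txt  — dot-bracket cloverleaf report
* run_summary.log      — version, config echo, one line per stage
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .annotation_io import (
    AnnotationTable,
    GeneClass,
    GenomeRecord,
    extract_feature_sequence,
    read_fasta,
    read_feature_table,
    read_genbank,
)
from .arrangement import write_arrangement_report
from .codon_usage import (
    classify_terminals,
    count_codons,
    genetic_code_partition,
    write_codon_report_long,
    write_codon_report_wide,
)
from .composition import composition_report, write_composition_report
from .control_region import RegionParams, region_report, write_region_report
from .junction_motifs import junction_window, motif_scan, write_windows_fasta
from .trna_cloverleaf import FoldParams, fold_all, write_structure_report

__all__ = ["RunConfig", "validate_config", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    fasta: Optional[str] = None
    annotation: Optional[str] = None  # feature-table TSV
    genbank: Optional[str] = None  # alternative combined input
    outdir: str = "mitoprofile_out"
    genetic_code: str = "standard"
    gc_skew_orientation: str = "g_minus_c"
    homopolymer_min: int = 10
    microsat_unit: int = 2
    microsat_min_copies: int = 5
    repeat_min: int = 30
    junction_pairs: list = field(
        default_factory=lambda: [["atp8", "atp6"], ["trnS2", "nad1"]]
    )
    motifs: list = field(default_factory=lambda: ["ATGATAA", "TTAACTA"])
    flanks: list = field(default_factory=lambda: [15, 15])
    max_mismatch: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.genetic_code not in ("standard", "invertebrate_mito"):
            raise ValueError(f"genetic_code must be standard or invertebrate_mito, "
                             f"got {self.genetic_code!r}")
        if self.gc_skew_orientation not in ("g_minus_c", "c_minus_g"):
            raise ValueError(
                f"gc_skew_orientation must be g_minus_c or c_minus_g, "
                f"got {self.gc_skew_orientation!r}"
            )


def validate_config(path: Optional[str | Path] = None, **overrides) -> RunConfig:
    """Load a YAML config; fill defaults; reject unknown keys."""
    data = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    cfg = RunConfig(**data)
    for p in (cfg.fasta, cfg.annotation, cfg.genbank):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    return cfg


def _load_inputs(cfg: RunConfig) -> tuple[GenomeRecord, AnnotationTable]:
    if cfg.genbank:
        return read_genbank(cfg.genbank)
    if not cfg.fasta or not cfg.annotation:
        raise PipelineError(
            "either 'genbank' or both 'fasta' and 'annotation' must be given"
        )
    genome = read_fasta(cfg.fasta)[0]
    table = read_feature_table(cfg.annotation, genome_length=genome.length,
                               genome_id=genome.id)
    return genome, table


def run_pipeline(cfg: RunConfig, log=None) -> dict[str, Path]:
    """Run every stage and emit the report bundle; returns output paths."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    log_lines = [f"mitoprofile {__version__}", f"config: {cfg}"]

    def stage(name: str, fn) -> None:
        t0 = time.perf_counter()
        fn()
        line = f"stage {name}: done in {time.perf_counter() - t0:.3f}s"
        log_lines.append(line)
        if log:
            log(line)

    genome, table = _load_inputs(cfg)
    partition = genetic_code_partition(cfg.genetic_code)

    def do_arrangement():
        p = outdir / "arrangement.tsv"
        write_arrangement_report(table, p)
        outputs["arrangement"] = p

    def do_composition():
        p = outdir / "composition.tsv"
        rows = composition_report(genome, table,
                                  gc_orientation=cfg.gc_skew_orientation)
        write_composition_report(rows, p)
        outputs["composition"] = p

    def do_codons():
        pcgs = table.by_class(GeneClass.PCG)
        if not pcgs:
            raise PipelineError("no protein-coding genes annotated")
        cds = [(f.name, extract_feature_sequence(genome, f)) for f in pcgs]
        usage = count_codons([s for _, s in cds])
        p_wide = outdir / "codon_usage.tsv"
        p_long = outdir / "codon_usage_long.tsv"
        write_codon_report_wide(usage, partition, p_wide)
        write_codon_report_long(usage, partition, p_long)
        terms = classify_terminals(cds, partition)
        p_term = outdir / "terminal_codons.tsv"
        with open(p_term, "w") as fh:
            fh.write("gene\tstart_codon\tis_ATN\tstop_codon\tcomplete\n")
            for t in terms:
                fh.write(f"{t.name}\t{t.start_codon}\t{t.is_atn}\t"
                         f"{t.stop_codon or ''}\t{t.stop_complete}\n")
        outputs["codon_usage"] = p_wide
        outputs["codon_usage_long"] = p_long
        outputs["terminal_codons"] = p_term

    def do_control_region():
        p = outdir / "control_region.tsv"
        rep = region_report(
            genome, table,
            RegionParams(cfg.homopolymer_min, cfg.microsat_unit,
                         cfg.microsat_min_copies, cfg.repeat_min),
            gc_orientation=cfg.gc_skew_orientation,
        )
        write_region_report(rep, p)
        outputs["control_region"] = p

    def do_junctions():
        windows = []
        rows = []
        import pandas as pd

        for (a, b), motif in zip(map(tuple, cfg.junction_pairs), cfg.motifs):
            w = junction_window(genome, table, a, b,
                                flank_a=cfg.flanks[0], flank_b=cfg.flanks[1])
            windows.append(w)
            rows.append(motif_scan([w], motif, cfg.max_mismatch))
        p = outdir / "junctions.tsv"
        pd.concat(rows, ignore_index=True).to_csv(p, sep="\t", index=False)
        write_windows_fasta(windows, outdir / "junction_windows.fasta")
        outputs["junctions"] = p

    def do_trna():
        rep = fold_all(genome, table)
        p = outdir / "trna_structures.txt"
        write_structure_report(rep, genome, table, p)
        outputs["trna_structures"] = p

    stages = [
        ("arrangement", do_arrangement),
        ("composition", do_composition),
        ("codons", do_codons),
        ("control_region", do_control_region),
        ("junctions", do_junctions),
        ("trna", do_trna),
    ]
    try:
        for name, fn in stages:
            stage(name, fn)
    finally:
        (outdir / "run_summary.log").write_text("\n".join(log_lines) + "\n")
    return outputs
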