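"""End-to-end orchestration of the reads pipeline.

Stage order follows the product-characterization workflow: triage against
the references (internal k-mer surrogate or an external aligner's SAM),
poly-C tail trimming of the unmapped fraction, composition / CPM /
homopolymer / positional profiling, then motif-input preparation
(poly(A) filter, exact-identity clustering, copy-number retention, FASTA
export). Everything is parameterized by one RunConfig; every parameter is
echoed into the machine-readable run report and all outputs are plain
text (TSV/JSON/FASTA/FASTQ).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import cluster_motif, read_profiles, read_triage, seqio, synthetic_data

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


class DataError(ValueError):
    """Input data violates a pipeline precondition."""


def _take(d: dict, section: str, allowed: set[str]) -> dict:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {section}: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )
    return d


@dataclass
class RunConfig:
    """Full parameterization of a reads-pipeline run."""

    out_dir: str = "drtkit_out"
    seed: int = 0
    # input: either a FASTQ/FASTA path, a SAM path (triage pre-done), or
    # simulate=True to generate reads from the synthetic module
    reads_path: str | None = None
    sam_path: str | None = None
    simulate: bool = False
    sim: dict[str, Any] = field(default_factory=dict)
    # references for k-mer triage: name -> path or literal sequence
    references: dict[str, str] = field(default_factory=dict)
    k: int = read_triage.DEFAULT_K
    min_hits: int = read_triage.DEFAULT_MIN_HITS
    min_tail: int = read_profiles.DEFAULT_MIN_TAIL
    max_mismatch: int = read_profiles.DEFAULT_MAX_MISMATCH
    trim_end: str = "3p"
    thresholds: tuple[int, ...] = read_profiles.DEFAULT_THRESHOLDS
    max_pos: int = read_profiles.DEFAULT_MAX_POS
    min_polya_run: int = cluster_motif.DEFAULT_MIN_POLYA_RUN
    min_copies: int = cluster_motif.DEFAULT_MIN_COPIES

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        _take(dict(raw), "config", allowed)
        cfg = cls(**raw)
        if cfg.simulate and cfg.sim:
            sim_allowed = {
                f.name for f in dataclasses.fields(synthetic_data.ReadSimParams)
            } - {"seed"}
            _take(dict(cfg.sim), "sim", sim_allowed)
        if cfg.trim_end not in ("3p", "5p"):
            raise ConfigError("trim_end must be '3p' or '5p'")
        cfg.thresholds = tuple(int(t) for t in cfg.thresholds)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def parameters(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d


@dataclass
class StageReport:
    name: str
    n_in: int
    n_out: int
    seconds: float
    details: dict[str, Any] = field(default_factory=dict)


@dataclass
class RunReport:
    parameters: dict[str, Any]
    stages: list[StageReport] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "parameters": self.parameters,
            "stages": [dataclasses.asdict(s) for s in self.stages],
            "outputs": self.outputs,
            "warnings": self.warnings,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
            fh.write("\n")


def _resolve_reference(value: str) -> str:
    try:
        is_file = Path(value).exists()
    except OSError:  # e.g. a literal sequence too long for a file name
        is_file = False
    if is_file:
        p = Path(value)
        records = seqio.parse_fastx(p)
        if not records:
            raise DataError(f"reference file {value} is empty")
        return records[0].seq
    return seqio.normalize_seq(value)


def _load_reads(config: RunConfig, out: Path, report: RunReport):
    if config.simulate:
        params = synthetic_data.ReadSimParams(seed=config.seed, **config.sim)
        if params.contaminant_reference is None and params.product_fraction < 1:
            raise ConfigError("sim.contaminant_reference required")
        readset = synthetic_data.simulate_product_read_set(params)
        fastq = out / "simulated.fastq"
        seqio.write_fastx(readset.reads, fastq, format="fastq")
        truth = out / "simulated_truth.tsv"
        readset.write_truth_tsv(truth)
        report.outputs["simulated_reads"] = str(fastq)
        report.outputs["simulated_truth"] = str(truth)
        return readset.reads
    if config.reads_path:
        reads = seqio.parse_fastx(config.reads_path)
        if not reads:
            raise DataError(f"no reads in {config.reads_path}")
        return reads
    raise ConfigError("one of reads_path / sam_path / simulate is required")


def run_pipeline(config: RunConfig) -> RunReport:
    """Run triage -> trim -> profiles -> cluster/export; return the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(parameters=config.parameters())

    # --- stage: input / triage -> unmapped reads
    t0 = time.perf_counter()
    if config.sam_path:
        unmapped = seqio.parse_sam_unmapped(config.sam_path)
        n_in = len(unmapped)  # total input count unknown from unmapped-only view
        details = {"route": "sam", "sam_path": config.sam_path}
        if not unmapped:
            raise DataError(f"no unmapped reads in {config.sam_path}")
    else:
        reads = _load_reads(config, out, report)
        if not config.references:
            raise ConfigError("references required for k-mer triage")
        refs = {
            name: _resolve_reference(val)
            for name, val in config.references.items()
        }
        result = read_triage.triage_reads(
            reads, refs, k=config.k, min_hits=config.min_hits
        )
        if result.n_mapped + len(result.unmapped) != result.n_reads:
            raise AssertionError("triage partition is not exact")
        _, unmapped = read_triage.split_by_triage(reads, result)
        n_in = len(reads)
        details = {"route": "kmer", **result.summary()}
    unmapped_path = out / "unmapped.fastq"
    if all(r.qual is not None for r in unmapped):
        seqio.write_fastx(unmapped, unmapped_path, format="fastq")
    else:
        unmapped_path = out / "unmapped.fasta"
        seqio.write_fastx(unmapped, unmapped_path, format="fasta")
    report.outputs["unmapped_reads"] = str(unmapped_path)
    report.stages.append(StageReport(
        "triage", n_in, len(unmapped), time.perf_counter() - t0, details
    ))
    if not unmapped:
        raise DataError("triage produced no unmapped reads to analyze")

    # --- stage: poly-C tail trimming
    t0 = time.perf_counter()
    trimmed, trim_report = read_profiles.trim_reads(
        unmapped, config.min_tail, config.max_mismatch, config.trim_end
    )
    trim_path = out / "trim_report.json"
    with open(trim_path, "w") as fh:
        json.dump(dataclasses.asdict(trim_report), fh, indent=2)
        fh.write("\n")
    report.outputs["trim_report"] = str(trim_path)
    report.stages.append(StageReport(
        "trim", len(unmapped), len(trimmed), time.perf_counter() - t0,
        {"reads_trimmed": trim_report.reads_trimmed,
         "reads_dropped": trim_report.reads_dropped,
         "bases_removed": trim_report.bases_removed},
    ))
    if trim_report.reads_dropped:
        report.warnings.append(
            f"{trim_report.reads_dropped} all-tail read(s) dropped"
        )
    if len(trimmed) + trim_report.reads_dropped != len(unmapped):
        raise AssertionError("trim stage lost reads")
    if not trimmed:
        raise DataError("all reads were dropped as poly-C tails")

    # --- stage: profiles
    t0 = time.perf_counter()
    spectrum = read_profiles.homopolymer_spectrum(trimmed, config.thresholds)
    posfreq = read_profiles.positional_frequency(trimmed, config.max_pos)
    ncpm = read_profiles.n_count_cpm(trimmed)
    spectrum_path = out / "homopolymer_spectrum.tsv"
    spectrum.to_tsv(spectrum_path)
    pos_path = out / "positional_frequency.tsv"
    posfreq.to_tsv(pos_path)
    report.outputs["homopolymer_spectrum"] = str(spectrum_path)
    report.outputs["positional_frequency"] = str(pos_path)
    report.stages.append(StageReport(
        "profiles", len(trimmed), len(trimmed), time.perf_counter() - t0,
        {"n_cpm": ncpm.cpm, "total_n": ncpm.total_n,
         "a_ge5_percent": spectrum.cell("A", config.thresholds[0])},
    ))

    # --- stage: cluster / motif export
    t0 = time.perf_counter()
    meme_path = out / "meme_input.fasta"
    table, retained = cluster_motif.prepare_meme_input(
        trimmed, meme_path,
        min_polya_run=config.min_polya_run, min_copies=config.min_copies,
    )
    if sum(table.counts()) != table.total_reads:
        raise AssertionError("cluster stage does not conserve read counts")
    table_path = out / "clusters.tsv"
    table.to_tsv(table_path)
    report.outputs["clusters"] = str(table_path)
    report.outputs["meme_input"] = str(meme_path)
    report.stages.append(StageReport(
        "cluster", len(trimmed), len(retained), time.perf_counter() - t0,
        {"n_clusters": len(table.clusters),
         "n_retained": len(retained),
         "meme_command": cluster_motif.meme_command(meme_path)},
    ))

    report_path = out / "run_report.json"
    report.to_json(report_path)
    report.outputs["run_report"] = str(report_path)
    return report
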