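"""Composition and homopolymer profiling of reverse-transcription reads.

These are the core read-level computations of the product-characterization
workflow: maximal homopolymer run detection, per-threshold run prevalence
spectra, poly-C terminal-transferase tail trimming, pooled base
composition, ambiguous-base counts-per-million, and positional base
frequencies.

Conventions:

* Runs are maximal stretches of one of A/C/G/T; N never forms a run and
  breaks runs.
* Spectrum counting is read-level — a read contributes at most once to
  each (base, threshold) cell, so a cell is "percent of reads containing
  at least one qualifying run". Run-level counting is available via
  ``count_runs=True`` for diagnostics.
* CPM uses the read count as denominator (ambiguous bases per million
  reads), not the base count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import ReadRecord

DEFAULT_THRESHOLDS = (5, 10, 15, 20, 25, 30, 35, 40)
RUN_BASES = ("A", "C", "G", "T")
ALL_BASES = ("A", "C", "G", "T", "N")


@dataclass(frozen=True)
class Run:
    """A maximal homopolymer run (0-based start)."""

    base: str
    start: int
    length: int


def find_runs(seq: str, min_len: int = 1) -> list[Run]:
    """All maximal A/C/G/T runs of length >= min_len, in position order."""
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    runs = []
    pos = 0
    for base, group in groupby(seq):
        length = sum(1 for _ in group)
        if base in RUN_BASES and length >= min_len:
            runs.append(Run(base, pos, length))
        pos += length
    return runs


@dataclass
class HomopolymerSpectrum:
    """Percent of reads containing a run of each base at each threshold."""

    thresholds: tuple[int, ...]
    percent: pd.DataFrame  # index: base, columns: thresholds
    total_reads: int

    def cell(self, base: str, threshold: int) -> float:
        return float(self.percent.loc[base, threshold])

    def to_tsv(self, path) -> None:
        out = self.percent.rename_axis("base").reset_index()
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def homopolymer_spectrum(
    reads: Sequence[ReadRecord],
    thresholds: Iterable[int] = DEFAULT_THRESHOLDS,
    count_runs: bool = False,
) -> HomopolymerSpectrum:
    """Per-(base, threshold) prevalence of homopolymer runs across reads.

    With ``count_runs=False`` (default) each cell is the percentage of
    reads containing >= 1 qualifying run; with ``count_runs=True`` each
    cell is runs per 100 reads (a read may count multiple times).
    """
    thresholds = tuple(sorted(set(int(t) for t in thresholds)))
    if not reads:
        raise ValueError("empty read set")
    if any(t < 1 for t in thresholds):
        raise ValueError("thresholds must be >= 1")
    counts = pd.DataFrame(
        0.0, index=list(RUN_BASES), columns=list(thresholds)
    )
    min_t = thresholds[0]
    for read in reads:
        runs = find_runs(read.seq, min_t)
        if count_runs:
            for run in runs:
                for t in thresholds:
                    if run.length >= t:
                        counts.loc[run.base, t] += 1
        else:
            best: dict[str, int] = {}
            for run in runs:
                if run.length > best.get(run.base, 0):
                    best[run.base] = run.length
            for base, longest in best.items():
                for t in thresholds:
                    if longest >= t:
                        counts.loc[base, t] += 1
    percent = counts * (100.0 / len(reads))
    return HomopolymerSpectrum(thresholds, percent, len(reads))


# ---------------------------------------------------------------------------
# Poly-C tail trimming

DEFAULT_MIN_TAIL = 5
DEFAULT_MAX_MISMATCH = 1


def trim_polyc_tail(
    read: ReadRecord,
    min_tail: int = DEFAULT_MIN_TAIL,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    end: str = "3p",
) -> tuple[ReadRecord | None, int]:
    """Remove a 3'-terminal poly-C tail; returns (read, bases_removed).

    The trimmed window is the longest terminal window of length >=
    ``min_tail`` that is C-delimited (first and last window base are C)
    and contains <= ``max_mismatch`` non-C bases, so the mismatch budget
    absorbs sequencing noise inside the tail but the trim never removes a
    template-derived boundary base. A read that is entirely tail is
    dropped (returned as None).
    ``end='5p'`` trims a leading poly-C instead, for reverse-complemented
    libraries (the read is reversed, trimmed, and reversed back).
    """
    if min_tail < 1:
        raise ValueError(f"min_tail must be >= 1, got {min_tail}")
    if end not in ("3p", "5p"):
        raise ValueError("end must be '3p' or '5p'")
    if end == "5p":
        flipped = ReadRecord(read.id, read.seq[::-1],
                             read.qual[::-1] if read.qual else None)
        trimmed, removed = trim_polyc_tail(flipped, min_tail, max_mismatch, "3p")
        if trimmed is None:
            return None, removed
        return ReadRecord(read.id, trimmed.seq[::-1],
                          trimmed.qual[::-1] if trimmed.qual else None), removed

    seq = read.seq
    if not seq.endswith("C"):
        return read, 0
    best = 0
    mismatches = 0
    for length in range(1, len(seq) + 1):
        starts_with_c = seq[len(seq) - length] == "C"
        if not starts_with_c:
            mismatches += 1
            if mismatches > max_mismatch:
                break
        if length >= min_tail and starts_with_c:
            best = length
    if best < min_tail:
        return read, 0
    if best >= len(seq):
        return None, len(seq)
    qual = read.qual[:-best] if read.qual else None
    return ReadRecord(read.id, seq[:-best], qual), best


@dataclass
class TailTrimReport:
    """Batch trimming outcome with before/after pooled composition."""

    reads_trimmed: int
    reads_dropped: int
    bases_removed: int
    composition_before: dict[str, float]
    composition_after: dict[str, float]
    min_tail: int
    max_mismatch: int


def trim_reads(
    reads: Sequence[ReadRecord],
    min_tail: int = DEFAULT_MIN_TAIL,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    end: str = "3p",
) -> tuple[list[ReadRecord], TailTrimReport]:
    """Trim every read; all-tail reads are dropped and counted."""
    before = base_composition(reads)
    out: list[ReadRecord] = []
    trimmed_n = dropped = removed_total = 0
    for read in reads:
        trimmed, removed = trim_polyc_tail(read, min_tail, max_mismatch, end)
        if trimmed is None:
            dropped += 1
            removed_total += removed
            continue
        if removed:
            trimmed_n += 1
            removed_total += removed
        out.append(trimmed)
    after = base_composition(out) if out else {b: 0.0 for b in ALL_BASES}
    return out, TailTrimReport(
        reads_trimmed=trimmed_n,
        reads_dropped=dropped,
        bases_removed=removed_total,
        composition_before=before,
        composition_after=after,
        min_tail=min_tail,
        max_mismatch=max_mismatch,
    )


# ---------------------------------------------------------------------------
# Composition / CPM / positional profile


def base_composition(reads: Sequence[ReadRecord]) -> dict[str, float]:
    """Pooled per-base fractions of {A,C,G,T,N} over all bases of all reads."""
    if not reads:
        raise ValueError("empty read set")
    pooled = "".join(r.seq for r in reads)
    if not pooled:
        raise ValueError("no bases in read set")
    n = len(pooled)
    return {b: pooled.count(b) / n for b in ALL_BASES}


@dataclass
class NCpmReport:
    total_n: int
    total_reads: int

    @property
    def cpm(self) -> float:
        return self.total_n / self.total_reads * 1e6


def n_count_cpm(reads: Sequence[ReadRecord]) -> NCpmReport:
    """Ambiguous-base counts per million reads."""
    if not reads:
        raise ValueError("empty read set")
    total_n = sum(r.seq.count("N") for r in reads)
    return NCpmReport(total_n=total_n, total_reads=len(reads))


DEFAULT_MAX_POS = 122


@dataclass
class PositionalFrequencyMatrix:
    """Per-position base frequencies from the 5' end (1-based positions)."""

    freq: pd.DataFrame      # index: position 1..max_pos, columns: A,T,C,G,N
    coverage: pd.Series     # reads covering each position
    max_pos: int

    def to_tsv(self, path) -> None:
        out = self.freq.copy()
        out["coverage"] = self.coverage
        out.rename_axis("position").reset_index().to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )


def positional_frequency(
    reads: Sequence[ReadRecord], max_pos: int = DEFAULT_MAX_POS
) -> PositionalFrequencyMatrix:
    """Base frequency at each 5'-anchored position up to ``max_pos``.

    Frequency of base b at position p = count(b at p) / coverage(p);
    uncovered positions have coverage 0 and NaN frequencies.
    """
    if max_pos < 1:
        raise ValueError(f"max_pos must be >= 1, got {max_pos}")
    order = ("A", "T", "C", "G", "N")
    counts = np.zeros((max_pos, len(order)), dtype=np.int64)
    code = {b: j for j, b in enumerate(order)}
    for read in reads:
        upto = min(len(read.seq), max_pos)
        for p in range(upto):
            counts[p, code[read.seq[p]]] += 1
    coverage = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / coverage[:, None]
    index = pd.RangeIndex(1, max_pos + 1, name="position")
    return PositionalFrequencyMatrix(
        freq=pd.DataFrame(freq, index=index, columns=list(order)),
        coverage=pd.Series(coverage, index=index, name="coverage"),
        max_pos=max_pos,
    )
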