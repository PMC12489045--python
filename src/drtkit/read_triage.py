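"""Partition reads into reference-mapped vs unmapped.

Two routes exist: consume an external aligner's SAM (via
seqio.parse_sam_unmapped) or use the internal k-mer surrogate classifier
implemented here. The surrogate is a desk-scale stand-in for a real
aligner, not a reproduction of one: a read is "mapped" when it shares at
least ``min_hits`` exact k-mers with a reference (either strand); k-mers
containing N never match. Defaults k=15, min_hits=2 tolerate one
substitution in a ~50 nt read while keeping chance matches negligible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .seqio import ReadRecord, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_K = 15
DEFAULT_MIN_HITS = 2


@dataclass
class TriageResult:
    """Exact partition of read ids into per-reference mapped sets + unmapped."""

    mapped: dict[str, list[str]]  # reference name -> read ids
    unmapped: list[str]
    n_reads: int

    @property
    def n_mapped(self) -> int:
        return sum(len(v) for v in self.mapped.values())

    @property
    def unmapped_fraction(self) -> float:
        return len(self.unmapped) / self.n_reads if self.n_reads else 0.0

    def summary(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_mapped": self.n_mapped,
            "n_unmapped": len(self.unmapped),
            "per_reference": {k: len(v) for k, v in self.mapped.items()},
        }


def build_kmer_index(reference: str, k: int = DEFAULT_K) -> frozenset[str]:
    """All k-mers of the reference and its reverse complement (no N k-mers)."""
    if k < 8:
        raise ValueError(f"k must be >= 8, got {k}")
    if len(reference) < k:
        raise ValueError(
            f"k={k} exceeds reference length {len(reference)}"
        )
    kmers = set()
    for seq in (reference, reverse_complement(reference)):
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" not in kmer:
                kmers.add(kmer)
    return frozenset(kmers)


def classify_read(
    read: ReadRecord,
    index: frozenset[str],
    k: int = DEFAULT_K,
    min_hits: int = DEFAULT_MIN_HITS,
) -> str:
    """'mapped' iff the read contains >= min_hits index k-mers.

    Reads shorter than k are unmapped by definition.
    """
    seq = read.seq
    hits = 0
    for i in range(len(seq) - k + 1):
        if seq[i:i + k] in index:
            hits += 1
            if hits >= min_hits:
                return "mapped"
    return "unmapped"


def triage_reads(
    reads: Sequence[ReadRecord],
    references: Mapping[str, str],
    k: int = DEFAULT_K,
    min_hits: int = DEFAULT_MIN_HITS,
) -> TriageResult:
    """Partition reads against one or more references.

    A read matching several references is assigned to the first one in
    mapping order and counted once. Duplicate read ids are an error: the
    partition invariant (mapped U unmapped = input, disjoint) would be
    ambiguous otherwise.
    """
    if not references:
        raise ValueError("at least one reference is required")
    seen: set[str] = set()
    for r in reads:
        if r.id in seen:
            raise ValueError(f"duplicate read id {r.id!r}")
        seen.add(r.id)
    indexes = {name: build_kmer_index(ref, k) for name, ref in references.items()}
    mapped: dict[str, list[str]] = {name: [] for name in references}
    unmapped: list[str] = []
    multi = 0
    for read in reads:
        hits = [
            name for name, idx in indexes.items()
            if classify_read(read, idx, k, min_hits) == "mapped"
        ]
        if hits:
            if len(hits) > 1:
                multi += 1
            mapped[hits[0]].append(read.id)
        else:
            unmapped.append(read.id)
    if multi:
        logger.info(
            "%d reads matched multiple references; assigned to first in order",
            multi,
        )
    return TriageResult(mapped=mapped, unmapped=unmapped, n_reads=len(reads))


def split_by_triage(
    reads: Sequence[ReadRecord], result: TriageResult
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Materialize (mapped_reads, unmapped_reads) from a TriageResult."""
    unmapped_ids = set(result.unmapped)
    unmapped = [r for r in reads if r.id in unmapped_ids]
    mapped = [r for r in reads if r.id not in unmapped_ids]
    return mapped, unmapped
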