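"""Motif-discovery input preparation.

After triage and tail trimming, unmapped reads are filtered for poly(A)
content, clustered by exact full-length identity, reduced to
representatives with at least ``min_copies`` identical copies, and
exported as FASTA for external de novo motif discovery (MEME). MEME
itself is never executed here; the recommended invocation (ZOOPS model,
motif width 35-40) is exposed as a string for the run log.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .read_profiles import find_runs
from .seqio import ReadRecord, write_fastx

logger = logging.getLogger(__name__)

DEFAULT_MIN_COPIES = 10
DEFAULT_MIN_POLYA_RUN = 10
MOTIF_WIDTH_RANGE = (35, 40)


@dataclass(frozen=True)
class Cluster:
    representative: str     # the sequence
    count: int
    member_ids: tuple[str, ...]


@dataclass
class ClusterTable:
    """Exact-identity clusters ordered by descending copy count."""

    clusters: list[Cluster]
    total_reads: int

    def counts(self) -> list[int]:
        return [c.count for c in self.clusters]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tcount\tlength\tsequence\n")
            for i, c in enumerate(self.clusters, start=1):
                fh.write(f"{i}\t{c.count}\t{len(c.representative)}\t"
                         f"{c.representative}\n")


def filter_polya(
    reads: Sequence[ReadRecord], min_run: int = DEFAULT_MIN_POLYA_RUN
) -> list[ReadRecord]:
    """Reads containing at least one A-run of length >= min_run."""
    if min_run < 1:
        raise ValueError(f"min_run must be >= 1, got {min_run}")
    return [
        r for r in reads
        if any(run.base == "A" for run in find_runs(r.seq, min_run))
    ]


def cluster_identical(reads: Sequence[ReadRecord]) -> ClusterTable:
    """Group reads by exact sequence identity.

    Clusters are ordered by descending copy count, ties broken by
    lexicographic representative, so output is deterministic.
    """
    groups: dict[str, list[str]] = defaultdict(list)
    for r in reads:
        groups[r.seq].append(r.id)
    clusters = [
        Cluster(seq, len(ids), tuple(ids)) for seq, ids in groups.items()
    ]
    clusters.sort(key=lambda c: (-c.count, c.representative))
    return ClusterTable(clusters=clusters, total_reads=len(reads))


def retain_min_copies(
    table: ClusterTable, min_copies: int = DEFAULT_MIN_COPIES
) -> list[Cluster]:
    """Clusters with at least ``min_copies`` identical copies, order kept."""
    if min_copies < 1:
        raise ValueError(f"min_copies must be >= 1, got {min_copies}")
    return [c for c in table.clusters if c.count >= min_copies]


def export_meme_fasta(retained: Sequence[Cluster], path: str | Path) -> int:
    """Write retained representatives as FASTA; ids encode copy counts.

    Record ids follow ``cluster{i}_n{count}`` with 1-based rank i. An
    empty retained set produces a valid empty file with a warning.
    Returns the number of records written.
    """
    if not retained:
        logger.warning("no clusters retained; writing empty FASTA to %s", path)
        Path(path).write_text("")
        return 0
    records = [
        ReadRecord(f"cluster{i}_n{c.count}", c.representative)
        for i, c in enumerate(retained, start=1)
    ]
    write_fastx(records, path, format="fasta")
    return len(records)


def meme_command(fasta_path: str | Path, out_dir: str = "meme_out") -> str:
    """Recommended external MEME invocation for the exported FASTA."""
    minw, maxw = MOTIF_WIDTH_RANGE
    return (
        f"meme {fasta_path} -dna -mod zoops -minw {minw} -maxw {maxw} "
        f"-oc {out_dir}"
    )


def prepare_meme_input(
    reads: Sequence[ReadRecord],
    path: str | Path,
    min_polya_run: int = DEFAULT_MIN_POLYA_RUN,
    min_copies: int = DEFAULT_MIN_COPIES,
) -> tuple[ClusterTable, list[Cluster]]:
    """Full filter -> cluster -> retain -> export chain.

    Returns the cluster table (of the poly(A)-filtered reads) and the
    retained clusters written to ``path``.
    """
    filtered = filter_polya(reads, min_polya_run)
    table = cluster_identical(filtered)
    retained = retain_min_copies(table, min_copies)
    n = export_meme_fasta(retained, path)
    logger.info(
        "meme input: %d/%d reads poly(A)-filtered, %d clusters, "
        "%d retained (>=%d copies) -> %s; suggested: %s",
        len(filtered), len(reads), len(table.clusters), n, min_copies,
        path, meme_command(path),
    )
    return table, retained
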