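"""ncRNA conservation profiling.

Workflow mirrored here: extract the region upstream of each ortholog
(strand-aware, since the ncRNA lies upstream of the RT gene), align
externally (MAFFT), strip the columns where the chosen reference carries a
gap so coordinates follow the reference ncRNA, then compute per-column
base frequencies and information content and scan for conserved tracts
such as the uracil tract in the ncRNA loop region.

Gap handling follows sequence-logo convention: gaps are excluded from the
frequency denominator and the gap fraction is reported separately.
Information content per column is ``2 + sum_b p_b log2 p_b`` bits (0 for
an all-gap column by convention), so a perfectly conserved column scores
2 bits and a uniform column 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import reverse_complement

logger = logging.getLogger(__name__)

PROFILE_BASES = ("A", "C", "G", "T")


@dataclass
class Alignment:
    """Ordered gapped records with a designated reference row."""

    records: list[tuple[str, str]]  # (id, gapped sequence over A,C,G,T,N,-)
    reference_id: str

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        if self.reference_id not in {rid for rid, _ in self.records}:
            raise ValueError(
                f"reference id {self.reference_id!r} absent from alignment"
            )

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    @property
    def reference_row(self) -> str:
        return next(s for rid, s in self.records if rid == self.reference_id)


def extract_upstream(
    genome: str,
    feature_start: int,
    feature_end: int,
    strand: str,
    length: int = 300,
) -> str:
    """Strand-aware upstream flank of a feature (0-based half-open coords).

    On '+' this is ``genome[start-length:start]``; on '-' the reverse
    complement of ``genome[end:end+length]``. The flank is truncated at
    contig edges with a warning.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if not (0 <= feature_start <= feature_end <= len(genome)):
        raise ValueError(
            f"feature [{feature_start}, {feature_end}) outside genome of "
            f"length {len(genome)}"
        )
    if strand == "+":
        lo = feature_start - length
        if lo < 0:
            logger.warning(
                "upstream flank truncated at contig start (%d < %d bp)",
                feature_start, length,
            )
            lo = 0
        return genome[lo:feature_start]
    hi = feature_end + length
    if hi > len(genome):
        logger.warning(
            "upstream flank truncated at contig end (%d < %d bp)",
            len(genome) - feature_end, length,
        )
        hi = len(genome)
    return reverse_complement(genome[feature_end:hi])


def strip_reference_gaps(aln: Alignment) -> Alignment:
    """Drop exactly the columns where the reference row has a gap.

    The output reference row is gap-free and the output column count
    equals the ungapped reference length. Idempotent.
    """
    ref = aln.reference_row
    keep = [j for j, c in enumerate(ref) if c != "-"]
    records = [
        (rid, "".join(seq[j] for j in keep)) for rid, seq in aln.records
    ]
    return Alignment(records=records, reference_id=aln.reference_id)


@dataclass
class ConservationMatrix:
    """Per-column base frequencies, gap fraction and information content."""

    freq: pd.DataFrame       # columns: A, C, G, T (non-gap denominators)
    gap_fraction: pd.Series
    information: pd.Series   # bits, in [0, 2]
    n_rows: int

    @property
    def n_columns(self) -> int:
        return len(self.freq)

    def consensus(self, rna: bool = False) -> str:
        letters = self.freq.idxmax(axis=1)
        s = "".join(letters)
        return s.replace("T", "U") if rna else s

    def to_tsv(self, path) -> None:
        out = self.freq.copy()
        out["gap_fraction"] = self.gap_fraction
        out["information_bits"] = self.information
        out.rename_axis("column").reset_index().to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )


def column_profile(aln: Alignment) -> ConservationMatrix:
    """Base frequencies and information content per alignment column.

    Frequencies are over non-gap symbols; N counts toward coverage but is
    spread over no base (it is excluded from the four-base denominator as
    well). All-gap columns get zero frequencies and IC 0 by convention.
    """
    arr = np.array([list(seq) for _, seq in aln.records], dtype="<U1")
    n_rows, n_cols = arr.shape
    counts = np.stack(
        [(arr == b).sum(axis=0) for b in PROFILE_BASES], axis=1
    ).astype(float)
    gaps = (arr == "-").sum(axis=0)
    denom = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(denom[:, None] > 0, counts / denom[:, None], 0.0)
    p = np.where(freq > 0, freq, 1.0)  # 0*log(0) = 0
    info = 2.0 + np.sum(freq * np.log2(p), axis=1)
    info = np.where(denom > 0, np.clip(info, 0.0, 2.0), 0.0)
    if (denom == 0).any():
        logger.warning(
            "%d all-gap column(s); IC set to 0 there", int((denom == 0).sum())
        )
    index = pd.RangeIndex(n_cols, name="column")
    return ConservationMatrix(
        freq=pd.DataFrame(freq, index=index, columns=list(PROFILE_BASES)),
        gap_fraction=pd.Series(gaps / n_rows, index=index, name="gap_fraction"),
        information=pd.Series(info, index=index, name="information_bits"),
        n_rows=n_rows,
    )


@dataclass(frozen=True)
class ConservedTract:
    start: int  # 0-based column, half-open interval [start, end)
    end: int
    consensus: str

    @property
    def length(self) -> int:
        return self.end - self.start


def conserved_tracts(
    matrix: ConservationMatrix,
    min_consensus: float = 0.95,
    min_len: int = 4,
    rna: bool = False,
) -> list[ConservedTract]:
    """Maximal runs of >= min_len columns whose top base reaches min_consensus.

    With ``rna=True`` consensus letters report T as U (display only).
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    top = matrix.freq.max(axis=1).to_numpy()
    letters = matrix.freq.idxmax(axis=1).to_numpy()
    qualifying = top >= min_consensus
    tracts = []
    j = 0
    n = len(qualifying)
    while j < n:
        if qualifying[j]:
            k = j
            while k < n and qualifying[k]:
                k += 1
            if k - j >= min_len:
                consensus = "".join(letters[j:k])
                if rna:
                    consensus = consensus.replace("T", "U")
                tracts.append(ConservedTract(j, k, consensus))
            j = k
        else:
            j += 1
    return tracts


def mafft_command(fasta_path: str) -> str:
    """Recommended external alignment invocation (not executed here)."""
    return f"mafft --auto {fasta_path} > aligned.fasta"
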