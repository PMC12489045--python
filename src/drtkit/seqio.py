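"""Readers and writers for the formats the pipeline touches.

FASTA/FASTQ parsing is delegated to Biopython; structures (mmCIF/PDB) to
gemmi. SAM is read directly at the line level because the unmapped-read
extraction must also accept headerless SAM fragments, and only the QNAME,
FLAG, SEQ and QUAL columns are consulted.

All sequences are normalized on input: uppercase, U -> T, and any character
outside {A, C, G, T, N} raises — corrupt input should surface early rather
than be silently masked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_NORMALIZE = str.maketrans("acgtunU", "ACGTTNT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SeqFormatError(ValueError):
    """Malformed sequence file or record."""


def normalize_seq(seq: str) -> str:
    """Uppercase, map U->T, and reject anything outside {A,C,G,T,N}."""
    s = seq.translate(_NORMALIZE)
    bad = set(s) - VALID_BASES
    if bad:
        raise SeqFormatError(
            f"sequence contains characters outside A/C/G/T/N: {sorted(bad)!r}"
        )
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: id, normalized sequence, optional qualities."""

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise SeqFormatError(f"read {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise SeqFormatError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Residue:
    """One residue reduced to its representative atom (CA or P)."""

    number: int
    name: str
    coord: tuple[float, float, float]


@dataclass
class StructureModel:
    """Chains of representative-atom coordinates, keyed by author chain id."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def chain_coords(self, chain_id: str) -> np.ndarray:
        return np.array([r.coord for r in self.chains[chain_id]], dtype=float)

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _detect_format(path: str | Path) -> str:
    with open(path) as fh:
        first = fh.read(1)
    if first in (">", ""):  # empty file parses as zero FASTA records
        return "fasta"
    if first == "@":
        return "fastq"
    raise SeqFormatError(
        f"{path}: cannot auto-detect format (first character {first!r})"
    )


def parse_fastx(path: str | Path) -> list[ReadRecord]:
    """Parse a FASTA or FASTQ file (auto-detected) into ReadRecords.

    Sequences are normalized; a malformed record raises SeqFormatError
    naming the 0-based record index.
    """
    fmt = _detect_format(path)
    out: list[ReadRecord] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
            try:
                qual = None
                if fmt == "fastq":
                    qual = "".join(
                        chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                    )
                out.append(ReadRecord(rec.id, normalize_seq(str(rec.seq)), qual))
            except SeqFormatError as exc:
                raise SeqFormatError(f"{path}: record {i}: {exc}") from exc
    except ValueError as exc:  # Biopython parse errors
        if isinstance(exc, SeqFormatError):
            raise
        raise SeqFormatError(f"{path}: record {len(out)}: {exc}") from exc
    return out


def write_fastx(
    records: Iterable[ReadRecord],
    path: str | Path,
    format: str = "fasta",
    wrap: int = 0,
    fill_qual: str | None = None,
) -> None:
    """Write records as FASTA or FASTQ; round-trips through parse_fastx.

    ``wrap`` > 0 line-wraps FASTA sequences. FASTQ output requires per-read
    qualities unless ``fill_qual`` supplies a fill character.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    seqrecords = []
    for rec in records:
        sr = SeqRecord(Seq(rec.seq), id=rec.id, description="")
        if format == "fastq":
            qual = rec.qual
            if qual is None:
                if fill_qual is None:
                    raise SeqFormatError(
                        f"read {rec.id!r} has no qualities; FASTQ output needs "
                        "a fill_qual character"
                    )
                qual = fill_qual * len(rec.seq)
            sr.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        seqrecords.append(sr)
    with open(path, "w") as fh:
        if format == "fasta":
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap or None)
            writer.write_file(seqrecords)
        else:
            SeqIO.write(seqrecords, fh, "fastq")


# ---------------------------------------------------------------------------
# SAM (minimal, read-only)

FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


def _iter_sam_fields(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise SeqFormatError(
                    f"{path}: line {lineno}: SAM record has "
                    f"{len(fields)} fields (< 11)"
                )
            yield lineno, fields


def parse_sam_unmapped(path: str | Path) -> list[ReadRecord]:
    """Extract unmapped reads (FLAG bit 0x4) from a SAM file.

    Secondary/supplementary records are ignored so each read appears once.
    If a record is flagged both unmapped and reverse-strand, the stored
    sequence is reverse-complemented back to original orientation
    (defensive; aligners normally leave unmapped reads unreversed).
    Works on headerless SAM.
    """
    out = []
    for lineno, fields in _iter_sam_fields(path):
        try:
            flag = int(fields[1])
        except ValueError:
            raise SeqFormatError(
                f"{path}: line {lineno}: non-integer FLAG {fields[1]!r}"
            ) from None
        if not flag & FLAG_UNMAPPED:
            continue
        if flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY):
            continue
        seq = normalize_seq(fields[9])
        qual = fields[10] if fields[10] != "*" else None
        if flag & FLAG_REVERSE:
            seq = reverse_complement(seq)
            if qual is not None:
                qual = qual[::-1]
        out.append(ReadRecord(fields[0], seq, qual))
    return out


def parse_sam_mapped_ids(path: str | Path) -> list[str]:
    """QNAMEs of primary mapped records (complement of parse_sam_unmapped)."""
    ids = []
    for _, fields in _iter_sam_fields(path):
        flag = int(fields[1])
        if flag & (FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_SUPPLEMENTARY):
            continue
        ids.append(fields[0])
    return ids


# ---------------------------------------------------------------------------
# Structures (mmCIF / PDB)

_NUCLEIC_NAMES = frozenset(
    {"A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU"}
)


def load_structure(path: str | Path) -> StructureModel:
    """Load a structure reduced to representative atoms.

    The representative atom is CA for amino acids and P for nucleotides;
    residues lacking it are skipped with a warning. Chains are keyed by
    author chain id; an empty selection is an error.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise SeqFormatError(f"{path}: cannot parse structure: {exc}") from exc
    model = StructureModel()
    if len(st) == 0:
        raise SeqFormatError(f"{path}: structure has no models")
    for chain in st[0]:
        residues = []
        for res in chain:
            atom_name = "P" if res.name.strip() in _NUCLEIC_NAMES else "CA"
            atom = res.find_atom(atom_name, "*")
            if atom is None:
                logger.warning(
                    "%s: chain %s residue %s%d lacks %s; skipped",
                    path, chain.name, res.name, res.seqid.num, atom_name,
                )
                continue
            residues.append(
                Residue(res.seqid.num, res.name,
                        (atom.pos.x, atom.pos.y, atom.pos.z))
            )
        if residues:
            model.chains.setdefault(chain.name, []).extend(residues)
    if not model.chains:
        raise SeqFormatError(f"{path}: no representative atoms found")
    for cid, residues in model.chains.items():
        nums = [r.number for r in residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise SeqFormatError(
                f"{path}: chain {cid}: residue numbers not strictly increasing"
            )
    return model


def write_structure_mmcif(model: StructureModel, path: str | Path,
                          name: str = "synthetic") -> None:
    """Write a StructureModel as mmCIF, one pseudo-CA ALA per residue."""
    st = gemmi.Structure()
    st.name = name
    gm = gemmi.Model("1")
    for cid, residues in model.chains.items():
        chain = gemmi.Chain(cid)
        for r in residues:
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(r.number, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*r.coord)
            res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.make_mmcif_document().write_file(str(path))


def read_alignment_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Aligned FASTA: (id, gapped sequence) pairs; gaps kept, bases normalized."""
    out = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        gapped = str(rec.seq)
        try:
            normalized = "".join(
                "-" if c == "-" else normalize_seq(c) for c in gapped
            )
        except SeqFormatError as exc:
            raise SeqFormatError(f"{path}: record {i}: {exc}") from exc
        out.append((rec.id, normalized))
    return out
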