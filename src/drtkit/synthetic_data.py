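"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the three data domains the pipeline analyses:

* protein-primed reverse-transcription read sets — a mixture of poly(dA)
  product reads (optionally carrying a 3' poly-C terminal-transferase tail)
  and contaminant reads drawn from a reference sequence, with substitution
  and N noise;
* planar oligomeric assemblies of idealized helices at specified inter-unit
  angles, the fixture for the tetramer/hexamer angle measurement;
* ncRNA homolog families mutated everywhere except a conserved tract.

All randomness flows from a single integer seed; per-read streams are
spawned deterministically so output is byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .seqio import ReadRecord, Residue, StructureModel

BASES = np.array(["A", "C", "G", "T"])

#: Uniform FASTQ quality character emitted by the simulator (qualities are
#: carried through the pipeline but never used by analysis stages).
SIM_QUALITY = "I"


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class ReadSimParams:
    """Parameters of the product/contaminant read mixture.

    Product reads are poly(dA) cores with geometric length (mean
    ``mu_core``), optionally extended by a 3' poly-C tail (probability
    ``p_tail``, geometric mean ``mu_tail``). Contaminant reads are
    fixed-length (``read_length_cap``) substrings of
    ``contaminant_reference``, emulating fixed-cycle sequencing of carryover
    DNA. Substitution noise ``sub_error_rate`` and ambiguous-base noise
    ``n_rate`` are applied per base after read assembly, so truth labels
    refer to the pre-noise structure.
    """

    n_reads: int = 10_000
    product_fraction: float = 0.8
    mu_core: float = 30.0
    p_tail: float = 0.3
    mu_tail: float = 8.0
    sub_error_rate: float = 0.01
    n_rate: float = 0.001
    contaminant_reference: str | None = None
    read_length_cap: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        _check_prob("product_fraction", self.product_fraction)
        _check_prob("p_tail", self.p_tail)
        _check_prob("sub_error_rate", self.sub_error_rate)
        _check_prob("n_rate", self.n_rate)
        if self.mu_core < 1:
            raise ValueError(f"mu_core must be >= 1, got {self.mu_core}")
        if self.mu_tail < 1:
            raise ValueError(f"mu_tail must be >= 1, got {self.mu_tail}")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.read_length_cap < 1:
            raise ValueError("read_length_cap must be >= 1")
        if self.product_fraction < 1.0 and not self.contaminant_reference:
            raise ValueError(
                "contaminant_reference required when product_fraction < 1"
            )
        if (self.contaminant_reference is not None
                and len(self.contaminant_reference) < self.read_length_cap):
            raise ValueError(
                "contaminant_reference shorter than read_length_cap"
            )


@dataclass(frozen=True)
class ReadTruth:
    label: str  # "product" | "contaminant"
    core_len: int
    tail_len: int


@dataclass
class LabeledReadSet:
    """Simulated reads plus per-read ground truth."""

    reads: list[ReadRecord]
    truth: list[ReadTruth]

    def __post_init__(self) -> None:
        if len(self.reads) != len(self.truth):
            raise ValueError("truth must have one entry per read")

    def truth_table(self) -> list[tuple[str, str, int, int]]:
        return [
            (r.id, t.label, t.core_len, t.tail_len)
            for r, t in zip(self.reads, self.truth)
        ]

    def write_truth_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tlabel\tcore_len\ttail_len\n")
            for row in self.truth_table():
                fh.write("\t".join(map(str, row)) + "\n")


def random_reference(length: int, seed: int = 0) -> str:
    """Uniform-composition random nucleotide sequence (contaminant stand-in)."""
    rng = np.random.default_rng(seed)
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _geometric(rng: np.random.Generator, mean: float) -> int:
    # support >= 1; mean `mean`
    return int(rng.geometric(1.0 / mean))


def _apply_noise(seq: np.ndarray, rng: np.random.Generator,
                 sub_rate: float, n_rate: float) -> np.ndarray:
    n = seq.size
    if sub_rate > 0:
        hit = rng.random(n) < sub_rate
        if hit.any():
            # replace with a uniformly chosen different base
            shifts = rng.integers(1, 4, size=int(hit.sum()))
            codes = np.searchsorted(BASES, seq[hit])
            seq = seq.copy()
            seq[hit] = BASES[(codes + shifts) % 4]
    if n_rate > 0:
        hit = rng.random(n) < n_rate
        if hit.any():
            seq = seq.copy()
            seq[hit] = "N"
    return seq


def simulate_product_read_set(params: ReadSimParams) -> LabeledReadSet:
    """Simulate a labeled mixture of poly(dA) product and contaminant reads."""
    ref = np.array(list(params.contaminant_reference or ""), dtype="<U1")
    streams = np.random.SeedSequence(params.seed).spawn(params.n_reads)
    reads: list[ReadRecord] = []
    truth: list[ReadTruth] = []
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        if rng.random() < params.product_fraction:
            core = min(_geometric(rng, params.mu_core), params.read_length_cap)
            tail = 0
            if rng.random() < params.p_tail:
                tail = min(_geometric(rng, params.mu_tail),
                           params.read_length_cap - core)
            seq = np.array(["A"] * core + ["C"] * tail, dtype="<U1")
            t = ReadTruth("product", core, tail)
        else:
            length = min(params.read_length_cap, ref.size)
            start = int(rng.integers(0, ref.size - length + 1))
            seq = ref[start:start + length]
            t = ReadTruth("contaminant", 0, 0)
        seq = _apply_noise(seq, rng, params.sub_error_rate, params.n_rate)
        reads.append(
            ReadRecord(f"sim_{i:06d}", "".join(seq), SIM_QUALITY * seq.size)
        )
        truth.append(t)
    return LabeledReadSet(reads, truth)


# ---------------------------------------------------------------------------
# Structural fixtures


@dataclass(frozen=True)
class HelixSimParams:
    """Ideal helix of pseudo-CA points.

    Defaults approximate an alpha helix (rise 1.5 A, 100 deg/residue,
    radius 2.3 A). Phases are centred on the helix midpoint so the
    principal-direction tilt of the finite spiral stays in a fixed plane
    (see the geometry methods note).
    """

    n_res: int = 20
    rise: float = 1.5
    twist: float = 100.0
    radius: float = 2.3
    orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_res < 3:
            raise ValueError(f"n_res must be >= 3, got {self.n_res}")
        nrm = float(np.linalg.norm(self.orientation))
        if not np.isclose(nrm, 1.0, atol=1e-6):
            raise ValueError(f"|orientation| must be 1, got {nrm}")


def _frame_for(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing a right-handed frame with `axis`."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(ref, axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def simulate_ideal_helix(params: HelixSimParams) -> np.ndarray:
    """(n_res, 3) pseudo-CA coordinates of an ideal helix."""
    axis = np.asarray(params.orientation, dtype=float)
    e1, e2 = _frame_for(axis)
    i = np.arange(params.n_res)
    t = (i - (params.n_res - 1) / 2) * params.rise
    phase = (i - (params.n_res - 1) / 2) * np.deg2rad(params.twist)
    # sin carries the spiral's nonzero cross-term with t (centred phases
    # cancel the cos term); keeping sin on e1 places the residual
    # principal-axis tilt in the axis-e1 plane, which simulate_planar_assembly
    # exploits to keep unit axes exactly in the assembly plane
    pts = (
        np.outer(t, axis)
        + params.radius * np.outer(np.sin(phase), e1)
        + params.radius * np.outer(np.cos(phase), e2)
    )
    return pts + np.asarray(params.origin, dtype=float)


@dataclass(frozen=True)
class AssemblySimParams:
    """Planar assembly of identical helical units at given adjacent angles.

    ``adjacent_angles[i]`` is the angle (degrees, in (0, 180)) between the
    directed axes of unit i and unit i+1, measured in the assembly plane.
    Unit centroids sit on a ring so centroid angular order matches unit
    order. The unit template uses a 90 deg twist (4 points per turn, full
    turns) so the assembly-plane normal is exact by symmetry.
    """

    n_units: int = 2
    adjacent_angles: tuple[float, ...] = (90.0,)
    helix: HelixSimParams = field(
        default_factory=lambda: HelixSimParams(twist=90.0)
    )
    ring_radius: float = 25.0
    in_plane: bool = True
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_units <= 6:
            raise ValueError("n_units must be in 2..6")
        if len(self.adjacent_angles) != self.n_units - 1:
            raise ValueError(
                f"need {self.n_units - 1} adjacent angles, "
                f"got {len(self.adjacent_angles)}"
            )
        for a in self.adjacent_angles:
            if not 0.0 < a < 180.0:
                raise ValueError(f"angles must be in (0, 180), got {a}")


_CHAIN_IDS = "ABCDEFGH"


def simulate_planar_assembly(params: AssemblySimParams) -> StructureModel:
    """Build a planar assembly; one chain per unit, axes in the xy plane."""
    template = simulate_ideal_helix(
        replace(params.helix, orientation=(1.0, 0.0, 0.0),
                origin=(0.0, 0.0, 0.0))
    )
    template = template - template.mean(axis=0)
    rng = np.random.default_rng(params.seed)
    cum = np.concatenate([[0.0], np.cumsum(params.adjacent_angles)])
    model = StructureModel()
    for k, ang in enumerate(cum):
        a = np.deg2rad(ang)
        rot = np.array([
            [np.cos(a), -np.sin(a), 0.0],
            [np.sin(a), np.cos(a), 0.0],
            [0.0, 0.0, 1.0],
        ])
        centroid = params.ring_radius * np.array([np.cos(a), np.sin(a), 0.0])
        pts = template @ rot.T + centroid
        if params.jitter_sd > 0:
            pts = pts + rng.normal(0.0, params.jitter_sd, size=pts.shape)
        model.chains[_CHAIN_IDS[k]] = [
            Residue(i + 1, "ALA", tuple(p)) for i, p in enumerate(pts)
        ]
    return model


# ---------------------------------------------------------------------------
# ncRNA family fixture


@dataclass
class NcrnaFamily:
    """Simulated homolog family plus the true alignment-column map.

    ``column_map[j]`` is the 0-based reference position of alignment column
    j, or None for columns inserted relative to the reference (reference
    gap columns).
    """

    records: list[tuple[str, str]]  # (id, gapped sequence)
    reference_id: str
    column_map: list[int | None]


def simulate_ncrna_family(
    reference: str,
    n_seqs: int,
    sub_rate: float,
    conserved_mask: Sequence[int] = (),
    n_insert_columns: int = 0,
    insert_present_prob: float = 0.5,
    seed: int = 0,
) -> NcrnaFamily:
    """Mutate a reference everywhere except masked positions.

    Masked positions (0-based) are never mutated; every other position is
    substituted i.i.d. with probability ``sub_rate`` (to a uniformly chosen
    different base). Optionally, ``n_insert_columns`` gap columns are
    inserted at random positions: the reference carries '-' there and each
    homolog carries a random base with probability ``insert_present_prob``
    (else '-'), mimicking insertions relative to the reference that
    reference-gap stripping must remove.
    """
    _check_prob("sub_rate", sub_rate)
    _check_prob("insert_present_prob", insert_present_prob)
    ref = np.array(list(reference), dtype="<U1")
    mask = np.zeros(ref.size, dtype=bool)
    for pos in conserved_mask:
        if not 0 <= pos < ref.size:
            raise ValueError(f"conserved position {pos} outside reference")
        mask[pos] = True
    rng = np.random.default_rng(seed)
    insert_at = sorted(
        rng.choice(ref.size + 1, size=n_insert_columns, replace=True)
    )
    column_map: list[int | None] = []
    ins_idx = 0
    for p in range(ref.size + 1):
        while ins_idx < len(insert_at) and insert_at[ins_idx] == p:
            column_map.append(None)
            ins_idx += 1
        if p < ref.size:
            column_map.append(p)

    records: list[tuple[str, str]] = []
    ref_row = "".join(
        "-" if cm is None else reference[cm] for cm in column_map
    )
    records.append(("reference", ref_row))
    codes = np.searchsorted(BASES, ref)
    for s in range(n_seqs):
        seq = ref.copy()
        hit = (rng.random(ref.size) < sub_rate) & ~mask
        if hit.any():
            shifts = rng.integers(1, 4, size=int(hit.sum()))
            seq[hit] = BASES[(codes[hit] + shifts) % 4]
        inserted = []
        for cm in column_map:
            if cm is None:
                if rng.random() < insert_present_prob:
                    inserted.append(str(BASES[rng.integers(0, 4)]))
                else:
                    inserted.append("-")
            else:
                inserted.append(str(seq[cm]))
        records.append((f"homolog_{s:04d}", "".join(inserted)))
    return NcrnaFamily(records, "reference", column_map)


def random_ncrna_reference(length: int = 188, seed: int = 0,
                           u_tract: tuple[int, int] | None = (123, 127)) -> str:
    """Random ncRNA-like reference (DNA alphabet) with an optional T tract.

    ``u_tract`` is a 0-based half-open interval forced to T, emulating the
    conserved uracil tract of the DRT9 ncRNA loop region.
    """
    rng = np.random.default_rng(seed)
    seq = BASES[rng.integers(0, 4, size=length)]
    if u_tract is not None:
        lo, hi = u_tract
        seq[lo:hi] = "T"
    return "".join(seq)
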