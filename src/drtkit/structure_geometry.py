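"""Inter-unit angle quantification for oligomeric assemblies.

A DRT9 "unit" is a head-to-head dimer of RT protomers; the substrate-free
tetramer is a dimer of such units at a ~90 deg inter-unit angle and the
substrate-bound hexamer is a trimer of units at ~120 deg. This module
measures that angle from atomic coordinates:

1. each unit gets a directed axis (first principal direction of its
   representative atoms, or of a designated helix residue range) and a
   centroid;
2. the assembly plane normal is the direction of least variance of all
   representative atoms (the "top view" direction);
3. adjacent units — consecutive in angular order of centroids about the
   normal — are compared by the angle between their directed axes after
   projection onto the assembly plane.

Angles are directed (in [0, 180] deg) so the obtuse 120 deg hexamer
geometry is representable; an undirected convention would fold it to 60.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .seqio import StructureModel

logger = logging.getLogger(__name__)

#: Classification windows (degrees) centred on the tetramer/hexamer values.
TETRAMER_WINDOW = (75.0, 105.0)   # [75, 105)
HEXAMER_WINDOW = (105.0, 135.0)   # [105, 135]


@dataclass(frozen=True)
class UnitDefinition:
    """Chains composing one dimer unit, plus how to derive its axis.

    ``axis_mode='unit_pca'`` uses all representative atoms of the unit's
    chains; ``'helix'`` restricts to ``helix_range = (chain_id, start,
    end)`` (inclusive residue numbers), e.g. an alpha-10 helix span read
    off the deposited model.
    """

    name: str
    chains: tuple[str, ...]
    axis_mode: str = "unit_pca"
    helix_range: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError(f"unit {self.name!r}: needs >= 1 chain")
        if self.axis_mode not in ("unit_pca", "helix"):
            raise ValueError(f"unknown axis_mode {self.axis_mode!r}")
        if self.axis_mode == "helix":
            if self.helix_range is None:
                raise ValueError(
                    f"unit {self.name!r}: helix mode needs helix_range"
                )
            _, start, end = self.helix_range
            if end - start + 1 < 5:
                raise ValueError(
                    f"unit {self.name!r}: helix range must span >= 5 residues"
                )


@dataclass(frozen=True)
class UnitFrame:
    """Centroid + directed unit axis of one dimer unit."""

    centroid: np.ndarray
    axis: np.ndarray
    collinearity: float  # fraction of variance on the first principal direction


def fit_axis(coords: np.ndarray) -> UnitFrame:
    """Directed principal axis of an ordered coordinate set.

    The axis is the first principal direction of the centered points, with
    sign chosen so that axis . (last - first point) > 0 — i.e. N-to-C for
    a protein chain in residue order.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n, 3)")
    if coords.shape[0] < 5:
        raise ValueError(f"need >= 5 points, got {coords.shape[0]}")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 1e-12:
        raise ValueError("degenerate coordinates (zero variance)")
    axis = vt[0]
    span = coords[-1] - coords[0]
    if axis @ span < 0:
        axis = -axis
    collinearity = float(s[0] ** 2 / np.sum(s ** 2))
    return UnitFrame(centroid=centroid, axis=axis, collinearity=collinearity)


def assembly_plane_normal(coords: np.ndarray) -> np.ndarray:
    """Direction of least variance of the pooled assembly coordinates.

    Sign is canonicalized so the first nonzero component is positive.
    A near-isotropic cloud (no preferred plane) is an error.
    """
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # the plane is well defined only if the smallest variance direction is
    # clearly separated from the middle one
    if s[1] <= 1e-12 or s[2] > 0.9 * s[1]:
        raise ValueError("isotropic or degenerate cloud: plane undefined")
    normal = vt[-1]
    for comp in normal:
        if abs(comp) > 1e-12:
            if comp < 0:
                normal = -normal
            break
    return normal


def projected_inter_unit_angle(
    a: UnitFrame, b: UnitFrame, normal: np.ndarray
) -> float:
    """Angle (degrees, [0, 180]) between directed axes projected in-plane."""
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    pa = a.axis - (a.axis @ normal) * normal
    pb = b.axis - (b.axis @ normal) * normal
    na, nb = np.linalg.norm(pa), np.linalg.norm(pb)
    if na < 1e-6 or nb < 1e-6:
        raise ValueError("unit axis is perpendicular to the assembly plane")
    cosang = np.clip(pa @ pb / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


@dataclass
class AssemblyAngleReport:
    """Frames, plane, adjacent projected angles and classification."""

    frames: dict[str, UnitFrame]
    normal: np.ndarray
    adjacent_pairs: list[tuple[str, str]]
    adjacent_angles: list[float]
    classification: str  # tetramer_like | hexamer_like | other

    @property
    def median_angle(self) -> float:
        return float(np.median(self.adjacent_angles))

    def to_json(self, path=None) -> str:
        payload = {
            "units": {
                name: {
                    "centroid": [round(x, 4) for x in f.centroid],
                    "axis": [round(x, 6) for x in f.axis],
                    "collinearity": round(f.collinearity, 6),
                }
                for name, f in self.frames.items()
            },
            "plane_normal": [round(x, 6) for x in self.normal],
            "adjacent_pairs": [list(p) for p in self.adjacent_pairs],
            "adjacent_angles_deg": [round(a, 4) for a in self.adjacent_angles],
            "median_angle_deg": round(self.median_angle, 4),
            "classification": self.classification,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def classify_angle(median_angle: float) -> str:
    if TETRAMER_WINDOW[0] <= median_angle < TETRAMER_WINDOW[1]:
        return "tetramer_like"
    if HEXAMER_WINDOW[0] <= median_angle <= HEXAMER_WINDOW[1]:
        return "hexamer_like"
    return "other"


def _unit_coords(structure: StructureModel, unit: UnitDefinition) -> np.ndarray:
    missing = [c for c in unit.chains if c not in structure.chains]
    if missing:
        raise ValueError(
            f"unit {unit.name!r}: chain(s) {missing} not in structure"
        )
    return np.vstack([structure.chain_coords(c) for c in unit.chains])


def _axis_coords(structure: StructureModel, unit: UnitDefinition) -> np.ndarray:
    if unit.axis_mode == "unit_pca":
        return _unit_coords(structure, unit)
    chain_id, start, end = unit.helix_range
    if chain_id not in structure.chains:
        raise ValueError(
            f"unit {unit.name!r}: helix chain {chain_id!r} not in structure"
        )
    sel = [
        r.coord for r in structure.chains[chain_id]
        if start <= r.number <= end
    ]
    if len(sel) < 5:
        raise ValueError(
            f"unit {unit.name!r}: helix range {chain_id}:{start}-{end} "
            f"selects only {len(sel)} residues"
        )
    return np.asarray(sel, dtype=float)


def assembly_report(
    structure: StructureModel, units: Sequence[UnitDefinition]
) -> AssemblyAngleReport:
    """Measure adjacent inter-unit angles of an assembly and classify it.

    Adjacency is defined by the angular order of unit centroids about the
    assembly plane normal; for more than two units the order is treated as
    cyclic (ring adjacency), for exactly two units there is one pair.
    """
    if len(units) < 2:
        raise ValueError("need >= 2 units")
    frames = {}
    for u in units:
        axis_frame = fit_axis(_axis_coords(structure, u))
        frames[u.name] = UnitFrame(
            centroid=_unit_coords(structure, u).mean(axis=0),
            axis=axis_frame.axis,
            collinearity=axis_frame.collinearity,
        )
    all_coords = np.vstack([_unit_coords(structure, u) for u in units])
    normal = assembly_plane_normal(all_coords)

    # angular order of centroids about the normal
    center = np.mean([f.centroid for f in frames.values()], axis=0)
    e1_ref = None
    names = list(frames)
    azimuth = {}
    for name in names:
        v = frames[name].centroid - center
        v = v - (v @ normal) * normal
        if e1_ref is None:
            nv = np.linalg.norm(v)
            e1_ref = v / nv if nv > 1e-9 else _any_perpendicular(normal)
        e2_ref = np.cross(normal, e1_ref)
        azimuth[name] = float(np.arctan2(v @ e2_ref, v @ e1_ref))
    ordered = sorted(names, key=lambda n: azimuth[n])

    if len(ordered) == 2:
        pairs = [(ordered[0], ordered[1])]
    else:
        pairs = [
            (ordered[i], ordered[(i + 1) % len(ordered)])
            for i in range(len(ordered))
        ]
    angles = [
        projected_inter_unit_angle(frames[a], frames[b], normal)
        for a, b in pairs
    ]
    report = AssemblyAngleReport(
        frames=frames,
        normal=normal,
        adjacent_pairs=pairs,
        adjacent_angles=angles,
        classification=classify_angle(float(np.median(angles))),
    )
    logger.info(
        "assembly: %d units, adjacent angles %s, classified %s",
        len(units), [f"{a:.2f}" for a in angles], report.classification,
    )
    return report


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(v @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    w = np.cross(v, ref)
    return w / np.linalg.norm(w)


def default_units(structure: StructureModel,
                  chains_per_unit: int = 1) -> list[UnitDefinition]:
    """Group consecutive chains into units (fallback when none configured)."""
    chain_ids = list(structure.chains)
    if len(chain_ids) % chains_per_unit:
        raise ValueError(
            f"{len(chain_ids)} chains not divisible into units of "
            f"{chains_per_unit}"
        )
    return [
        UnitDefinition(
            name=f"unit{i // chains_per_unit + 1}",
            chains=tuple(chain_ids[i:i + chains_per_unit]),
        )
        for i in range(0, len(chain_ids), chains_per_unit)
    ]


def parse_units_spec(spec: str) -> list[UnitDefinition]:
    """Parse a CLI units spec like ``"A+A',B+B'"`` into UnitDefinitions."""
    units = []
    for i, group in enumerate(spec.split(","), start=1):
        chains = tuple(c.strip() for c in group.split("+") if c.strip())
        if not chains:
            raise ValueError(f"empty unit group in spec {spec!r}")
        units.append(UnitDefinition(name=f"unit{i}", chains=chains))
    return units
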