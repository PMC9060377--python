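"""Structure-derived residue descriptors in a membrane frame.

The coordinate model must arrive pre-oriented (OPM-style): membrane normal
along z, membrane mid-plane at z = 0.  Each residue is reduced to one
representative point — the side-chain heavy-atom centroid, falling back to the
alpha-carbon for glycine or residues without side-chain coordinates.  Four
geometric descriptors are computed from these points:

* distance from the channel pore axis (separates pore-domain from
  voltage-sensor-domain sites),
* membrane burial: a depth-dependent weight in [0, 1] from a three-layer slab
  model (hydrophobic core, polar interface, solution),
* functional density: inverse-distance-weighted average of an amino-acid
  property over the residues within a radius of the site,
* neighbor vector: solvent exposure as the norm of the weighted mean of unit
  vectors toward neighbors (0 = evenly surrounded/buried, 1 = one-sided or
  isolated/exposed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .aatables import PropertyTable


class StructureError(ValueError):
    """Unresolved position, malformed coordinates, or frame inconsistency."""


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class StructureModel:
    """Residue representative points in the membrane frame plus a pore axis."""

    positions: np.ndarray          # (n,) int residue numbers, unique
    wt_aas: np.ndarray             # (n,) one-letter codes
    points: np.ndarray             # (n, 3) float Angstroms
    axis_point: np.ndarray = None  # point on the pore axis
    axis_dir: np.ndarray = None    # unit direction of the pore axis

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=int)
        self.wt_aas = np.asarray(self.wt_aas, dtype=object)
        self.points = np.asarray(self.points, dtype=float)
        if len(set(self.positions.tolist())) != len(self.positions):
            raise StructureError("residue positions must be unique")
        if not np.all(np.isfinite(self.points)):
            raise StructureError("non-finite coordinates")
        if self.axis_point is None:
            # default pore axis: z through the x-y centroid of all points
            c = self.points.mean(axis=0)
            self.axis_point = np.array([c[0], c[1], 0.0])
        if self.axis_dir is None:
            self.axis_dir = np.array([0.0, 0.0, 1.0])
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        d = np.asarray(self.axis_dir, dtype=float)
        self.axis_dir = d / np.linalg.norm(d)
        self._index = {int(p): i for i, p in enumerate(self.positions)}

    def __len__(self) -> int:
        return len(self.positions)

    def index_of(self, position: int) -> int:
        try:
            return self._index[int(position)]
        except KeyError:
            raise StructureError(f"position {position} not resolved in structure") from None

    def wt_aa(self, position: int) -> str:
        return str(self.wt_aas[self.index_of(position)])

    def point(self, position: int) -> np.ndarray:
        return self.points[self.index_of(position)]

    def resolved_positions(self) -> list[tuple[int, str]]:
        return [(int(p), str(a)) for p, a in zip(self.positions, self.wt_aas)]

    def set_pore_axis_from_residues(self, positions: list[int]) -> None:
        """Re-anchor the pore axis at the x-y centroid of pore-lining residues."""
        pts = np.array([self.point(p) for p in positions])
        c = pts.mean(axis=0)
        self.axis_point = np.array([c[0], c[1], 0.0])
        self.axis_dir = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class MembraneModel:
    """Three-layer slab: full weight over the hydrophobic core, half-cosine
    decay across each polar interface, zero in solution."""

    core_half_thickness: float = 15.0  # Angstrom
    interface_thickness: float = 5.0   # Angstrom

    def __post_init__(self):
        if self.core_half_thickness <= 0 or self.interface_thickness <= 0:
            raise StructureError("membrane layer thicknesses must be positive")

    def weight(self, z: float) -> float:
        a = abs(float(z))
        if a <= self.core_half_thickness:
            return 1.0
        b = a - self.core_half_thickness
        if b >= self.interface_thickness:
            return 0.0
        return 0.5 * (1.0 + math.cos(math.pi * b / self.interface_thickness))


def read_structure(
    path: str | Path,
    chains: list[str] | None = None,
    representative: str = "sidechain_centroid",
) -> StructureModel:
    """Read a PDB/mmCIF file (first model) into a StructureModel.

    ``representative`` is ``sidechain_centroid`` (default; Calpha fallback for
    glycine or missing side chains) or ``cbeta`` (Calpha fallback).  Residue
    numbering is taken verbatim from the file.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    model = st[0]
    positions, aas, points = [], [], []
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for res in chain:
            one = THREE_TO_ONE.get(res.name)
            if one is None:
                continue  # waters, ligands, modified residues
            pt = _representative_point(res, representative)
            if pt is None:
                continue
            positions.append(res.seqid.num)
            aas.append(one)
            points.append(pt)
    if not positions:
        raise StructureError(f"no protein residues read from {path}")
    return StructureModel(np.array(positions), np.array(aas, dtype=object), np.array(points))


def _representative_point(res: gemmi.Residue, mode: str) -> np.ndarray | None:
    ca = None
    side = []
    cb = None
    for atom in res:
        if atom.is_hydrogen():
            continue
        if atom.name == "CA":
            ca = atom.pos
        elif atom.name == "CB":
            cb = atom.pos
        if atom.name not in _BACKBONE_ATOMS:
            side.append(atom.pos)
    if mode == "cbeta":
        pos = cb if cb is not None else ca
        return np.array([pos.x, pos.y, pos.z]) if pos is not None else None
    if side:
        arr = np.array([[p.x, p.y, p.z] for p in side])
        return arr.mean(axis=0)
    if ca is not None:
        return np.array([ca.x, ca.y, ca.z])
    return None


def pore_axis_distance(structure: StructureModel, position: int) -> float:
    """Perpendicular distance (Angstrom) of a residue's point from the pore axis."""
    v = structure.point(position) - structure.axis_point
    return float(np.linalg.norm(v - np.dot(v, structure.axis_dir) * structure.axis_dir))


def membrane_burial(
    structure: StructureModel, position: int, membrane: MembraneModel | None = None
) -> float:
    """Depth-dependent membrane weight in [0, 1] from the slab model."""
    membrane = membrane or MembraneModel()
    return membrane.weight(structure.point(position)[2])


#: Distance floor (Angstrom) bounding the inverse-distance weight in
#: functional density.
FD_DISTANCE_FLOOR = 1.0


def functional_density(
    structure: StructureModel,
    position: int,
    table: PropertyTable,
    property_name: str,
    radius: float,
    mutant_aa: str | None = None,
) -> float:
    """Inverse-distance-weighted property average over neighbors within radius.

    Neighbors are every resolved residue other than the site whose
    representative point lies within ``radius`` of the site's; weights are
    1/d with d floored at 1 Angstrom.  An empty neighborhood (e.g. the 1 A
    radius) falls back to the property of the residue placed at the site —
    the mutant residue, so the tightest-radius densities track the
    substitution itself.
    """
    if radius <= 0:
        raise StructureError("radius must be positive")
    i = structure.index_of(position)
    if mutant_aa is None:
        mutant_aa = str(structure.wt_aas[i])
    d = np.linalg.norm(structure.points - structure.points[i], axis=1)
    mask = (d <= radius) & (np.arange(len(structure)) != i)
    if not mask.any():
        return table.get(mutant_aa, property_name)
    w = 1.0 / np.maximum(d[mask], FD_DISTANCE_FLOOR)
    props = np.array([table.get(str(a), property_name) for a in structure.wt_aas[mask]])
    return float(np.sum(w * props) / np.sum(w))


#: Smooth neighbor-weight bounds (Angstrom): weight 1 at or below the lower
#: bound, 0 at or above the upper bound, half-cosine in between.
NV_LOWER = 3.3
NV_UPPER = 11.4


def _nv_weight(d: np.ndarray) -> np.ndarray:
    w = np.zeros_like(d)
    w[d <= NV_LOWER] = 1.0
    mid = (d > NV_LOWER) & (d < NV_UPPER)
    w[mid] = 0.5 * (1.0 + np.cos(np.pi * (d[mid] - NV_LOWER) / (NV_UPPER - NV_LOWER)))
    return w


def neighbor_vector(structure: StructureModel, position: int) -> float:
    """Solvent exposure in [0, 1]: norm of the weighted mean unit vector to neighbors."""
    i = structure.index_of(position)
    rel = structure.points - structure.points[i]
    d = np.linalg.norm(rel, axis=1)
    mask = (d < NV_UPPER) & (np.arange(len(structure)) != i) & (d > 0)
    if not mask.any():
        return 1.0
    w = _nv_weight(d[mask])
    units = rel[mask] / d[mask, None]
    num = np.linalg.norm(np.sum(w[:, None] * units, axis=0))
    return float(min(1.0, num / np.sum(w)))
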