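"""Structural features and reactive-like criteria.

Features are evaluated on a single frame of coordinates, shape
``(n_atoms, 3)`` in Angstrom.  Four feature kinds are supported:

* ``distance(i, j)`` -- Angstrom;
* ``angle(i, j, k)`` -- vertex at j, degrees in [0, 180];
* ``dihedral(i, j, k, l)`` -- degrees; by default the absolute torsion
  magnitude in [0, 180] (a signed mode exists for diagnostics);
* ``min_dihedral(i, j, k, H-set)`` -- the minimum absolute dihedral over a
  set of candidate atoms (e.g. the hydrogens bound to a carbon), the
  convention used for tracking eclipsed conformations.

Three boolean reactive-like criteria are evaluated per frame from an
atom-role map (thresholds strict, "less than"):

* hydrogen bond: donor-H -> acceptor distance < 2.3 A, donor-axis angle
  within 30 deg of 180, acceptor-carbonyl angle within 30 deg of 120;
* rotated side chain: angle between two undirected axes < 75 deg
  (folded into [0, 90] since the axes are undirected);
* eclipsed center: minimum hydrogen dihedral < 30 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "FeatureDef",
    "FeatureSchema",
    "CriterionReport",
    "UndefinedGeometryError",
    "compute_lambda",
    "distance",
    "angle",
    "dihedral",
    "min_dihedral",
    "axis_angle",
    "compute_features",
    "compute_feature_matrix",
    "evaluate_criteria",
    "criterion_population",
    "read_pdb_coordinates",
]

HBOND_DISTANCE_MAX = 2.3      # A, strict <
HBOND_DONOR_ANGLE_TARGET = 180.0   # deg, within 30
HBOND_ACCEPTOR_ANGLE_TARGET = 120.0  # deg, within 30
HBOND_ANGLE_TOL = 30.0
ROTATED_AXIS_ANGLE_MAX = 75.0  # deg, strict <
ECLIPSED_DIHEDRAL_MAX = 30.0   # deg, strict <


class UndefinedGeometryError(ValueError):
    """Coincident atoms or collinear rays make a feature undefined."""


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def distance(frame: np.ndarray, i: int, j: int) -> float:
    d = np.asarray(frame)[i] - np.asarray(frame)[j]
    r = float(np.linalg.norm(d))
    if r == 0.0:
        raise UndefinedGeometryError(f"coincident atoms {i}, {j}")
    return r


def compute_lambda(frame: np.ndarray, breaking: tuple[int, int],
                   forming: tuple[int, int]) -> float:
    """Order parameter: breaking-bond length minus forming-bond length (A)."""
    return distance(frame, *breaking) - distance(frame, *forming)


def angle(frame: np.ndarray, i: int, j: int, k: int) -> float:
    """Angle i-j-k at vertex j, degrees in [0, 180]."""
    frame = np.asarray(frame)
    u = frame[i] - frame[j]
    v = frame[k] - frame[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise UndefinedGeometryError("zero-length ray for angle")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def dihedral(frame: np.ndarray, i: int, j: int, k: int, l: int,
             signed: bool = False) -> float:
    """Torsion i-j-k-l, degrees; |value| in [0, 180] unless signed."""
    frame = np.asarray(frame)
    b1 = frame[j] - frame[i]
    b2 = frame[k] - frame[j]
    b3 = frame[l] - frame[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) == 0.0 or np.linalg.norm(n2) == 0.0:
        raise UndefinedGeometryError("collinear atoms for dihedral")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return ang if signed else abs(ang)


def min_dihedral(frame: np.ndarray, i: int, j: int, k: int,
                 h_set: Sequence[int]) -> float:
    """Minimum absolute dihedral i-j-k-h over candidate atoms h."""
    if not len(h_set):
        raise UndefinedGeometryError("empty hydrogen set")
    return min(dihedral(frame, i, j, k, h) for h in h_set)


def axis_angle(frame: np.ndarray, axis1: tuple[int, int],
               axis2: tuple[int, int]) -> float:
    """Angle between two undirected axes, folded into [0, 90] degrees."""
    frame = np.asarray(frame)
    u = frame[axis1[1]] - frame[axis1[0]]
    v = frame[axis2[1]] - frame[axis2[0]]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise UndefinedGeometryError("zero-length axis")
    c = np.clip(abs(np.dot(u, v)) / (nu * nv), 0.0, 1.0)
    return float(np.degrees(np.arccos(c)))


# ---------------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureDef:
    name: str
    kind: str                 # distance | angle | dihedral | min_dihedral
    atoms: tuple              # indices; for min_dihedral: (i, j, k)
    h_set: tuple = ()         # candidate atoms for min_dihedral

    def evaluate(self, frame: np.ndarray, signed_dihedrals: bool = False) -> float:
        if self.kind == "distance":
            return distance(frame, *self.atoms)
        if self.kind == "angle":
            return angle(frame, *self.atoms)
        if self.kind == "dihedral":
            return dihedral(frame, *self.atoms, signed=signed_dihedrals)
        if self.kind == "min_dihedral":
            return min_dihedral(frame, *self.atoms, h_set=self.h_set)
        raise ValueError(f"unknown feature kind {self.kind!r}")


@dataclass
class FeatureSchema:
    """Ordered, uniquely named feature definitions."""

    features: list[FeatureDef] = field(default_factory=list)

    def __post_init__(self):
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __len__(self):
        return len(self.features)

    def max_atom_index(self) -> int:
        idx = 0
        for f in self.features:
            idx = max(idx, max(f.atoms), max(f.h_set, default=0))
        return idx

    def to_yaml(self) -> str:
        rows = [{"name": f.name, "kind": f.kind, "atoms": list(f.atoms),
                 **({"h_set": list(f.h_set)} if f.h_set else {})}
                for f in self.features]
        return yaml.safe_dump({"features": rows}, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "FeatureSchema":
        data = yaml.safe_load(text)
        feats = [FeatureDef(r["name"], r["kind"], tuple(r["atoms"]),
                            tuple(r.get("h_set", ()))) for r in data["features"]]
        return cls(feats)


def compute_features(frame: np.ndarray, schema: FeatureSchema,
                     signed_dihedrals: bool = False) -> np.ndarray:
    """Feature vector aligned to schema order (A / degrees)."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[1] != 3:
        raise ValueError("frame must have shape (n_atoms, 3)")
    if schema.max_atom_index() >= frame.shape[0]:
        raise ValueError("schema indices exceed frame size")
    return np.array([f.evaluate(frame, signed_dihedrals) for f in schema.features])


def compute_feature_matrix(frames: np.ndarray, schema: FeatureSchema) -> np.ndarray:
    """Stack feature vectors for frames of shape (m, n_atoms, 3) or flat
    (m, 3*n_atoms)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames.reshape(frames.shape[0], -1, 3)
    return np.array([compute_features(f, schema) for f in frames])


# ---------------------------------------------------------------------------
# reactive-like criteria
# ---------------------------------------------------------------------------

@dataclass
class CriterionReport:
    """Booleans per frame; None when the role map omits a criterion's atoms."""

    hbond_present: bool | None
    rotated: bool | None
    eclipsed: bool | None


def _hbond(frame, roles) -> bool | None:
    needed = ("donor_heavy", "donor_h", "acceptor", "acceptor_antecedent")
    if not all(r in roles for r in needed):
        return None
    dh, h, a, c = (roles[r] for r in needed)
    d = distance(frame, h, a)
    donor_axis = angle(frame, dh, h, a)       # N-H...O, near 180 when linear
    acceptor_ang = angle(frame, h, a, c)      # H...O=C
    return (d < HBOND_DISTANCE_MAX
            and abs(donor_axis - HBOND_DONOR_ANGLE_TARGET) < HBOND_ANGLE_TOL
            and abs(acceptor_ang - HBOND_ACCEPTOR_ANGLE_TARGET) < HBOND_ANGLE_TOL)


def _rotated(frame, roles) -> bool | None:
    if "rotated_axis1" not in roles or "rotated_axis2" not in roles:
        return None
    a = axis_angle(frame, tuple(roles["rotated_axis1"]),
                   tuple(roles["rotated_axis2"]))
    return a < ROTATED_AXIS_ANGLE_MAX


def _eclipsed(frame, roles) -> bool | None:
    quads = roles.get("eclipsed_quads")
    if not quads:
        return None
    best = min(min_dihedral(frame, i, j, k, h_set=hs) for (i, j, k, hs) in quads)
    return best < ECLIPSED_DIHEDRAL_MAX


def evaluate_criteria(frame: np.ndarray, roles: dict) -> CriterionReport:
    """Evaluate the three reactive-like criteria on one frame.

    ``roles`` maps role names to atom indices: donor_heavy, donor_h, acceptor,
    acceptor_antecedent (hydrogen bond); rotated_axis1/rotated_axis2 as index
    pairs; eclipsed_quads as a list of (i, j, k, h_set) tuples.  Missing roles
    disable the corresponding criterion (reported as None).
    """
    frame = np.asarray(frame, dtype=float)
    return CriterionReport(
        hbond_present=_hbond(frame, roles),
        rotated=_rotated(frame, roles),
        eclipsed=_eclipsed(frame, roles),
    )


def criterion_population(frames: np.ndarray, roles: dict,
                         weights: np.ndarray | None = None,
                         reference: dict | None = None) -> dict:
    """Weighted fraction of frames meeting each criterion.

    Returns {criterion: fraction} (None for disabled criteria); with a
    ``reference`` dict of fractions, each value is additionally normalized as
    fraction / reference_fraction under key ``<criterion>_normalized``.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames.reshape(frames.shape[0], -1, 3)
    m = frames.shape[0]
    if weights is None:
        weights = np.ones(m)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() == 0:
        raise ValueError("weights must be nonnegative with positive total")
    acc = {"hbond_present": 0.0, "rotated": 0.0, "eclipsed": 0.0}
    enabled = {k: True for k in acc}
    for f, w in zip(frames, weights):
        rep = evaluate_criteria(f, roles)
        for k in acc:
            val = getattr(rep, k)
            if val is None:
                enabled[k] = False
            elif val:
                acc[k] += w
    total = weights.sum()
    out = {k: (acc[k] / total if enabled[k] else None) for k in acc}
    if reference is not None:
        for k in list(out):
            ref = reference.get(k)
            if out[k] is not None and ref:
                out[k + "_normalized"] = out[k] / ref
    return out


def read_pdb_coordinates(path) -> tuple[np.ndarray, "pandas.DataFrame"]:
    """Read one PDB model: (coords (n_atoms, 3), atom table).

    The table preserves the file's 1-based residue numbering (columns: serial,
    name, resname, chain, resseq).
    """
    import pandas as pd
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    rows, xyz = [], []
    for chain in model:
        for res in chain:
            for atom in res:
                rows.append({
                    "serial": atom.serial_number,
                    "name": atom.get_name(),
                    "resname": res.get_resname(),
                    "chain": chain.id,
                    "resseq": res.id[1],
                })
                xyz.append(atom.coord)
    return np.asarray(xyz, dtype=float), pd.DataFrame(rows)
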