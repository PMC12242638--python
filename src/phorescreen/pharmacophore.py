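"""Pharmacophore models, 3D ligand feature perception and consensus maps.

A pharmacophore model is a named set of typed 3D points — hydrogen-bond
acceptor (HBA), hydrogen-bond donor (HBD) or aromatic-ring center — each
with a tolerance radius (Å) and a dimensionless weight, optionally
accompanied by a protein hydrogen-bond constraint (e.g. the backbone amide
H of the kinase hinge methionine).

Two four-point models for the ATP sites of ROCK1 (frame of PDB 6E9W) and
ROCK2 (frame of PDB 7JNT) ship as built-ins: a tight hinge acceptor
(weight 10), a catalytic-lysine acceptor, a hinge aromatic-ring center and
an affinity-pocket aromatic-ring center (weight 5 each), plus the
mandatory hinge H-bond constraint (MET156:H / MET172:H).

Consensus elucidation groups same-kind features across pre-aligned ligand
poses by single linkage and emits a point wherever a group is supported by
a sufficient fraction of the ligands.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np


class FeatureKind(str, Enum):
    """Closed set of pharmacophoric feature types."""

    HBA = "HBA"
    HBD = "HBD"
    AromaticRing = "AromaticRing"


@dataclass(frozen=True)
class LigandFeature:
    """A perceived 3D feature of one ligand conformer.

    Aromatic-ring positions are the unweighted centroid of the ring atoms;
    acceptor/donor positions sit on the heavy atom.
    """

    kind: FeatureKind
    position: tuple[float, float, float]
    source_atom_indices: tuple[int, ...] = ()

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass(frozen=True)
class PharmacophorePoint:
    """One typed model point: center (Å), tolerance radius, score weight."""

    kind: FeatureKind
    center: tuple[float, float, float]
    radius: float
    weight: float
    label: str

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"point {self.label!r}: radius must be > 0")
        if self.weight <= 0:
            raise ValueError(f"point {self.label!r}: weight must be > 0")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass(frozen=True)
class HBondConstraint:
    """Protein H-bond requirement (donor H atom descriptor, e.g. MET156:H)."""

    chain: str
    resnum: int
    atom: str
    weight: float
    min_geometry_weight: float = 0.005
    # resolved donor geometry, when known (model frame, Å)
    h_position: Optional[tuple[float, float, float]] = None
    donor_position: Optional[tuple[float, float, float]] = None


@dataclass(frozen=True)
class PharmacophoreModel:
    name: str
    points: tuple[PharmacophorePoint, ...]
    frame_pdb_id: Optional[str] = None
    hbond_constraint: Optional[HBondConstraint] = None

    def __post_init__(self) -> None:
        if len(self.points) == 0:
            raise ValueError("a pharmacophore model needs at least one point")
        labels = [p.label for p in self.points]
        if len(set(labels)) != len(labels):
            raise ValueError(f"point labels must be unique, got {labels}")

    def point_by_label(self, label: str) -> PharmacophorePoint:
        for p in self.points:
            if p.label == label:
                return p
        raise KeyError(label)

    @property
    def total_weight(self) -> float:
        return sum(p.weight for p in self.points)

    # -- JSON round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "name": self.name,
            "frame_pdb_id": self.frame_pdb_id,
            "points": [
                {
                    "kind": p.kind.value,
                    "center": list(p.center),
                    "radius": p.radius,
                    "weight": p.weight,
                    "label": p.label,
                }
                for p in self.points
            ],
        }
        if self.hbond_constraint is not None:
            c = self.hbond_constraint
            d["hbond_constraint"] = {
                "chain": c.chain,
                "resnum": c.resnum,
                "atom": c.atom,
                "weight": c.weight,
                "min_geometry_weight": c.min_geometry_weight,
            }
            if c.h_position is not None:
                d["hbond_constraint"]["h_position"] = list(c.h_position)
            if c.donor_position is not None:
                d["hbond_constraint"]["donor_position"] = list(c.donor_position)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PharmacophoreModel":
        required = {"name", "points"}
        missing = required - set(d)
        if missing:
            raise ValueError(f"model JSON missing keys: {sorted(missing)}")
        points = []
        for i, pd in enumerate(d["points"]):
            for key in ("kind", "center", "radius", "weight"):
                if key not in pd:
                    raise ValueError(f"point {i}: missing {key!r}")
            if pd["kind"] not in FeatureKind.__members__:
                raise ValueError(f"point {i}: unknown kind {pd['kind']!r}")
            center = pd["center"]
            if len(center) != 3 or not all(math.isfinite(v) for v in center):
                raise ValueError(f"point {i}: center must be 3 finite numbers")
            points.append(
                PharmacophorePoint(
                    kind=FeatureKind(pd["kind"]),
                    center=tuple(float(v) for v in center),
                    radius=float(pd["radius"]),
                    weight=float(pd["weight"]),
                    label=str(pd.get("label", f"point{i + 1}")),
                )
            )
        constraint = None
        if d.get("hbond_constraint"):
            c = d["hbond_constraint"]
            constraint = HBondConstraint(
                chain=str(c["chain"]),
                resnum=int(c["resnum"]),
                atom=str(c["atom"]),
                weight=float(c["weight"]),
                min_geometry_weight=float(c.get("min_geometry_weight", 0.005)),
                h_position=tuple(c["h_position"]) if "h_position" in c else None,
                donor_position=tuple(c["donor_position"]) if "donor_position" in c else None,
            )
        return cls(
            name=str(d["name"]),
            points=tuple(points),
            frame_pdb_id=d.get("frame_pdb_id"),
            hbond_constraint=constraint,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PharmacophoreModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Built-in ROCK1/ROCK2 screening models
# ---------------------------------------------------------------------------

_BUILTIN_MODELS: dict[str, PharmacophoreModel] = {
    "ROCK1": PharmacophoreModel(
        name="ROCK1",
        frame_pdb_id="6E9W",
        points=(
            PharmacophorePoint(FeatureKind.HBA, (50.3, 98.8, 23.7), 0.5, 10.0, "hinge HBA"),
            PharmacophorePoint(FeatureKind.HBA, (50.6, 105.4, 30.1), 0.7, 5.0, "Lys HBA"),
            PharmacophorePoint(FeatureKind.AromaticRing, (50.5, 99.6, 24.9), 2.0, 5.0, "hinge ring"),
            PharmacophorePoint(FeatureKind.AromaticRing, (48.7, 104.7, 34.2), 2.0, 5.0, "affinity-pocket ring"),
        ),
        hbond_constraint=HBondConstraint(chain="A", resnum=156, atom="H", weight=10.0),
    ),
    "ROCK2": PharmacophoreModel(
        name="ROCK2",
        frame_pdb_id="7JNT",
        points=(
            PharmacophorePoint(FeatureKind.HBA, (-5.8, -5.0, -34.8), 0.5, 10.0, "hinge HBA"),
            PharmacophorePoint(FeatureKind.HBA, (-2.3, 2.3, -30.5), 0.7, 5.0, "Lys HBA"),
            PharmacophorePoint(FeatureKind.AromaticRing, (-5.4, -3.9, -34.2), 2.0, 5.0, "hinge ring"),
            PharmacophorePoint(FeatureKind.AromaticRing, (-1.6, 5.8, -33.1), 2.0, 5.0, "affinity-pocket ring"),
        ),
        hbond_constraint=HBondConstraint(chain="A", resnum=172, atom="H", weight=10.0),
    ),
}


def builtin_model(name: str) -> PharmacophoreModel:
    """Return a built-in screening model (``"ROCK1"`` or ``"ROCK2"``).

    Both models carry four points — hinge HBA (r 0.5 Å, w 10), catalytic-Lys
    HBA (r 0.7, w 5), hinge aromatic-ring center (r 2, w 5) and
    affinity-pocket aromatic-ring center (r 2, w 5) — and a mandatory hinge
    backbone H-bond constraint (weight 10).
    """
    try:
        return _BUILTIN_MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown builtin model {name!r}; choices: {sorted(_BUILTIN_MODELS)}"
        ) from None


# ---------------------------------------------------------------------------
# Feature perception
# ---------------------------------------------------------------------------

def perceive_features(mol, conf_id: int = -1) -> list[LigandFeature]:
    """Perceive HBA / HBD / aromatic-ring features of a 3D conformer.

    Typing rules (editable via the module-level predicates):

    * HBA — N or O, not positively charged, not an amide nitrogen;
      positioned on the heavy atom.
    * HBD — heavy atom (N or O) bearing at least one hydrogen; positioned
      on the heavy atom.
    * AromaticRing — one feature per smallest aromatic ring, positioned at
      the unweighted centroid of the ring atoms.

    Output ordering is deterministic: by (kind, first source atom index).
    """
    from rdkit import Chem

    if mol.GetNumConformers() == 0:
        raise ValueError("no conformer: molecule has no 3D coordinates")
    conf = mol.GetConformer(conf_id)

    features: list[LigandFeature] = []

    def atom_pos(idx: int) -> tuple[float, float, float]:
        p = conf.GetAtomPosition(idx)
        return (p.x, p.y, p.z)

    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        sym = atom.GetSymbol()
        if sym not in ("N", "O"):
            continue
        if _is_acceptor(atom):
            features.append(LigandFeature(FeatureKind.HBA, atom_pos(idx), (idx,)))
        if atom.GetTotalNumHs(includeNeighbors=True) > 0 and atom.GetFormalCharge() <= 0:
            features.append(LigandFeature(FeatureKind.HBD, atom_pos(idx), (idx,)))

    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            coords = np.array([atom_pos(i) for i in ring])
            centroid = tuple(coords.mean(axis=0))
            features.append(LigandFeature(FeatureKind.AromaticRing, centroid, tuple(sorted(ring))))

    features.sort(key=lambda f: (f.kind.value, f.source_atom_indices))
    return features


def _is_acceptor(atom) -> bool:
    """N/O acceptor rule: no positive charge; amide N excluded."""
    if atom.GetFormalCharge() > 0:
        return False
    if atom.GetSymbol() == "N":
        # amide nitrogen: N bonded to a carbonyl carbon
        for nbr in atom.GetNeighbors():
            if nbr.GetSymbol() != "C":
                continue
            for bond in nbr.GetBonds():
                other = bond.GetOtherAtom(nbr)
                if other.GetSymbol() == "O" and bond.GetBondTypeAsDouble() == 2.0:
                    return False
        # pyrrole-type aromatic N-H donates its lone pair into the ring
        if atom.GetIsAromatic() and atom.GetTotalNumHs(includeNeighbors=True) > 0:
            return False
    return True


# ---------------------------------------------------------------------------
# Consensus elucidation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsensusParams:
    """Grouping parameters for consensus-map elucidation.

    merge_radius
        Single-linkage merge distance (Å) between same-kind features of
        different ligands. Default 1.0 Å tolerates crystal-pose scatter.
    min_support
        Fraction of ligands (0, 1] that must contribute to a group before
        it becomes a model point. Default 0.6.
    radius_floor
        Minimum emitted point radius (Å) when the group spread is smaller.
    """

    merge_radius: float = 1.0
    min_support: float = 0.6
    radius_floor: float = 0.5

    def __post_init__(self) -> None:
        if self.merge_radius <= 0:
            raise ValueError("merge_radius must be > 0")
        if not (0 < self.min_support <= 1):
            raise ValueError("min_support must be in (0, 1]")


def consensus_map(
    feature_sets: Sequence[Sequence[LigandFeature]],
    params: ConsensusParams = ConsensusParams(),
    name: str = "consensus",
) -> PharmacophoreModel:
    """Elucidate a consensus pharmacophore from pre-aligned ligand features.

    Same-kind features across ligands are grouped by single linkage at
    ``params.merge_radius``; groups supported by at least
    ``params.min_support`` of the ligands become model points with center =
    group centroid and radius = max(radius floor, RMS spread). Weights
    default to 1.

    Ligands must already share a coordinate frame (e.g. crystal poses from
    superposed structures). Returns an empty-pointed sentinel model (with a
    warning) when no group reaches the support threshold.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import pdist

    if len(feature_sets) == 0:
        raise ValueError("consensus_map needs at least one ligand feature set")
    n_ligands = len(feature_sets)
    min_count = math.ceil(params.min_support * n_ligands - 1e-9)

    points: list[PharmacophorePoint] = []
    counter: dict[FeatureKind, int] = {}
    for kind in FeatureKind:
        entries = [
            (lig_idx, f.xyz)
            for lig_idx, feats in enumerate(feature_sets)
            for f in feats
            if f.kind == kind
        ]
        if not entries:
            continue
        coords = np.array([e[1] for e in entries])
        owners = np.array([e[0] for e in entries])
        if len(entries) == 1:
            labels = np.array([1])
        else:
            z = linkage(pdist(coords), method="single")
            labels = fcluster(z, t=params.merge_radius, criterion="distance")
        for lab in np.unique(labels):
            mask = labels == lab
            support = len(np.unique(owners[mask]))
            if support < min_count:
                continue
            group = coords[mask]
            center = group.mean(axis=0)
            spread = float(np.sqrt(np.mean(np.sum((group - center) ** 2, axis=1))))
            counter[kind] = counter.get(kind, 0) + 1
            points.append(
                PharmacophorePoint(
                    kind=kind,
                    center=tuple(center),
                    radius=max(params.radius_floor, spread),
                    weight=1.0,
                    label=f"{kind.value}-{counter[kind]}",
                )
            )

    if not points:
        warnings.warn("no consensus point reached the support threshold; returning empty model")
        return _EmptyModel(name=name)
    # deterministic order: by kind then center
    points.sort(key=lambda p: (p.kind.value, p.center))
    return PharmacophoreModel(name=name, points=tuple(points))


class _EmptyModel(PharmacophoreModel):
    """Sentinel for a consensus run that produced no supported points."""

    def __init__(self, name: str) -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "points", ())
        object.__setattr__(self, "frame_pdb_id", None)
        object.__setattr__(self, "hbond_constraint", None)

    def __post_init__(self) -> None:  # pragma: no cover - not called
        pass
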