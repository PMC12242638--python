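"""Synthetic inputs with planted ground truth for every pipeline stage.

Four generator families, each a pure function of its spec + seed:

* activity tables with a known active/inactive/intermediate/IC50
  composition (drives curation tests);
* clustered coordinate populations with a planted cluster count (drives
  chemical-space selection tests);
* 3D feature libraries with a planted pharmacophore plus positional
  jitter and configurable decoys (drives screening/ROC tests);
* toy two-chain PDB pairs with known site identity / RMSD / atom counts
  (drives structure-comparison tests).

Synthetic SMILES come from a small fragment grammar (aromatic cores x
alkyl linkers x substituents) rather than real drug structures; every
emitted SMILES is checked to parse and canonical duplicates are skipped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from phorescreen.geometry import random_rotation
from phorescreen.pharmacophore import FeatureKind, LigandFeature, PharmacophoreModel

# ---------------------------------------------------------------------------
# SMILES fragment grammar
# ---------------------------------------------------------------------------

_CORES = (
    "c1ccncc1",      # pyridine
    "c1cncnc1",      # pyrimidine
    "c1ccc2ncccc2c1",  # quinoline
    "c1cc[nH]n1",    # pyrazole
    "c1ccoc1",       # furan
    "c1ccsc1",       # thiophene
    "c1ccccc1",      # benzene
    "c1ncc[nH]1",    # imidazole
)
_LINKERS = ("C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC", "CCCCCCC")
_HEADS = ("", "O", "N", "Cl", "F", "OC", "NC", "N#C", "OCC", "NCC")


def synthetic_smiles(n: int, seed: int = 0) -> list[str]:
    """``n`` unique, parseable SMILES from the fragment grammar."""
    from rdkit import Chem

    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise RuntimeError(f"fragment grammar exhausted after {attempts} attempts")
        head = _HEADS[int(rng.integers(len(_HEADS)))]
        linker = _LINKERS[int(rng.integers(len(_LINKERS)))]
        core = _CORES[int(rng.integers(len(_CORES)))]
        extra = _LINKERS[int(rng.integers(len(_LINKERS)))] if rng.random() < 0.4 else ""
        smi = head + linker + extra + core
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        out.append(canonical)
    return out


# ---------------------------------------------------------------------------
# Activity tables
# ---------------------------------------------------------------------------

def make_activity_table(
    n_active: int,
    n_inactive: int,
    n_intermediate: int,
    n_ic50: int,
    seed: int,
    out_dir: Optional[str | Path] = None,
    active_nM: float = 100.0,
    inactive_nM: float = 5000.0,
):
    """Activity CSV with a known class composition plus a truth table.

    Ki/Kd values are drawn log-uniform inside the correct band per class
    (active <= ``active_nM``; inactive >= ``inactive_nM``; intermediate
    strictly between); IC50 rows are potent but excluded by type. Returns
    ``(DataFrame, truth_dict)`` and, when ``out_dir`` is given, writes
    ``activities.csv`` and ``truth.json`` there.
    """
    import pandas as pd

    counts = (n_active, n_inactive, n_intermediate, n_ic50)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be >= 0")
    if sum(counts) == 0:
        raise ValueError("at least one record required")
    rng = np.random.default_rng(seed)
    smiles = synthetic_smiles(sum(counts), seed=seed)

    def logu(lo: float, hi: float, size: int) -> np.ndarray:
        return 10 ** rng.uniform(np.log10(lo), np.log10(hi), size)

    rows = []
    truth = []
    idx = 0
    specs = [
        ("active", n_active, lambda k: logu(0.1, active_nM, k)),
        ("inactive", n_inactive, lambda k: logu(inactive_nM, 1e6, k)),
        ("intermediate", n_intermediate,
         lambda k: logu(active_nM * 1.01, inactive_nM * 0.99, k)),
        ("ic50", n_ic50, lambda k: logu(0.1, active_nM, k)),
    ]
    for klass, n, draw in specs:
        values = draw(n)
        for v in values:
            cid = f"SYN{idx:05d}"
            stype = "IC50" if klass == "ic50" else ("Ki" if rng.random() < 0.5 else "Kd")
            rows.append(
                {
                    "compound_id": cid,
                    "smiles": smiles[idx],
                    "standard_type": stype,
                    "standard_value": round(float(v), 4),
                    "pchembl_value": round(9.0 - math.log10(float(v)), 2),
                }
            )
            truth.append({"compound_id": cid, "true_class": klass})
            idx += 1
    df = pd.DataFrame(rows)
    truth_d = {
        "n_active": n_active,
        "n_inactive": n_inactive,
        "n_intermediate": n_intermediate,
        "n_ic50": n_ic50,
        "records": truth,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "activities.csv", index=False)
        (out_dir / "truth.json").write_text(json.dumps(truth_d, indent=2))
    return df, truth_d


# ---------------------------------------------------------------------------
# Planted feature libraries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedLibrarySpec:
    """Conditions for a planted screening library.

    Defaults are the package's standard validation fixture: 20 actives
    carrying the model geometry under 0.3 Å isotropic jitter against 180
    position-scrambled decoys.
    """

    model: PharmacophoreModel
    n_actives: int = 20
    n_decoys: int = 180
    jitter_sigma: float = 0.3
    decoy_mode: str = "scramble_positions"
    n_distractors: int = 3
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_actives < 1 or self.n_decoys < 1:
            raise ValueError("n_actives and n_decoys must be >= 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if self.decoy_mode not in (
            "scramble_positions", "drop_required_feature", "random_features"
        ):
            raise ValueError(f"unknown decoy_mode {self.decoy_mode!r}")


def make_planted_feature_library(
    spec: PlantedLibrarySpec,
) -> tuple[dict[str, list[list[LigandFeature]]], dict[str, int]]:
    """Per-compound feature sets with a planted pharmacophore, plus labels.

    Actives carry the model's point kinds at the point centers plus
    Gaussian jitter and ``n_distractors`` random extra features, then a
    random rigid motion per compound (so matching must be frame-free).
    Decoys follow ``spec.decoy_mode``:

    * ``scramble_positions`` — same feature kinds, positions re-drawn
      from a Gaussian matched to the per-axis mean and spread of a
      jittered active-like feature set, so decoys share the actives'
      spatial extent at every jitter level and only the geometric
      arrangement separates the classes (AUC tends to 0.5, not below, as
      jitter grows);
    * ``drop_required_feature`` — active-like but with every HBA removed,
      so a required hinge-HBA match is impossible;
    * ``random_features`` — random kinds and positions.

    Returns ``(library, labels)`` with label 1 = active.
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.model
    centers = np.array([p.xyz for p in model.points])
    kinds = [p.kind for p in model.points]
    lo = centers.min(axis=0) - 2.0
    hi = centers.max(axis=0) + 2.0
    all_kinds = list(FeatureKind)

    def rigid(features: list[LigandFeature]) -> list[LigandFeature]:
        rot = random_rotation(rng)
        trans = rng.uniform(-20, 20, 3)
        return [
            LigandFeature(f.kind, tuple(rot @ f.xyz + trans), f.source_atom_indices)
            for f in features
        ]

    def distractors(k: int) -> list[LigandFeature]:
        feats = []
        for _ in range(k):
            kind = all_kinds[int(rng.integers(len(all_kinds)))]
            pos = rng.uniform(lo - 3, hi + 3)
            feats.append(LigandFeature(kind, tuple(pos)))
        return feats

    library: dict[str, list[list[LigandFeature]]] = {}
    labels: dict[str, int] = {}
    for i in range(spec.n_actives):
        feats = [
            LigandFeature(kind, tuple(c + rng.normal(0, spec.jitter_sigma, 3)))
            for kind, c in zip(kinds, centers)
        ] + distractors(spec.n_distractors)
        cid = f"ACT{i:04d}"
        library[cid] = [rigid(feats)]
        labels[cid] = 1
    for i in range(spec.n_decoys):
        if spec.decoy_mode == "scramble_positions":
            ref = centers + rng.normal(0, spec.jitter_sigma, centers.shape)
            mu, sd = ref.mean(axis=0), ref.std(axis=0, ddof=1)
            feats = [
                LigandFeature(kind, tuple(rng.normal(mu, sd))) for kind in kinds
            ] + distractors(spec.n_distractors)
        elif spec.decoy_mode == "drop_required_feature":
            feats = [
                LigandFeature(kind, tuple(c + rng.normal(0, spec.jitter_sigma, 3)))
                for kind, c in zip(kinds, centers)
                if kind != FeatureKind.HBA
            ] + [f for f in distractors(spec.n_distractors) if f.kind != FeatureKind.HBA]
            if not feats:
                feats = [LigandFeature(FeatureKind.HBD, tuple(rng.uniform(lo, hi)))]
        else:
            feats = [
                LigandFeature(
                    all_kinds[int(rng.integers(len(all_kinds)))], tuple(rng.uniform(lo, hi))
                )
                for _ in range(len(kinds) + spec.n_distractors)
            ]
        cid = f"DEC{i:04d}"
        library[cid] = [rigid(feats)]
        labels[cid] = 0
    return library, labels


# ---------------------------------------------------------------------------
# Planted clusters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedClusterSpec:
    k_true: int = 5
    points_per_cluster: int = 30
    separation: float = 10.0     # center spacing in units of the blob sigma
    dimension: int = 2
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if self.separation <= 0:
            raise ValueError("separation must be > 0")


def make_planted_clusters(spec: PlantedClusterSpec) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian blobs with centers at mutual distance >= separation.

    Centers are drawn by rejection in a box scaled to hold ``k_true``
    well-spread points. Returns ``(coords, labels)``.
    """
    rng = np.random.default_rng(spec.seed)
    min_dist = spec.separation * spec.sigma
    box = max(4.0, 2.5 * min_dist * spec.k_true ** (1.0 / spec.dimension))
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < spec.k_true:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not place cluster centers; lower the separation")
        c = rng.uniform(0, box, spec.dimension)
        if all(np.linalg.norm(c - o) >= min_dist for o in centers):
            centers.append(c)
    coords = []
    labels = []
    for ci, c in enumerate(centers):
        coords.append(rng.normal(0, spec.sigma, (spec.points_per_cluster, spec.dimension)) + c)
        labels.extend([ci] * spec.points_per_cluster)
    return np.vstack(coords), np.asarray(labels)


# ---------------------------------------------------------------------------
# Toy structure pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyStructureSpec:
    n_site_residues: int = 10
    n_distant_residues: int = 5
    identity_fraction: float = 1.0
    rigid_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotate: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.identity_fraction <= 1):
            raise ValueError("identity_fraction must be in [0, 1]")


_BB_OFFSETS = {
    "N": np.array([-1.2, 0.8, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.3, 0.5, 0.0]),
    "O": np.array([1.4, 1.7, 0.0]),
    "CB": np.array([-0.3, -1.4, 0.6]),
}


def _pdb_line(record: str, serial: int, name: str, resname: str, chain: str,
              resseq: int, xyz: np.ndarray, element: str) -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:>5d} {name_field:<4s} {resname:<3s} {chain}"
        f"{resseq:>4d}    {xyz[0]:>8.3f}{xyz[1]:>8.3f}{xyz[2]:>8.3f}"
        f"{1.00:>6.2f}{0.00:>6.2f}          {element:>2s}"
    )


def make_toy_structure_pair(
    spec: ToyStructureSpec, out_dir: Optional[str | Path] = None
) -> tuple[str, str, dict]:
    """Two toy PDB texts whose site comparison has a known outcome.

    Structure A is a poly-alanine chain: ``n_site_residues`` placed on a
    ~6 Å shell around a HETATM ligand at the origin and
    ``n_distant_residues`` ~30 Å away (outside any 10 Å site). Structure B
    is a rigid copy (optional rotation + ``rigid_offset``) with
    ``1 - identity_fraction`` of the site residues renamed to glycine
    (their CB dropped). The truth dict carries the exact identity
    percentage, the brute-force site RMSD (0 for a pure rigid motion) and
    per-site residue counts.

    Returns ``(pdb_text_a, pdb_text_b, truth)``; when ``out_dir`` is
    given also writes ``a.pdb``, ``b.pdb`` and ``truth.json``.
    """
    rng = np.random.default_rng(spec.seed)
    n_site, n_far = spec.n_site_residues, spec.n_distant_residues

    residues = []  # (resseq, resname, {atom: coord})
    for i in range(n_site + n_far):
        if i < n_site:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            center = direction * rng.uniform(5.0, 8.0)
        else:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            center = direction * rng.uniform(28.0, 35.0)
        rot = random_rotation(rng)
        atoms = {name: center + rot @ off for name, off in _BB_OFFSETS.items()}
        residues.append((i + 1, "ALA", atoms))

    lig_atoms = {"C1": np.array([0.0, 0.0, 0.0]),
                 "C2": np.array([1.4, 0.0, 0.0]),
                 "C3": np.array([0.7, 1.2, 0.0])}

    n_renamed = int(round((1 - spec.identity_fraction) * n_site))
    renamed = set(rng.choice(np.arange(1, n_site + 1), size=n_renamed, replace=False)) \
        if n_renamed else set()

    rot_b = random_rotation(rng) if spec.rotate else np.eye(3)
    off_b = np.asarray(spec.rigid_offset, float)

    def build(which: str) -> str:
        lines = []
        serial = 1
        for resseq, resname, atoms in residues:
            name_out = "GLY" if (which == "B" and resseq in renamed) else resname
            for aname in ("N", "CA", "C", "O", "CB"):
                if name_out == "GLY" and aname == "CB":
                    continue
                xyz = atoms[aname]
                if which == "B":
                    xyz = rot_b @ xyz + off_b
                lines.append(
                    _pdb_line("ATOM", serial, aname, name_out, "A", resseq, xyz,
                              aname[0])
                )
                serial += 1
        lines.append("TER")
        for aname, xyz in lig_atoms.items():
            if which == "B":
                xyz = rot_b @ xyz + off_b
            lines.append(_pdb_line("HETATM", serial, aname, "LIG", "A", 900, xyz, "C"))
            serial += 1
        lines.append("END")
        return "\n".join(lines) + "\n"

    text_a, text_b = build("A"), build("B")

    # brute-force RMSD over paired backbone atoms of the site residues
    from phorescreen.geometry import superpose_rmsd

    pa, pb = [], []
    for resseq, _, atoms in residues[:n_site]:
        for aname in ("N", "CA", "C", "O"):
            pa.append(atoms[aname])
            pb.append(rot_b @ atoms[aname] + off_b)
    rmsd, _, _ = superpose_rmsd(np.array(pb), np.array(pa))

    truth = {
        "identity_percent": 100.0 * (n_site - n_renamed) / n_site,
        "rmsd": rmsd,
        "n_site_residues": n_site,
        "n_distant_residues": n_far,
        "renamed_residues": sorted(int(r) for r in renamed),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "a.pdb").write_text(text_a)
        (out_dir / "b.pdb").write_text(text_b)
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return text_a, text_b, truth
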