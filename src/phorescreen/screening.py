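"""Pharmacophore-constrained 3D screening.

Matching is frame-free: for every kind-compatible injective assignment of
model points to ligand features (covering at least a required subset, by
default the hinge hydrogen-bond acceptor), the features are rigidly
superposed onto the point centers by Kabsch least squares (proper
rotations only), a point is *satisfied* when its assigned feature lands
within the point's tolerance radius, and the match score is the sum of the
weights of the satisfied points. The assignment maximizing the score wins;
ties go to the lower superposition RMSD, then to the lexicographically
smallest assignment.

Candidate assignments are pruned by pairwise distance compatibility
(``|d_features - d_points| <= r_a + r_b``) before any superposition, which
keeps exact equivalence with exhaustive enumeration: an assignment whose
internal distances disagree beyond the combined radii cannot place both
features inside their spheres simultaneously.

Library screening evaluates up to ``max_conformers`` conformers per
compound (default cap 200) and ranks by best score.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from phorescreen.geometry import apply_transform, superpose_rmsd
from phorescreen.pharmacophore import (
    FeatureKind,
    HBondConstraint,
    LigandFeature,
    PharmacophoreModel,
)

DEFAULT_MAX_CONFORMERS = 200
HBOND_DIST_MAX = 2.5       # acceptor...H distance cutoff, Å
HBOND_ANGLE_MIN = 120.0    # donor-H...acceptor angle cutoff, degrees


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one conformer's features against a model.

    correspondence maps point index -> feature index (injective,
    kind-compatible). ``satisfied[i]`` is meaningful only for matched
    points; unmatched points are unsatisfied by definition.
    """

    correspondence: tuple[tuple[int, int], ...]
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    satisfied: tuple[bool, ...]
    score: float
    hbond_ok: Optional[bool] = None

    @property
    def matched_point_indices(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.correspondence)


@dataclass(frozen=True)
class ScreenRecord:
    compound_id: str
    best_score: float
    best_rmsd: float
    best_conformer_index: int
    n_conformers_tried: int
    matched_labels: tuple[str, ...]
    hbond_ok: Optional[bool] = None


def _kind_candidates(
    model: PharmacophoreModel, features: Sequence[LigandFeature]
) -> list[list[int]]:
    """Per model point, the feature indices of compatible kind."""
    return [
        [j for j, f in enumerate(features) if f.kind == p.kind]
        for p in model.points
    ]


def _pair_compatible(
    model: PharmacophoreModel,
    features: Sequence[LigandFeature],
    point_dists: np.ndarray,
    feat_dists: np.ndarray,
    pi: int,
    fi: int,
    pj: int,
    fj: int,
) -> bool:
    slack = model.points[pi].radius + model.points[pj].radius
    return abs(feat_dists[fi, fj] - point_dists[pi, pj]) <= slack + 1e-9


def match_model(
    features: Sequence[LigandFeature],
    model: PharmacophoreModel,
    require: Iterable[str] = ("hinge HBA",),
    prune: bool = True,
) -> Optional[MatchResult]:
    """Find the best-scoring rigid match of ligand features onto a model.

    Parameters
    ----------
    features:
        Perceived 3D features of one conformer.
    model:
        The pharmacophore model to match against.
    require:
        Labels of model points that every candidate assignment must cover
        *and satisfy*; an empty set allows any non-empty assignment.
    prune:
        Apply the pairwise-distance compatibility filter before
        superposition (results are identical with or without it).

    Returns
    -------
    The best :class:`MatchResult`, or ``None`` when no assignment covers
    and satisfies the required points.
    """
    if len(model.points) == 0:
        raise ValueError("model with zero points")
    if len(features) == 0:
        return None
    require = set(require)
    labels = [p.label for p in model.points]
    unknown = require - set(labels)
    if unknown:
        raise KeyError(f"required labels not in model: {sorted(unknown)}")
    required_idx = frozenset(i for i, lab in enumerate(labels) if lab in require)

    n_points = len(model.points)
    point_xyz = np.array([p.xyz for p in model.points])
    feat_xyz = np.array([f.xyz for f in features])
    point_d = np.linalg.norm(point_xyz[:, None] - point_xyz[None, :], axis=-1)
    feat_d = np.linalg.norm(feat_xyz[:, None] - feat_xyz[None, :], axis=-1)
    candidates = _kind_candidates(model, features)
    if any(not candidates[i] for i in required_idx):
        return None

    best: Optional[MatchResult] = None
    best_key: Optional[tuple] = None

    # enumerate subsets of model points containing the required ones,
    # largest subsets first only for readability (scoring decides)
    optional_idx = [i for i in range(n_points) if i not in required_idx]
    for r in range(len(optional_idx) + 1):
        for extra in itertools.combinations(optional_idx, r):
            subset = sorted(required_idx | set(extra))
            if not subset:
                continue
            for assign in _injective_assignments(
                subset, candidates, model, features, point_d, feat_d, prune
            ):
                result = _evaluate_assignment(
                    subset, assign, model, features, point_xyz, feat_xyz, required_idx
                )
                if result is None:
                    continue
                key = (-result.score, result.rmsd, result.correspondence)
                if best_key is None or key < best_key:
                    best, best_key = result, key
    return best


def _injective_assignments(
    subset: list[int],
    candidates: list[list[int]],
    model,
    features,
    point_d,
    feat_d,
    prune: bool,
):
    """Backtracking enumeration of injective feature choices for ``subset``."""
    chosen: list[int] = []

    def rec(k: int):
        if k == len(subset):
            yield tuple(chosen)
            return
        pi = subset[k]
        for fi in candidates[pi]:
            if fi in chosen:
                continue
            if prune:
                ok = all(
                    _pair_compatible(model, features, point_d, feat_d, subset[m], chosen[m], pi, fi)
                    for m in range(k)
                )
                if not ok:
                    continue
            chosen.append(fi)
            yield from rec(k + 1)
            chosen.pop()

    yield from rec(0)


def _evaluate_assignment(
    subset: list[int],
    assign: tuple[int, ...],
    model: PharmacophoreModel,
    features: Sequence[LigandFeature],
    point_xyz: np.ndarray,
    feat_xyz: np.ndarray,
    required_idx: frozenset[int],
) -> Optional[MatchResult]:
    mobile = feat_xyz[list(assign)]
    target = point_xyz[subset]
    rmsd, rot, trans = superpose_rmsd(mobile, target)
    moved = apply_transform(mobile, rot, trans)
    satisfied = [False] * len(model.points)
    score = 0.0
    for k, pi in enumerate(subset):
        dist = float(np.linalg.norm(moved[k] - point_xyz[pi]))
        if dist <= model.points[pi].radius + 1e-9:
            satisfied[pi] = True
            score += model.points[pi].weight
    if any(not satisfied[i] for i in required_idx):
        return None
    correspondence = tuple(zip(subset, assign))
    return MatchResult(
        correspondence=correspondence,
        rotation=rot,
        translation=trans,
        rmsd=rmsd,
        satisfied=tuple(satisfied),
        score=score,
    )


def match_model_bruteforce(
    features: Sequence[LigandFeature],
    model: PharmacophoreModel,
    require: Iterable[str] = ("hinge HBA",),
) -> Optional[MatchResult]:
    """Unpruned exhaustive matcher (reference oracle; identical contract)."""
    return match_model(features, model, require=require, prune=False)


def check_hinge_hbond(
    acceptor_position: np.ndarray,
    h_position: np.ndarray,
    donor_position: np.ndarray,
    max_distance: float = HBOND_DIST_MAX,
    min_angle_deg: float = HBOND_ANGLE_MIN,
) -> bool:
    """Geometric hydrogen-bond gate for the hinge constraint.

    True iff the acceptor lies within ``max_distance`` of the donor H and
    the donor-H...acceptor angle is at least ``min_angle_deg``.
    """
    acc = np.asarray(acceptor_position, float)
    h = np.asarray(h_position, float)
    don = np.asarray(donor_position, float)
    if np.linalg.norm(acc - h) > max_distance:
        return False
    v1 = don - h
    v2 = acc - h
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return False
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang))) >= min_angle_deg


def _apply_hbond_constraint(
    result: MatchResult,
    model: PharmacophoreModel,
    features: Sequence[LigandFeature],
) -> Optional[bool]:
    """Evaluate the model's protein H-bond constraint on a match, if resolvable."""
    c = model.hbond_constraint
    if c is None or c.h_position is None or c.donor_position is None:
        return None
    # the hinge acceptor feature, transformed into the model frame
    hinge_idx = next(
        (i for i, p in enumerate(model.points) if "hinge" in p.label and p.kind == FeatureKind.HBA),
        None,
    )
    if hinge_idx is None:
        return None
    corr = dict(result.correspondence)
    if hinge_idx not in corr:
        return False
    acc = apply_transform(
        features[corr[hinge_idx]].xyz[None, :], result.rotation, result.translation
    )[0]
    return check_hinge_hbond(acc, np.asarray(c.h_position), np.asarray(c.donor_position))


def screen_library(
    library: Mapping[str, Sequence[Sequence[LigandFeature]]],
    model: PharmacophoreModel,
    max_conformers: int = DEFAULT_MAX_CONFORMERS,
    require: Iterable[str] = ("hinge HBA",),
) -> list[ScreenRecord]:
    """Screen a conformer library against a model and rank it.

    Parameters
    ----------
    library:
        Mapping compound_id -> list of conformers, each a list of
        :class:`LigandFeature`.
    model, require:
        Passed to :func:`match_model`.
    max_conformers:
        At most this many conformers are tried per compound.

    Returns
    -------
    Records sorted by (score desc, rmsd asc, compound_id asc). Compounds
    with no match get score 0 and rank after every matched compound.
    """
    if not library:
        raise ValueError("empty library")
    records: list[ScreenRecord] = []
    for cid in library:
        confs = library[cid]
        if len(confs) == 0:
            raise ValueError(f"compound {cid!r} has no conformers")
        best: Optional[MatchResult] = None
        best_conf = -1
        tried = 0
        for ci, feats in enumerate(confs[:max_conformers]):
            tried += 1
            res = match_model(feats, model, require=require)
            if res is None:
                continue
            if best is None or (-res.score, res.rmsd) < (-best.score, best.rmsd):
                best, best_conf = res, ci
        if best is None:
            records.append(ScreenRecord(cid, 0.0, float("inf"), -1, tried, (), None))
        else:
            matched = tuple(
                model.points[p].label for p, _ in best.correspondence if best.satisfied[p]
            )
            records.append(
                ScreenRecord(
                    cid,
                    best.score,
                    best.rmsd,
                    best_conf,
                    tried,
                    matched,
                    _apply_hbond_constraint(best, model, confs[best_conf]),
                )
            )
    records.sort(key=lambda r: (-r.best_score, r.best_rmsd, r.compound_id))
    return records


# ---------------------------------------------------------------------------
# Conformers for SMILES input
# ---------------------------------------------------------------------------

def generate_conformers(smiles: str, n_conformers: int = 10, seed: int = 7,
                        rms_threshold: float = 0.5):
    """Distance-geometry (ETKDG) conformers for a SMILES, hydrogens added.

    Seeded and RMS-deduplicated; capped at ``n_conformers`` (the screening
    default caps the *evaluated* conformers at 200 independently).
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    params.pruneRmsThresh = rms_threshold
    AllChem.EmbedMultipleConfs(mol, numConfs=n_conformers, params=params)
    if mol.GetNumConformers() == 0:
        raise ValueError(f"conformer embedding failed for {smiles!r}")
    return mol


def screen_smiles_library(
    smiles_by_id: Mapping[str, str],
    model: PharmacophoreModel,
    n_conformers: int = 10,
    seed: int = 7,
    max_conformers: int = DEFAULT_MAX_CONFORMERS,
    require: Iterable[str] = ("hinge HBA",),
) -> list[ScreenRecord]:
    """Generate conformers per compound, perceive features, screen, rank."""
    from phorescreen.pharmacophore import perceive_features

    feature_library: dict[str, list[list[LigandFeature]]] = {}
    for cid, smi in smiles_by_id.items():
        mol = generate_conformers(smi, n_conformers=n_conformers, seed=seed)
        feature_library[cid] = [
            perceive_features(mol, conf_id=conf.GetId()) for conf in mol.GetConformers()
        ]
    return screen_library(feature_library, model, max_conformers=max_conformers, require=require)
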