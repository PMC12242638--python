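"""Bioactivity curation: from raw activity tables to screening-ready sets.

The curation rules mirror a standard kinase-inhibitor ChEMBL workflow:

* only equilibrium binding measurements (Ki or Kd) define the activity
  classes — IC50 values vary too much with assay conditions to be pooled;
* active: value <= 100 nM; inactive: value >= 5000 nM (the KNIME-style
  inclusive bound; pass ``inactive_exclusive=True`` for a strict > 5000
  reading); the band in between is excluded as intermediate;
* structural filters: strip salt counterions (keep the largest organic
  fragment), canonicalize, drop duplicates, drop molecules with
  unspecified stereocenters and molecules with MW >= 550 Da;
* diversity selection: average-linkage hierarchical clustering on the
  Tanimoto fingerprint distance, tree cut at 0.5, one medoid per cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

ACTIVE_NM = 100.0
INACTIVE_NM = 5000.0
MAX_MW = 550.0
DIVERSITY_THRESHOLD = 0.5


class ActivityType(str, Enum):
    Ki = "Ki"
    Kd = "Kd"
    IC50 = "IC50"
    other = "other"

    @classmethod
    def parse(cls, raw: str) -> "ActivityType":
        norm = str(raw).strip().lower().replace("_", "")
        return {"ki": cls.Ki, "kd": cls.Kd, "ic50": cls.IC50}.get(norm, cls.other)


@dataclass(frozen=True)
class ActivityRecord:
    """One compound-target measurement (value in nM)."""

    compound_id: str
    smiles: str
    standard_type: ActivityType
    standard_value: float
    pchembl_value: Optional[float] = None
    target_id: str = ""

    def __post_init__(self) -> None:
        if self.standard_value < 0:
            raise ValueError(
                f"record {self.compound_id!r}: negative standard_value {self.standard_value}"
            )
        if self.pchembl_value is not None and self.standard_value > 0:
            implied = 9.0 - math.log10(self.standard_value)
            if abs(self.pchembl_value - implied) > 0.05:
                raise ValueError(
                    f"record {self.compound_id!r}: pchembl_value {self.pchembl_value} "
                    f"inconsistent with {self.standard_value} nM (implies {implied:.2f})"
                )


@dataclass(frozen=True)
class Compound:
    compound_id: str
    smiles: str                       # desalted canonical SMILES
    mol_weight: float
    n_unspecified_stereocenters: int = 0


@dataclass
class LabeledSet:
    actives: list
    inactives: list
    excluded: list  # (record_or_compound, reason)

    def counts(self) -> tuple[int, int, int]:
        return len(self.actives), len(self.inactives), len(self.excluded)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS = {
    "smiles": "smiles",
    "type": "standard_type",
    "value": "standard_value",
    "id": "compound_id",
    "pchembl": "pchembl_value",
}


def parse_activity_table(
    path: str | Path, columns: Optional[dict] = None
) -> tuple[list[ActivityRecord], list[tuple[dict, str]]]:
    """Read an activity CSV into records, routing bad rows to a rejects list.

    ``columns`` maps the roles smiles/type/value (mandatory) and
    id/pchembl (optional) to the CSV header names. Rows with unparseable
    SMILES or non-numeric values are returned as ``(row_dict, reason)``
    rejects, never dropped silently.
    """
    import pandas as pd
    from rdkit import Chem
    from rdkit import RDLogger

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path)
    for role in ("smiles", "type", "value"):
        if cols[role] not in df.columns:
            raise ValueError(
                f"missing mandatory column {cols[role]!r} (role {role}); "
                f"found {list(df.columns)}"
            )
    RDLogger.DisableLog("rdApp.error")
    records: list[ActivityRecord] = []
    rejects: list[tuple[dict, str]] = []
    try:
        for i, row in df.iterrows():
            rowd = row.to_dict()
            smi = row[cols["smiles"]]
            if not isinstance(smi, str) or Chem.MolFromSmiles(smi) is None:
                rejects.append((rowd, "unparseable SMILES"))
                continue
            try:
                value = float(row[cols["value"]])
                if math.isnan(value):
                    raise ValueError
            except (TypeError, ValueError):
                rejects.append((rowd, "non-numeric value"))
                continue
            pchembl = None
            if cols["pchembl"] in df.columns:
                raw = row[cols["pchembl"]]
                try:
                    pchembl = float(raw)
                    if math.isnan(pchembl):
                        pchembl = None
                except (TypeError, ValueError):
                    pchembl = None
            cid = str(row[cols["id"]]) if cols["id"] in df.columns else f"row{i}"
            records.append(
                ActivityRecord(
                    compound_id=cid,
                    smiles=smi,
                    standard_type=ActivityType.parse(row[cols["type"]]),
                    standard_value=value,
                    pchembl_value=pchembl,
                )
            )
    finally:
        RDLogger.EnableLog("rdApp.error")
    return records, rejects


# ---------------------------------------------------------------------------
# Activity classification
# ---------------------------------------------------------------------------

def classify_activity(
    records: Sequence[ActivityRecord],
    active_nM: float = ACTIVE_NM,
    inactive_nM: float = INACTIVE_NM,
    inactive_exclusive: bool = False,
) -> LabeledSet:
    """Partition records into actives / inactives / excluded.

    Only Ki and Kd measurements participate; IC50 and other types are
    excluded ("unsupported type"). A compound with several Ki/Kd values
    keeps its most potent (lowest nM) record. Active iff value <=
    ``active_nM``; inactive iff value >= ``inactive_nM`` (or strictly >
    with ``inactive_exclusive``); in between -> "intermediate activity".
    """
    if len(records) == 0:
        raise ValueError("no records to classify")
    result = LabeledSet([], [], [])
    best: dict[str, ActivityRecord] = {}
    for rec in records:
        if rec.standard_type not in (ActivityType.Ki, ActivityType.Kd):
            result.excluded.append((rec, "unsupported type"))
            continue
        prev = best.get(rec.compound_id)
        if prev is None or rec.standard_value < prev.standard_value:
            if prev is not None:
                result.excluded.append((prev, "duplicate measurement (less potent)"))
            best[rec.compound_id] = rec
        else:
            result.excluded.append((rec, "duplicate measurement (less potent)"))
    for rec in best.values():
        v = rec.standard_value
        if v <= active_nM:
            result.actives.append(rec)
        elif (v > inactive_nM) if inactive_exclusive else (v >= inactive_nM):
            result.inactives.append(rec)
        else:
            result.excluded.append((rec, "intermediate activity"))
    return result


# ---------------------------------------------------------------------------
# Structural filters
# ---------------------------------------------------------------------------

def _desalt_canonical(smiles: str):
    """Largest organic fragment, canonical SMILES, or None on parse failure."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    def frag_key(m):
        has_c = any(a.GetSymbol() == "C" for a in m.GetAtoms())
        return (has_c, m.GetNumHeavyAtoms())
    parent = max(frags, key=frag_key)
    return parent


def count_unspecified_stereocenters(mol) -> int:
    """Potential stereocenters whose configuration is not specified."""
    from rdkit.Chem import FindMolChiralCenters

    centers = FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    return sum(1 for _, tag in centers if tag == "?")


def apply_structural_filters(
    compounds: Sequence, max_mw: float = MAX_MW
) -> tuple[list[Compound], list[tuple[object, str]]]:
    """Desalt, canonicalize, deduplicate and filter a compound list.

    Accepts ``ActivityRecord``s, ``Compound``s or ``(id, smiles)`` pairs.
    Removes (with reasons): parse failures, molecules with any unspecified
    stereocenter, molecules with MW >= ``max_mw`` (inclusive bound) and
    exact duplicates by desalted canonical SMILES. Kept order is input
    order; the function is idempotent.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    kept: list[Compound] = []
    removed: list[tuple[object, str]] = []
    seen: set[str] = set()
    for item in compounds:
        if isinstance(item, (ActivityRecord, Compound)):
            cid, smi = item.compound_id, item.smiles
        else:
            cid, smi = item
        parent = _desalt_canonical(smi)
        if parent is None:
            removed.append((item, "unparseable SMILES"))
            continue
        canonical = Chem.MolToSmiles(parent)
        n_unspec = count_unspecified_stereocenters(parent)
        if n_unspec > 0:
            removed.append((item, "unspecified stereocenters"))
            continue
        mw = Descriptors.MolWt(parent)
        if mw >= max_mw:
            removed.append((item, f"MW >= {max_mw:g}"))
            continue
        if canonical in seen:
            removed.append((item, "duplicate"))
            continue
        seen.add(canonical)
        kept.append(Compound(cid, canonical, mw, 0))
    return kept, removed


# ---------------------------------------------------------------------------
# Hinge-binder prefilter
# ---------------------------------------------------------------------------

def hinge_motif_filter(smiles_or_compound) -> bool:
    """True iff the molecule carries a plausible kinase hinge-binder motif.

    The motif is an aromatic nitrogen heterocycle of ring size 5 or 6, or
    a fused bicyclic aromatic system whose perimeter counts 10 atoms
    (naphthalene-like) containing at least one nitrogen.
    """
    from rdkit import Chem

    smi = smiles_or_compound.smiles if isinstance(smiles_or_compound, Compound) else smiles_or_compound
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smi!r}")
    ri = mol.GetRingInfo()
    aromatic_rings = [
        set(ring)
        for ring in ri.AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    ]

    def has_n(atoms: set[int]) -> bool:
        return any(mol.GetAtomWithIdx(i).GetSymbol() == "N" for i in atoms)

    for ring in aromatic_rings:
        if len(ring) in (5, 6) and has_n(ring):
            return True
    # fused bicyclic aromatic systems: two rings sharing an edge, 10 atoms total
    for i in range(len(aromatic_rings)):
        for j in range(i + 1, len(aromatic_rings)):
            shared = aromatic_rings[i] & aromatic_rings[j]
            union = aromatic_rings[i] | aromatic_rings[j]
            if len(shared) == 2 and len(union) == 10 and has_n(union):
                return True
    return False


# ---------------------------------------------------------------------------
# Diversity selection
# ---------------------------------------------------------------------------

def diversity_select(
    compounds: Sequence[Compound],
    distance_threshold: float = DIVERSITY_THRESHOLD,
    linkage_method: str = "average",
) -> tuple[list[Compound], np.ndarray]:
    """One representative (medoid) per Tanimoto cluster at a distance cut.

    Hierarchical clustering (default average linkage) on the pairwise
    Tanimoto fingerprint distance, tree cut at ``distance_threshold``;
    each cluster contributes its medoid.

    Returns ``(representatives, cluster_labels)`` with labels aligned to
    the input order.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    from phorescreen.chemspace import (
        fingerprint_matrix,
        medoid_representatives,
        tanimoto_distance_matrix,
    )

    if len(compounds) == 0:
        raise ValueError("no compounds for diversity selection")
    if len(compounds) == 1:
        return list(compounds), np.zeros(1, dtype=int)
    fps = fingerprint_matrix([c.smiles for c in compounds])
    d = tanimoto_distance_matrix(fps)
    z = linkage(squareform(d, checks=False), method=linkage_method)
    labels = fcluster(z, t=distance_threshold, criterion="distance") - 1
    medoids = medoid_representatives(d, labels)
    reps = [compounds[i] for i in sorted(medoids)]
    return reps, labels
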