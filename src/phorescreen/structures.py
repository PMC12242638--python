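"""Protein binding-site utilities: extraction, comparison, SASA, pockets.

A binding site is the set of whole residues having at least one heavy atom
within a ligand-centered radius (default 10 Å, the standard docking-box
choice for kinase ATP sites). Two sites are compared by pairing their
residues in residue-number order (or by global sequence alignment when the
lengths differ), reporting percent identity of the paired residue names
and the Kabsch RMSD over shared atom names; solvent-accessible surface
area is computed per site by Shrake-Rupley sphere sampling with a 1.4 Å
probe.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from phorescreen.geometry import superpose_rmsd

SITE_RADIUS = 10.0
PROBE_RADIUS = 1.4
SASA_POINTS = 960

#: Bondi van der Waals radii (Å), overridable per call.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "B": 1.92,
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def read_structure(path: str | Path):
    """Read a PDB file into a Biotite AtomArray.

    First model only; altlocs resolved to the highest occupancy (ties go
    to 'A' because Biotite keeps the first-listed conformer on ties).
    """
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(
        model=1, altloc="occupancy", extra_fields=["occupancy"]
    )
    if atoms.array_length() == 0 or not np.any(~atoms.hetero):
        raise ValueError(f"{path}: no ATOM records")
    return atoms


@dataclass(frozen=True)
class BindingSite:
    """Residue/atom subset of a structure selected by ligand radius."""

    structure_id: str
    atoms: object                   # Biotite AtomArray of the site
    residue_keys: tuple             # (chain, resnum) per residue, ordered
    ligand_resname: str
    radius: float

    @property
    def residue_names(self) -> tuple[str, ...]:
        names = []
        for chain, resnum in self.residue_keys:
            mask = (self.atoms.chain_id == chain) & (self.atoms.res_id == resnum)
            names.append(str(self.atoms.res_name[mask][0]))
        return tuple(names)


def extract_site(
    structure,
    ligand_resname: str,
    radius: float = SITE_RADIUS,
    structure_id: str = "",
    include_waters: bool = False,
) -> BindingSite:
    """Residues with >= 1 heavy atom within ``radius`` of a ligand heavy atom.

    Whole residues are included; waters are excluded unless requested.
    Raises with the available HET residue names when the ligand is absent.
    """
    atoms = structure
    lig_mask = atoms.hetero & (atoms.res_name == ligand_resname)
    if not np.any(lig_mask):
        available = sorted(
            set(atoms.res_name[atoms.hetero]) - _WATER_NAMES
        )
        raise ValueError(
            f"ligand {ligand_resname!r} not found; HET residues present: {available}"
        )
    lig_heavy = atoms.coord[lig_mask & (atoms.element != "H")]
    prot_mask = ~atoms.hetero & (atoms.element != "H")
    if not include_waters:
        prot_mask &= ~np.isin(atoms.res_name, list(_WATER_NAMES))
    prot_idx = np.where(prot_mask)[0]
    dists = np.linalg.norm(
        atoms.coord[prot_idx][:, None, :] - lig_heavy[None, :, :], axis=-1
    ).min(axis=1)
    near = prot_idx[dists <= radius]
    keys = []
    seen = set()
    for i in near:
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]))
        if key not in seen:
            seen.add(key)
            keys.append(key)
    keys.sort()
    res_mask = np.zeros(atoms.array_length(), dtype=bool)
    for chain, resnum in keys:
        res_mask |= (~atoms.hetero) & (atoms.chain_id == chain) & (atoms.res_id == resnum)
    return BindingSite(
        structure_id=structure_id,
        atoms=atoms[res_mask],
        residue_keys=tuple(keys),
        ligand_resname=ligand_resname,
        radius=radius,
    )


@dataclass(frozen=True)
class SiteComparison:
    percent_identity: float
    rmsd: float
    sasa_a: float
    sasa_b: float
    aligned_pairs: tuple
    n_rmsd_atoms: int
    atom_mode: str


def _aligned_residue_pairs(site_a: BindingSite, site_b: BindingSite) -> list[tuple]:
    """Pair residues of two sites, gap-free when lengths match, else by
    global alignment of the one-letter residue strings."""
    na, nb = len(site_a.residue_keys), len(site_b.residue_keys)
    if na == nb:
        return list(zip(site_a.residue_keys, site_b.residue_keys))
    from Bio.Align import PairwiseAligner
    from Bio.Data.PDBData import protein_letters_3to1

    def seq(site):
        return "".join(
            protein_letters_3to1.get(n.upper(), "X") for n in site.residue_names
        )

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq(site_a), seq(site_b))[0]
    pairs = []
    for (sa, ea), (sb, eb) in zip(aln.aligned[0], aln.aligned[1]):
        for off in range(ea - sa):
            pairs.append((site_a.residue_keys[sa + off], site_b.residue_keys[sb + off]))
    if not pairs:
        raise ValueError("no alignable residue pairs between sites")
    return pairs


_BACKBONE = ("N", "CA", "C", "O")


def compare_sites(
    site_a: BindingSite,
    site_b: BindingSite,
    atom_mode: str = "heavy",
    vdw_radii: Optional[dict] = None,
) -> SiteComparison:
    """Identity, Kabsch RMSD and SASA comparison of two binding sites.

    ``atom_mode`` selects the superposed atoms: ``"ca"`` (Cα only),
    ``"backbone"`` (N/CA/C/O) or ``"heavy"`` (all shared heavy-atom names
    of identically named aligned residues; differing residues contribute
    backbone atoms only).
    """
    if atom_mode not in ("ca", "backbone", "heavy"):
        raise ValueError("atom_mode must be ca|backbone|heavy")
    pairs = _aligned_residue_pairs(site_a, site_b)

    def res_atoms(site, key):
        mask = (site.atoms.chain_id == key[0]) & (site.atoms.res_id == key[1])
        sub = site.atoms[mask]
        return {str(n): c for n, c in zip(sub.atom_name, sub.coord)}, str(sub.res_name[0])

    n_identical = 0
    coords_a, coords_b = [], []
    for ka, kb in pairs:
        atoms_a, name_a = res_atoms(site_a, ka)
        atoms_b, name_b = res_atoms(site_b, kb)
        same = name_a == name_b
        if same:
            n_identical += 1
        if atom_mode == "ca":
            wanted = ("CA",)
        elif atom_mode == "backbone":
            wanted = _BACKBONE
        else:
            wanted = sorted(atoms_a.keys() & atoms_b.keys()) if same else _BACKBONE
        for an in wanted:
            if an in atoms_a and an in atoms_b:
                coords_a.append(atoms_a[an])
                coords_b.append(atoms_b[an])
    if not coords_a:
        raise ValueError("no shared atoms to superpose")
    rmsd, _, _ = superpose_rmsd(np.array(coords_a), np.array(coords_b))
    identity = 100.0 * n_identical / len(pairs)
    sasa_a = shrake_rupley_sasa(site_a.atoms, vdw_radii=vdw_radii)[0]
    sasa_b = shrake_rupley_sasa(site_b.atoms, vdw_radii=vdw_radii)[0]
    return SiteComparison(
        percent_identity=identity,
        rmsd=rmsd,
        sasa_a=sasa_a,
        sasa_b=sasa_b,
        aligned_pairs=tuple(pairs),
        n_rmsd_atoms=len(coords_a),
        atom_mode=atom_mode,
    )


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


def shrake_rupley_sasa(
    atoms,
    probe: float = PROBE_RADIUS,
    n_points: int = SASA_POINTS,
    vdw_radii: Optional[dict] = None,
) -> tuple[float, np.ndarray]:
    """Solvent-accessible surface area by sphere-point sampling.

    ``atoms`` is a Biotite AtomArray or an ``(coords, elements)`` pair.
    Each atom's solvent sphere (vdW radius + probe) is sampled with a
    deterministic golden-spiral point set; points buried inside any
    neighbor's solvent sphere are discarded. Hydrogens are skipped (their
    area is absorbed by the heavy atoms, the common united-atom choice).

    Returns ``(total_area, per_atom_area)`` in Å².
    """
    radii_table = dict(VDW_RADII)
    if vdw_radii:
        radii_table.update({k.upper(): v for k, v in vdw_radii.items()})
    if isinstance(atoms, tuple):
        coords, elements = atoms
        coords = np.asarray(coords, float)
        elements = [str(e).upper() for e in elements]
    else:
        coords = np.asarray(atoms.coord, float)
        elements = [str(e).upper() for e in atoms.element]
    keep = [i for i, e in enumerate(elements) if e != "H"]
    coords = coords[keep]
    elements = [elements[i] for i in keep]
    radii = np.empty(len(elements))
    for i, e in enumerate(elements):
        if e not in radii_table:
            raise ValueError(f"no van der Waals radius configured for element {e!r}")
        radii[i] = radii_table[e] + probe
    sphere = _fibonacci_sphere(n_points)
    n = len(coords)
    per_atom = np.zeros(n)
    if n == 0:
        return 0.0, per_atom
    # pairwise neighbor lists: only atoms whose solvent spheres intersect
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    # exactly coincident same-radius atoms are degenerate: count one copy
    dup = np.zeros(n, dtype=bool)
    for i in range(n):
        if dup[i]:
            continue
        same = (d[i] < 1e-6) & (np.abs(radii - radii[i]) < 1e-9)
        same[: i + 1] = False
        dup |= same
    keep_idx = np.where(~dup)[0]
    coords, radii, d = coords[keep_idx], radii[keep_idx], d[np.ix_(keep_idx, keep_idx)]
    sub_area = np.zeros(len(coords))
    n = len(coords)
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        neighbors = np.where((d[i] < radii[i] + radii) & (np.arange(n) != i))[0]
        if len(neighbors):
            dist2 = ((pts[:, None, :] - coords[neighbors][None, :, :]) ** 2).sum(-1)
            buried = (dist2 < (radii[neighbors] ** 2)[None, :]).any(axis=1)
            accessible = int((~buried).sum())
        else:
            accessible = n_points
        sub_area[i] = 4.0 * np.pi * radii[i] ** 2 * accessible / n_points
    per_atom[keep_idx] = sub_area
    return float(per_atom.sum()), per_atom


# ---------------------------------------------------------------------------
# Affinity pocket
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PocketReport:
    atom_indices: tuple[int, ...]
    centroid: tuple[float, float, float]
    inscribed_radius: float


def describe_affinity_pocket(
    site: BindingSite,
    glycine_loop_resrange: tuple[int, int],
    catalytic_lys_resnum: int,
    grid_spacing: float = 0.5,
) -> PocketReport:
    """Describe the pocket between the glycine-rich loop and the catalytic Lys.

    Collects the loop-range atoms and the lysine side-chain atoms, then
    scans a ``grid_spacing`` grid spanning the region between the two
    groups for the point with maximal clearance (largest inscribed
    sphere). A loop in direct contact with the lysine yields radius ~ 0,
    not an error.
    """
    atoms = site.atoms
    lo, hi = glycine_loop_resrange
    loop_mask = (~atoms.hetero) & (atoms.res_id >= lo) & (atoms.res_id <= hi)
    lys_mask = (~atoms.hetero) & (atoms.res_id == catalytic_lys_resnum)
    if not np.any(loop_mask):
        raise ValueError(f"glycine-loop residues {lo}-{hi} not in site")
    if not np.any(lys_mask):
        raise ValueError(f"catalytic lysine {catalytic_lys_resnum} not in site")
    side_chain = lys_mask & ~np.isin(atoms.atom_name, list(_BACKBONE))
    if not np.any(side_chain):
        side_chain = lys_mask
    pocket_idx = np.where(loop_mask | side_chain)[0]
    pocket_coords = atoms.coord[pocket_idx]
    heavy = pocket_coords[np.asarray([atoms.element[i] != "H" for i in pocket_idx])]

    lob = atoms.coord[loop_mask].mean(axis=0)
    lyb = atoms.coord[side_chain].mean(axis=0)
    lo_box = np.minimum(lob, lyb) - 2.0
    hi_box = np.maximum(lob, lyb) + 2.0
    axes = [np.arange(lo_box[k], hi_box[k] + grid_spacing / 2, grid_spacing) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    clearance = np.linalg.norm(grid[:, None, :] - heavy[None, :, :], axis=-1).min(axis=1)
    # a pocket point must sit between the walls, not outside the region
    mid_ok = (
        np.linalg.norm(grid - lob, axis=1) + np.linalg.norm(grid - lyb, axis=1)
        <= np.linalg.norm(lob - lyb) + 4.0
    )
    clearance = np.where(mid_ok, clearance, -np.inf)
    best = int(np.argmax(clearance))
    vdw_mean = 1.7
    radius = max(0.0, float(clearance[best]) - vdw_mean)
    return PocketReport(
        atom_indices=tuple(int(i) for i in pocket_idx),
        centroid=tuple(float(v) for v in grid[best]),
        inscribed_radius=radius,
    )
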