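"""PDB reading, binding-site extraction/comparison, SASA, pockets."""

import math

import numpy as np
import pytest

from phorescreen.structures import (
    compare_sites,
    describe_affinity_pocket,
    extract_site,
    read_structure,
    shrake_rupley_sasa,
)
from phorescreen.synthetic import ToyStructureSpec, _pdb_line, make_toy_structure_pair


def write_pdb(tmp_path, name, lines):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\nEND\n")
    return p


def simple_residue(serial0, resname, resseq, center, chain="A"):
    offs = {"N": (-1.2, 0.8, 0), "CA": (0, 0, 0), "C": (1.3, 0.5, 0), "O": (1.4, 1.7, 0)}
    lines = []
    for i, (aname, off) in enumerate(offs.items()):
        xyz = np.asarray(center, float) + np.asarray(off)
        lines.append(_pdb_line("ATOM", serial0 + i, aname, resname, chain, resseq, xyz, aname[0]))
    return lines


class TestReadStructure:
    def test_toy_three_residue_round_trip(self, tmp_path):
        lines = []
        for i, c in enumerate([(0, 0, 0), (4, 0, 0), (8, 0, 0)]):
            lines += simple_residue(1 + 4 * i, "ALA", i + 1, c)
        p = write_pdb(tmp_path, "toy.pdb", lines)
        atoms = read_structure(p)
        assert len(set(atoms.res_id[~atoms.hetero])) == 3

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        lines = [
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C",
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.40  0.00           C",
        ]
        atoms = read_structure(write_pdb(tmp_path, "alt.pdb", lines))
        assert atoms.array_length() == 1
        assert atoms.coord[0][0] == pytest.approx(0.0)

    def test_multi_model_uses_first(self, tmp_path):
        res = simple_residue(1, "GLY", 1, (0, 0, 0))
        res2 = simple_residue(1, "GLY", 1, (9, 9, 9))
        lines = ["MODEL        1", *res, "ENDMDL", "MODEL        2", *res2, "ENDMDL"]
        atoms = read_structure(write_pdb(tmp_path, "nmr.pdb", lines))
        assert atoms.coord[:, 0].max() < 5

    def test_no_atom_records_rejected(self, tmp_path):
        p = write_pdb(tmp_path, "empty.pdb", ["HETATM    1  C1  LIG A 900       0.000   0.000   0.000  1.00  0.00           C"])
        with pytest.raises(ValueError, match="no ATOM"):
            read_structure(p)


class TestExtractSite:
    def _structure_with_ligand(self, tmp_path, residue_centers):
        lines = []
        serial = 1
        for i, c in enumerate(residue_centers):
            lines += simple_residue(serial, "ALA", i + 1, c)
            serial += 4
        lines.append(_pdb_line("HETATM", serial, "C1", "LIG", "A", 900, np.zeros(3), "C"))
        return read_structure(write_pdb(tmp_path, "s.pdb", lines))

    def test_boundary_residue_included(self, tmp_path):
        # CA at 9.9 from the ligand atom -> inside a 10 A site
        atoms = self._structure_with_ligand(tmp_path, [(9.9, 0, 0)])
        site = extract_site(atoms, "LIG", 10.0)
        assert len(site.residue_keys) == 1

    def test_fully_distant_residue_excluded(self, tmp_path):
        # every heavy atom of the residue beyond 10 A
        atoms = self._structure_with_ligand(tmp_path, [(14, 0, 0)])
        with np.errstate(all="ignore"):
            site = extract_site(atoms, "LIG", 10.0)
        assert len(site.residue_keys) == 0

    def test_planted_site_count_exact(self, tmp_path):
        centers = [(6, 0, 0), (0, 6, 0), (0, 0, 6), (-6, 0, 0), (0, -6, 0),
                   (30, 0, 0), (0, 30, 0)]
        atoms = self._structure_with_ligand(tmp_path, centers)
        site = extract_site(atoms, "LIG", 10.0)
        assert len(site.residue_keys) == 5

    def test_monotone_in_radius(self, tmp_path):
        centers = [(5, 0, 0), (9, 0, 0), (13, 0, 0), (20, 0, 0)]
        atoms = self._structure_with_ligand(tmp_path, centers)
        small = set(extract_site(atoms, "LIG", 7.0).residue_keys)
        big = set(extract_site(atoms, "LIG", 12.0).residue_keys)
        assert small <= big

    def test_absent_ligand_lists_available(self, tmp_path):
        atoms = self._structure_with_ligand(tmp_path, [(5, 0, 0)])
        with pytest.raises(ValueError, match="LIG"):
            extract_site(atoms, "XYZ", 10.0)


class TestCompareSites:
    def test_site_against_itself(self, tmp_path):
        _, _, _ = make_toy_structure_pair(ToyStructureSpec(seed=1), out_dir=tmp_path)
        site = extract_site(read_structure(tmp_path / "a.pdb"), "LIG", 10.0)
        cmp_ = compare_sites(site, site)
        assert cmp_.percent_identity == 100.0
        assert cmp_.rmsd == pytest.approx(0.0, abs=1e-9)
        assert cmp_.sasa_a == pytest.approx(cmp_.sasa_b)

    @pytest.mark.parametrize("atom_mode", ["ca", "backbone", "heavy"])
    def test_rigidly_moved_renamed_pair(self, tmp_path, atom_mode):
        spec = ToyStructureSpec(
            n_site_residues=10, n_distant_residues=4, identity_fraction=0.9,
            rigid_offset=(4.0, -2.0, 1.0), rotate=True, seed=6,
        )
        _, _, truth = make_toy_structure_pair(spec, out_dir=tmp_path)
        sa = extract_site(read_structure(tmp_path / "a.pdb"), "LIG", 10.0)
        sb = extract_site(read_structure(tmp_path / "b.pdb"), "LIG", 10.0)
        cmp_ = compare_sites(sa, sb, atom_mode=atom_mode)
        assert cmp_.percent_identity == pytest.approx(truth["identity_percent"])
        # PDB text carries 3 decimals, so the rigid-motion RMSD only
        # vanishes to coordinate-rounding precision
        assert cmp_.rmsd == pytest.approx(truth["rmsd"], abs=2e-3)


class TestSasa:
    def test_single_sphere_analytic(self):
        total, per = shrake_rupley_sasa((np.zeros((1, 3)), ["C"]))
        analytic = 4 * math.pi * (1.70 + 1.4) ** 2
        assert total == pytest.approx(analytic, rel=0.01)

    def test_distant_atoms_are_additive(self):
        coords = np.array([[0, 0, 0], [100, 0, 0]], float)
        total, per = shrake_rupley_sasa((coords, ["N", "N"]))
        single = 4 * math.pi * (1.55 + 1.4) ** 2
        assert total == pytest.approx(2 * single, rel=0.01)

    def test_fully_overlapping_atoms_count_once(self):
        coords = np.zeros((2, 3))
        total, per = shrake_rupley_sasa((coords, ["O", "O"]))
        single = 4 * math.pi * (1.52 + 1.4) ** 2
        assert total == pytest.approx(single, rel=0.01)

    def test_point_count_convergence(self, tmp_path):
        _, _, _ = make_toy_structure_pair(ToyStructureSpec(seed=2), out_dir=tmp_path)
        atoms = read_structure(tmp_path / "a.pdb")
        t1, _ = shrake_rupley_sasa(atoms, n_points=960)
        t2, _ = shrake_rupley_sasa(atoms, n_points=1920)
        assert abs(t1 - t2) / t2 < 0.005

    def test_agreement_with_independent_implementation(self, tmp_path):
        import biotite.structure as struc

        _, _, _ = make_toy_structure_pair(ToyStructureSpec(seed=3), out_dir=tmp_path)
        atoms = read_structure(tmp_path / "a.pdb")
        prot = atoms[~atoms.hetero]
        ours, _ = shrake_rupley_sasa(prot)
        ref = float(np.nansum(struc.sasa(prot, probe_radius=1.4, point_number=960,
                                         vdw_radii="Single")))
        assert ours == pytest.approx(ref, rel=0.03)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            shrake_rupley_sasa((np.zeros((1, 3)), ["Xx"]))


class TestAffinityPocket:
    def _cavity_structure(self, tmp_path):
        # glycine-loop wall at z=+6, lysine at z=-6, ligand in between
        lines = []
        serial = 1
        for i, x in enumerate((-4.0, 0.0, 4.0)):
            lines += simple_residue(serial, "GLY", i + 1, (x, 0, 6.0))
            serial += 4
        for aname, off in (("N", (-1.2, 0.8, 0)), ("CA", (0, 0, 0)), ("C", (1.3, 0.5, 0)),
                           ("O", (1.4, 1.7, 0)), ("CB", (-0.3, -1.2, -0.8)),
                           ("NZ", (0.2, -2.2, -1.8))):
            xyz = np.array([0, 0, -6.0]) + np.asarray(off)
            lines.append(_pdb_line("ATOM", serial, aname, "LYS", "A", 10, xyz, aname[0]))
            serial += 1
        lines.append(_pdb_line("HETATM", serial, "C1", "LIG", "A", 900, np.zeros(3), "C"))
        atoms = read_structure(write_pdb(tmp_path, "cavity.pdb", lines))
        return extract_site(atoms, "LIG", 12.0)

    def test_centroid_sits_inside_the_cavity(self, tmp_path):
        site = self._cavity_structure(tmp_path)
        report = describe_affinity_pocket(site, (1, 3), 10)
        walls = site.atoms.coord
        d = np.linalg.norm(walls - np.asarray(report.centroid), axis=1).min()
        assert d > 1.0
        assert report.inscribed_radius > 0.5

    def test_missing_lysine_is_explicit_error(self, tmp_path):
        site = self._cavity_structure(tmp_path)
        with pytest.raises(ValueError, match="lysine"):
            describe_affinity_pocket(site, (1, 3), 99)

    def test_contacting_walls_report_near_zero_radius(self, tmp_path):
        lines = []
        serial = 1
        lines += simple_residue(serial, "GLY", 1, (0, 0, 1.5)); serial += 4
        for aname, off in (("N", (-1.2, 0.8, 0)), ("CA", (0, 0, 0)), ("CB", (0, 0.5, 1.0))):
            xyz = np.array([0, 0, -1.5]) + np.asarray(off)
            lines.append(_pdb_line("ATOM", serial, aname, "LYS", "A", 5, xyz, aname[0]))
            serial += 1
        lines.append(_pdb_line("HETATM", serial, "C1", "LIG", "A", 900, np.zeros(3), "C"))
        atoms = read_structure(write_pdb(tmp_path, "contact.pdb", lines))
        site = extract_site(atoms, "LIG", 12.0)
        report = describe_affinity_pocket(site, (1, 1), 5)
        assert report.inscribed_radius < 1.0      # contact -> essentially no sphere
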