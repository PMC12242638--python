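"""Extract and compare two ligand-defined kinase binding sites.

Generates a toy structure pair - same fold, one site residue renamed,
whole structure rigidly moved - then extracts the 10 A ligand-radius
sites and reports residue identity, Kabsch RMSD and Shrake-Rupley SASA.
"""

import tempfile
from pathlib import Path

from phorescreen.structures import compare_sites, extract_site, read_structure
from phorescreen.synthetic import ToyStructureSpec, make_toy_structure_pair

spec = ToyStructureSpec(
    n_site_residues=10, n_distant_residues=5, identity_fraction=0.9,
    rigid_offset=(5.0, -3.0, 2.0), rotate=True, seed=6,
)
with tempfile.TemporaryDirectory() as td:
    _, _, truth = make_toy_structure_pair(spec, out_dir=td)
    site_a = extract_site(read_structure(Path(td) / "a.pdb"), "LIG", radius=10.0)
    site_b = extract_site(read_structure(Path(td) / "b.pdb"), "LIG", radius=10.0)
    cmp_ = compare_sites(site_a, site_b, atom_mode="heavy")

print(f"site A: {len(site_a.residue_keys)} residues within 10 A of the ligand")
print(f"residue identity: {cmp_.percent_identity:.0f}% "
      f"(planted truth {truth['identity_percent']:.0f}%)")
print(f"site RMSD after Kabsch superposition: {cmp_.rmsd:.4f} A "
      f"over {cmp_.n_rmsd_atoms} atoms")
print(f"site SASA: {cmp_.sasa_a:.0f} vs {cmp_.sasa_b:.0f} A^2")
# The rigid motion between the copies is removed by superposition, so the
# residual RMSD reflects only PDB coordinate rounding; the one renamed
# residue shows up as 90% identity, and the SASA difference as the
# renamed residue's lost side-chain surface.
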