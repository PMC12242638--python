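# phorescreen

Pharmacophore-constrained virtual screening for kinase inhibitor
discovery, packaged as a tested, reusable Python library.

The pipeline reproduces a ligand-based + structure-informed screening
campaign against the Rho-associated kinases ROCK1/ROCK2, a drug-repurposing
target family in cardiovascular and neurodegenerative disease:

1. **Curation** — bioactivity tables (ChEMBL-style exports) are split into
   actives (Ki or Kd ≤ 100 nM) and inactives (≥ 5000 nM); IC50 values are
   excluded because they are not comparable across assay conditions. Salt
   counterions are stripped, molecules with unspecified stereocenters or
   MW ≥ 550 Da removed, and one diverse representative per cluster is
   chosen by hierarchical clustering on Tanimoto distance cut at 0.5.
2. **Chemical space** — ECFP fingerprints (diameter 6, 2048 bits),
   Z-score + PCA or Tanimoto-distance MDS embedding, and clustering-model
   selection by the mean silhouette coefficient s̄ = mean((b − a)/max(a, b))
   over hierarchical, k-means and k-medoids at k = 3…30, with k-medoid
   cluster representatives.
3. **Pharmacophore** — typed 3D models (HBA/HBD/aromatic-ring points with
   radius rᵢ and weight wᵢ), feature perception on conformers, and
   consensus-map elucidation from overlaid ligand poses. The four-point
   ROCK1 (PDB 6E9W frame) and ROCK2 (PDB 7JNT frame) ATP-site models ship
   as built-ins, including the mandatory hinge H-bond constraint
   (MET156:H / MET172:H, weight 10).
4. **Screening** — frame-free matching: for every kind-compatible injective
   assignment of model points to ligand features, a Kabsch least-squares
   proper rotation superposes features onto point centers; a point is
   satisfied when its feature lands within rᵢ, and the score is
   Σ wᵢ·[satisfied]. Libraries are ranked over ≤ 200 conformers per
   compound.
5. **Evaluation** — ROC curves with grouped ties, trapezoidal AUC (equal to
   the tie-corrected Mann–Whitney statistic) and enrichment factors.

A structures module adds ATP-site comparison: 10 Å ligand-radius site
extraction from PDB files, residue identity, Kabsch site RMSD and
Shrake–Rupley SASA (1.4 Å probe), plus a geometric description of the
"affinity pocket" between the glycine-rich loop and the catalytic lysine.
A synthetic-data module generates every input class with planted ground
truth, so the full pipeline is testable offline.

## Worked example

`examples/` contains one narrative script per capability. Screening the
planted validation library (`examples/04_screen_library.py` and
`examples/05_validate_roc.py`):

```text
model ROCK1 (frame 6E9W), 4 points, max score 25
top 5 of the ranked library:
  ACT0004  score= 25.0 rmsd=0.114 A  (active)
  ACT0016  score= 25.0 rmsd=0.183 A  (active)
  ...
20 actives / 180 decoys at 0.3 A jitter: AUC = 0.994
enrichment factor in the top 10%: EF(0.1) = 9.50 (max possible 10)
jitter (A) -> AUC:
     0     1.000
   0.3     0.987
     1     0.693
     3     0.523
    10     0.517
```

A score of 25 (= 10 + 5 + 5 + 5) means the hinge acceptor, the
catalytic-lysine acceptor and both aromatic-ring centers all fall inside
their tolerance radii after rigid alignment; AUC 0.994 means the protocol
ranks essentially every geometry-bearing active above the
arrangement-scrambled decoys, and the decay toward AUC 0.5 with growing
positional noise shows the score responds to geometry rather than to
library composition.

The library can also be driven from the shell:

```sh
phorescreen simulate activity --seed 1 --out run/sim
phorescreen curate --activities run/sim/activities.csv --out run/curated
phorescreen run --config run.yaml
```

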