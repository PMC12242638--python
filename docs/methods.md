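# Methods

## Scope and model

`phorescreen` implements a ligand-based + structure-informed virtual
screening protocol for ATP-competitive kinase inhibitors, parameterized
for the ROCK1/ROCK2 isoforms. The central object is the pharmacophore
model: a set of typed 3D points (hydrogen-bond acceptor, donor, or
aromatic-ring centroid), each with a center **c**ᵢ (Å), a tolerance
radius rᵢ and a weight wᵢ, optionally plus a protein H-bond constraint
naming a donor hydrogen (the hinge methionine backbone amide). The
built-in ROCK1 model lives in the coordinate frame of PDB 6E9W and the
ROCK2 model in that of 7JNT; matching is frame-free, so the frame choice
is internal.

### Matching and scoring

Given a conformer's perceived features, the matcher enumerates injective,
kind-compatible assignments of model points to features over every point
subset that contains the required points (by default the hinge HBA).
Assignments are pre-filtered by pairwise distance compatibility
(|d_feat − d_point| ≤ rₐ + r_b): two points whose assigned features
disagree beyond the combined radii cannot both be satisfied by any rigid
placement. Each surviving assignment is scored under its least-squares
rigid superposition (Kabsch, SVD with the determinant sign fixed so that
reflections are never returned): point i is satisfied when its feature
lands within rᵢ of **c**ᵢ, and score = Σ wᵢ over satisfied points, with
the required points obliged to be satisfied, not merely assigned. The best
assignment maximizes the score; ties break to lower superposition RMSD,
then to the lexicographically smallest assignment, making rankings
deterministic. The pruned search is checked against an unpruned
exhaustive enumeration on randomized instances in the test suite and the
acceptance script.

Scoring is a hard in/out sum of weights rather than a smooth fitness
blend: commercial docking engines fold constraint weights into a
proprietary fitness, which is not publishable as an algorithm. The
protein H-bond requirement is therefore expressed two ways: the hinge
HBA point is required (a no-match compound scores 0), and when the model
carries resolved donor geometry, an explicit geometric gate is applied —
acceptor…H ≤ 2.5 Å and donor–H…acceptor angle ≥ 120°, both configurable.

### Feature perception

Typing rules, kept deliberately editable: acceptors are N/O atoms that are
not positively charged, excluding amide nitrogens and pyrrole-type
aromatic N–H; donors are N/O bearing a hydrogen; one aromatic-ring feature
per smallest aromatic ring at the unweighted centroid of the ring atoms.
Output order is deterministic (kind, then first atom index).

### Consensus elucidation

Consensus maps from pre-aligned ligand poses group same-kind features
across ligands by single linkage at a 1.0 Å merge radius; a group
supported by ≥ 60% of the ligands becomes a point with center = group
centroid and radius = max(0.5 Å floor, RMS spread). Single linkage is the
right topology here because crystal-pose scatter is chain-like rather
than spherical; both parameters are exposed. Consensus assumes the poses
already share a frame (e.g. superposed crystal structures); it performs
no flexible overlay optimization.

## Curation rules

Only Ki/Kd measurements define activity classes (IC50 varies with ATP
concentration and assay format). Defaults: active ≤ 100 nM, inactive
≥ 5000 nM — the inclusive inactive bound matches the operational
workflow-filter reading; `inactive_exclusive=True` switches to a strict
> 5000 nM. The band in between is excluded as "intermediate activity",
never silently dropped; the partition property (every record lands in
exactly one bucket) is a tested invariant. A compound with several Ki/Kd
entries keeps its most potent record — conservative for the active class.
Structural filters: largest organic fragment (salt stripping), canonical
deduplication, removal of molecules with any unspecified potential
stereocenter, and MW ≥ 550 Da (inclusive), computed on the desalted
parent with average atomic masses. Diversity selection clusters ECFP
Tanimoto distances by average-linkage hierarchical clustering cut at 0.5
and keeps each cluster's medoid; linkage is configurable since different
linkage criteria shift cluster counts on real data.

The hinge-binder prefilter accepts molecules containing an aromatic
N-heterocycle of ring size 5 or 6, or a fused bicyclic aromatic system of
10 perimeter atoms containing nitrogen — the motif classes that hydrogen-
bond to the kinase hinge.

## Chemical space

Fingerprints are Morgan/ECFP, radius 3 (diameter 6), 2048 bits. Z-scoring
maps constant bit columns to zero instead of dropping them, preserving
column indexing. PCA keeps the top two components and min–max rescales
each to [0, 1]; MDS is metric SMACOF initialized from classical
(Torgerson) scaling, which makes the layout a deterministic function of
the input and seed. Clustering selection fits hierarchical (average
linkage), k-means (10 restarts) and k-medoids (Voronoi iteration,
seeded farthest-point start, 10 restarts, objective non-increasing) at
each k in 3…30 and keeps the (method, k) with the highest mean
silhouette; ties prefer smaller k, then hierarchical < kmeans < kmedoids.
Silhouettes are computed in the space being clustered — the embedded 2D
coordinates on the PCA/MDS path, precomputed Tanimoto distances on the
fingerprint path.

## Structures

Binding sites are whole residues with ≥ 1 heavy atom within a
ligand-centered radius (default 10 Å); waters excluded by default. Site
comparison pairs residues gap-free in residue order when the sites have
equal length, else by global sequence alignment; identity is the percent
of aligned pairs with equal residue names, and the RMSD is a Kabsch
superposition over `ca`, `backbone` or `heavy` atom selections (default
heavy atoms of identically named pairs, backbone otherwise) — the
selection is a flag because published site-RMSD figures rarely state it.
SASA is Shrake–Rupley with a 1.4 Å probe, 960 deterministic
golden-spiral points per atom, Bondi vdW radii (shipped, overridable),
hydrogens absorbed into heavy atoms; exactly coincident same-radius atoms
are counted once. The affinity-pocket descriptor collects the
glycine-rich-loop atoms and the catalytic-lysine side chain and scans a
0.5 Å grid between the two groups for the largest inscribed sphere
(clearance minus a mean 1.7 Å vdW radius, floored at zero so wall
contact reports radius ≈ 0 rather than raising).

## Synthetic study conditions

The generators define the package's validation conditions:

* **Activity tables** — Ki/Kd values log-uniform inside each class band
  (active ≤ 100 nM, inactive ≥ 5000 nM, intermediate strictly between),
  IC50 rows potent but excluded by type; SMILES from a fragment grammar
  (aromatic cores × alkyl linkers × small substituents) guaranteeing
  parseable, unique, stereocenter-free structures.
* **Planted libraries** — the standard fixture is 20 actives / 180
  decoys. Actives carry the model's point kinds at the point centers with
  isotropic Gaussian jitter (default σ = 0.3 Å, the scale of crystal-pose
  scatter) plus 3 distractor features, then a random rigid motion per
  compound. `scramble_positions` decoys redraw positions from a Gaussian
  matched to the per-axis mean and spread of a jittered active-like set —
  extent-matched decoys, so only the geometric *arrangement* separates
  the classes and the screening AUC decays toward 0.5 (not below) as the
  jitter grows. `drop_required_feature` decoys lack every HBA and are
  structurally unmatchable under the hinge requirement.
* **Planted clusters** — isotropic Gaussian blobs (σ = 1) with centers
  placed by rejection at mutual distance ≥ 10 σ for recovery tests.
* **Toy structure pairs** — poly-alanine shells around a HETATM ligand
  (site residues at 5–8 Å, distractor residues at ~30 Å), copy B rigidly
  moved with a chosen fraction of site residues renamed to glycine; the
  truth JSON carries the exact identity and a brute-force RMSD.

What the synthetic conditions do *not* emulate: real conformational
strain, protein flexibility, tautomer/protonation ambiguity, and the
correlation structure of real chemotypes. Passing the planted-recovery
tests demonstrates the algorithms are correct and well-conditioned, not
that the screening protocol's real-world hit rate matches any particular
prospective campaign.

## Numerical choices

* Kabsch uses SVD with the smallest singular direction flipped when the
  unconstrained optimum is a reflection; RMSD on exactly transformable
  sets is < 1e-9 (tested).
* Radius satisfaction uses a 1e-9 slack so exact-boundary placements are
  deterministic.
* Tanimoto distance of two all-zero fingerprints is 0 by convention
  (identical objects).
* ROC ties are grouped into single curve steps (diagonal segments), so
  metrics are independent of input order; the trapezoidal AUC is verified
  against the tie-corrected rank-sum statistic to 1e-12.
* Enrichment-factor top sets include all compounds tied with the boundary
  score.
* PDB text carries three decimals, so rigid-motion RMSDs on written
  fixtures vanish only to ~1e-3 Å; tests use that tolerance where a file
  round-trip is involved.
* Acceptance-script problem sizes: 500 random matcher instances, a
  20/180 library plus 5 × (60/120) libraries per jitter level, 100 ROC
  datasets, 100 activity tables, three planted-k clustering runs —
  chosen to make each estimate stable at a few seconds per block.

## Known limitations

* The matcher's subset enumeration is exponential in the number of model
  points; it is intended for the 4–6-point models typical of kinase
  pharmacophores, not dense feature maps.
* A single required HBA point alone always scores its weight (a single
  pair superposes exactly), so score margins — not bare matches — carry
  the ranking signal.
* Site SASA depends on the surrounding-context choice; sites are scored
  in isolation from the rest of their parent chain here, which is the
  right comparison between two equally extracted sites but not an
  absolute accessibility.
* Consensus elucidation requires pre-aligned poses and does not search
  conformers or optimize the overlay.
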