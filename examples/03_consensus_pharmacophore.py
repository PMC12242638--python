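"""Elucidate a consensus pharmacophore from overlaid ligand poses.

Emulates a set of crystal ligands sharing four interaction hotspots
(two H-bond acceptors, two aromatic-ring centers) with 0.2 A positional
scatter, and recovers the consensus map by single-linkage grouping.
"""

import numpy as np

from phorescreen.pharmacophore import (
    ConsensusParams,
    FeatureKind,
    LigandFeature,
    consensus_map,
)

rng = np.random.default_rng(3)
truth = [
    (FeatureKind.HBA, (0.0, 0.0, 0.0)),       # hinge acceptor
    (FeatureKind.HBA, (5.0, 1.0, 0.5)),       # catalytic-lysine acceptor
    (FeatureKind.AromaticRing, (1.0, 2.5, 1.0)),
    (FeatureKind.AromaticRing, (6.0, 4.0, 2.0)),
]
ligands = [
    [LigandFeature(kind, tuple(np.asarray(c) + rng.normal(0, 0.2, 3)))
     for kind, c in truth]
    for _ in range(10)
]

model = consensus_map(ligands, ConsensusParams(merge_radius=1.0, min_support=0.6))
print(f"consensus model with {len(model.points)} points from {len(ligands)} ligands:")
for p in model.points:
    x, y, z = p.center
    print(f"  {p.kind.value:<12s} center=({x:5.2f},{y:5.2f},{z:5.2f}) "
          f"radius={p.radius:.2f} A")
# Each point's center is the centroid of the grouped features; its radius
# (floored at 0.5 A) reflects the pose scatter - a tolerance for matching.
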