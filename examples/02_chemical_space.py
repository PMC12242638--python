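"""Map a compound library into 2D chemical space and pick a clustering.

Fingerprints a small synthetic library (ECFP, radius 3, 2048 bits),
embeds it by Z-score + PCA, and lets the mean silhouette coefficient
choose both the clustering algorithm and the cluster count over k=3..10.
"""

from phorescreen.chemspace import (
    fingerprint_matrix,
    medoid_representatives,
    select_clustering,
    tanimoto_distance_matrix,
    zscore_pca_embed,
)
from phorescreen.synthetic import synthetic_smiles

smiles = synthetic_smiles(60, seed=5)
fps = fingerprint_matrix(smiles)
emb = zscore_pca_embed(fps)
result = select_clustering(emb.coords, k_range=range(3, 11), seed=0)

print(f"{len(smiles)} compounds, PCA explains "
      f"{100 * emb.diagnostic:.1f}% of the z-scored bit variance in 2D")
print(f"selected {result.method} with k={result.k} "
      f"(mean silhouette {result.mean_silhouette:.3f})")
d = tanimoto_distance_matrix(fps)
medoids = medoid_representatives(d, result.labels)
print("cluster medoid compounds:", [smiles[i] for i in medoids[:4]], "...")
# The silhouette (cohesion vs separation, in [-1, 1]) scores each
# candidate (algorithm, k); the winning medoids are the most central
# real molecules of each cluster - the representative chemotypes.
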