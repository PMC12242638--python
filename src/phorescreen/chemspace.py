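"""Chemical-space embedding and clustering of compound libraries.

Compounds are encoded as extended-connectivity circular fingerprints
(ECFP, diameter 6 = Morgan radius 3, hashed to 2048 bits). Two embeddings
are offered: per-bit Z-score normalization followed by 2-component PCA
(rescaled to [0, 1] per axis), and metric MDS (SMACOF with a
classical-scaling start, making it seed-stable) on the Tanimoto distance
matrix.

Clustering-model selection fits hierarchical clustering, k-means and
k-medoids over a k range (default 3-30) and keeps the (method, k)
maximizing the mean silhouette coefficient; ties break toward the smaller
k, then toward hierarchical < kmeans < kmedoids. Cluster representatives
are medoids: the member minimizing summed distance to its co-members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

N_BITS = 2048
FP_RADIUS = 3  # diameter 6
METHOD_ORDER = ("hierarchical", "kmeans", "kmedoids")


@dataclass(frozen=True)
class Embedding:
    coords: np.ndarray            # (n, 2)
    method: str                   # "PCA" | "MDS"
    diagnostic: float             # explained variance fraction or stress


@dataclass(frozen=True)
class ClusteringResult:
    labels: np.ndarray
    method: str
    k: int
    mean_silhouette: float
    medoid_indices: np.ndarray
    candidates: Optional[dict] = None  # (method, k) -> silhouette, for diagnostics


# ---------------------------------------------------------------------------
# Fingerprints and distances
# ---------------------------------------------------------------------------

def circular_fingerprint(smiles_or_mol, n_bits: int = N_BITS, radius: int = FP_RADIUS) -> np.ndarray:
    """ECFP-style Morgan bit vector (radius 3 / diameter 6, 2048 bits)."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    if isinstance(smiles_or_mol, str):
        mol = Chem.MolFromSmiles(smiles_or_mol)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles_or_mol!r}")
    else:
        mol = smiles_or_mol
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def fingerprint_matrix(smiles: Sequence[str], n_bits: int = N_BITS) -> np.ndarray:
    """Stack fingerprints for a compound list into an (n, n_bits) 0/1 matrix."""
    return np.array([circular_fingerprint(s, n_bits=n_bits) for s in smiles], dtype=np.uint8)


def tanimoto_distance_matrix(fps: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto distance 1 - |A∩B| / |A∪B| on fingerprint rows.

    Two all-zero fingerprints are identical by convention (distance 0).
    """
    fps = np.asarray(fps)
    if fps.ndim != 2 or fps.shape[0] < 2:
        raise ValueError("need a (n>=2, n_bits) fingerprint matrix")
    x = fps.astype(np.float64)
    inter = x @ x.T
    counts = x.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


# ---------------------------------------------------------------------------
# Embeddings
# ---------------------------------------------------------------------------

def zscore_pca_embed(fps: np.ndarray) -> Embedding:
    """Z-score the bit columns, project to the top-2 PCs, rescale to [0, 1].

    Constant bit columns map to zero under Z-scoring (they carry no
    information but keep their index); a constant embedded dimension maps
    to 0 under the min-max rescale.
    """
    from sklearn.decomposition import PCA

    x = np.asarray(fps, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("PCA embedding needs at least 3 compounds")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    pca = PCA(n_components=2, svd_solver="full")
    y = pca.fit_transform(z)
    rng = y.max(axis=0) - y.min(axis=0)
    y = np.where(rng > 0, (y - y.min(axis=0)) / np.where(rng > 0, rng, 1.0), 0.0)
    return Embedding(coords=y, method="PCA", diagnostic=float(pca.explained_variance_ratio_.sum()))


def _classical_mds_init(d: np.ndarray, dim: int = 2) -> np.ndarray:
    """Torgerson classical scaling, used as a deterministic SMACOF start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:dim]
    lam = np.clip(w[order], 0, None)
    return v[:, order] * np.sqrt(lam)


def mds_embed(distances: np.ndarray, seed: int = 0) -> Embedding:
    """2D metric MDS (least-squares SMACOF) on a precomputed distance matrix.

    Initialized from classical scaling so a given input and seed always
    produce the same layout. The reported diagnostic is the raw stress
    (sum of squared residual distances).
    """
    from sklearn.manifold import MDS

    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    init = _classical_mds_init(d)
    mds = MDS(
        n_components=2,
        metric="precomputed",
        metric_mds=True,
        n_init=1,
        init="classical_mds",
        max_iter=500,
        eps=1e-9,
        random_state=seed,
        normalized_stress=False,
    )
    coords = mds.fit_transform(d, init=init)
    return Embedding(coords=coords, method="MDS", diagnostic=float(mds.stress_))


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _hierarchical_labels(x: np.ndarray, k: int, precomputed: bool, linkage_method: str) -> np.ndarray:
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    if precomputed:
        cond = squareform(x, checks=False)
    else:
        from scipy.spatial.distance import pdist

        cond = pdist(x)
    z = linkage(cond, method=linkage_method)
    return fcluster(z, t=k, criterion="maxclust") - 1


def _farthest_point_init(d: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = d.shape[0]
    first = int(rng.integers(n))
    chosen = [first]
    mind = d[first].copy()
    for _ in range(k - 1):
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, d[nxt])
    return np.array(chosen)


def kmedoids(d: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10,
             max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, float]:
    """k-medoids by alternating assignment / medoid update (Voronoi iteration).

    Seeded farthest-point initialization with ``n_restarts`` restarts; the
    lowest-objective run wins. The objective (summed distance to assigned
    medoid) never increases across iterations.

    Returns ``(labels, medoid_indices, objective)``.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if k > n:
        raise ValueError("k cannot exceed the number of points")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        medoids = _farthest_point_init(d, k, rng)
        for _ in range(max_iter):
            labels = np.argmin(d[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.where(labels == c)[0]
                if len(members) == 0:
                    continue
                sub = d[np.ix_(members, members)].sum(axis=1)
                new_medoids[c] = members[np.argmin(sub)]
            if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                break
            medoids = new_medoids
        medoids = np.sort(medoids)
        labels = np.argmin(d[:, medoids], axis=1)
        obj = float(d[np.arange(n), medoids[labels]].sum())
        if best is None or obj < best[2]:
            best = (labels, medoids, obj)
    return best


def _silhouette(x: np.ndarray, labels: np.ndarray, precomputed: bool) -> float:
    from sklearn.metrics import silhouette_score

    if len(np.unique(labels)) < 2:
        return -1.0
    metric = "precomputed" if precomputed else "euclidean"
    return float(silhouette_score(x, labels, metric=metric))


def medoid_representatives(distances: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per cluster, the member minimizing summed distance to co-members.

    Ties break toward the lowest row index. Returns one index per distinct
    label, ordered by label.
    """
    d = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    medoids = []
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        sums = d[np.ix_(members, members)].sum(axis=1)
        medoids.append(int(members[np.argmin(sums)]))  # argmin takes first = lowest index
    return np.array(medoids)


def select_clustering(
    x: np.ndarray,
    methods: Sequence[str] = METHOD_ORDER,
    k_range: Iterable[int] = range(3, 31),
    precomputed: bool = False,
    seed: int = 0,
    linkage_method: str = "average",
) -> ClusteringResult:
    """Silhouette-driven selection of clustering algorithm and cluster count.

    Fits every requested method at every k in ``k_range`` (truncated with a
    warning when k would reach the sample count) and returns the labeling
    with the highest mean silhouette; ties break toward smaller k, then by
    method order hierarchical < kmeans < kmedoids. Medoids of the winning
    labeling are computed on the same distances used for the silhouette.

    ``x`` is either an (n, d) coordinate matrix (``precomputed=False``,
    Euclidean geometry) or an (n, n) distance matrix.
    """
    from sklearn.cluster import KMeans

    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 2 for k in ks):
        raise ValueError("k must be >= 2")
    if ks[-1] >= n:
        warnings.warn(f"k range truncated to {n - 1} (only {n} points)")
        ks = [k for k in ks if k < n]
        if not ks:
            raise ValueError("not enough points for any requested k")
    if precomputed:
        dist = x
    else:
        if np.allclose(x, x[0]):
            raise ValueError("degenerate data: all points identical, silhouette undefined")
        diff = x[:, None, :] - x[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=-1))

    bad = [m for m in methods if m not in METHOD_ORDER]
    if bad:
        raise ValueError(f"unknown methods: {bad}; choices {METHOD_ORDER}")
    methods = sorted(set(methods), key=METHOD_ORDER.index)

    candidates: dict[tuple[str, int], float] = {}
    labelings: dict[tuple[str, int], np.ndarray] = {}
    for method in methods:
        for k in ks:
            if method == "hierarchical":
                labels = _hierarchical_labels(
                    dist if precomputed else x, k, precomputed, linkage_method
                )
            elif method == "kmeans":
                if precomputed:
                    continue  # k-means needs coordinates
                km = KMeans(n_clusters=k, n_init=10, random_state=seed)
                labels = km.fit_predict(x)
            else:
                labels, _, _ = kmedoids(dist, k, seed=seed)
            sil = _silhouette(
                dist if precomputed else x, labels, precomputed
            )
            candidates[(method, k)] = sil
            labelings[(method, k)] = labels

    if not candidates:
        raise ValueError("no (method, k) candidate could be fitted")
    # maximize silhouette; ties -> smaller k -> method order
    winner = min(
        candidates,
        key=lambda mk: (-candidates[mk], mk[1], METHOD_ORDER.index(mk[0])),
    )
    labels = labelings[winner]
    # relabel to consecutive ints for stable output
    _, labels = np.unique(labels, return_inverse=True)
    return ClusteringResult(
        labels=labels,
        method=winner[0],
        k=int(len(np.unique(labels))),
        mean_silhouette=float(candidates[winner]),
        medoid_indices=medoid_representatives(dist, labels),
        candidates={f"{m}:{k}": v for (m, k), v in candidates.items()},
    )
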