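"""Fingerprints, embeddings, silhouette-selected clustering."""

import numpy as np
import pytest

from phorescreen.chemspace import (
    circular_fingerprint,
    fingerprint_matrix,
    kmedoids,
    mds_embed,
    medoid_representatives,
    select_clustering,
    tanimoto_distance_matrix,
    zscore_pca_embed,
)
from phorescreen.synthetic import PlantedClusterSpec, make_planted_clusters


def brute_force_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    """Per-point (b - a)/max(a, b) silhouette, straight from the definition."""
    n = len(labels)
    vals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            vals.append(0.0)
            continue
        a = np.mean([dist[i, j] for j in own])
        b = min(
            np.mean([dist[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels)
            if lab != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


class TestFingerprints:
    def test_canonical_invariance(self):
        assert np.array_equal(
            circular_fingerprint("OCC"), circular_fingerprint("CCO")
        )

    def test_self_similarity_is_one(self):
        fps = fingerprint_matrix(["c1ccccc1", "c1ccccc1"])
        d = tanimoto_distance_matrix(fps)
        assert d[0, 1] == 0.0

    def test_disjoint_environment_sets_give_zero_similarity(self):
        # ethane environments are all sp3-carbon-centered, benzene's all
        # aromatic: the two environment sets are disjoint, so the expected
        # Tanimoto similarity is exactly 0 (no shared bits).
        fps = fingerprint_matrix(["CC", "c1ccccc1"])
        d = tanimoto_distance_matrix(fps)
        assert d[0, 1] == 1.0

    def test_hand_counted_tanimoto(self):
        # A = {1,2,3}, B = {2,3,4}: distance = 1 - 2/4 = 0.5
        a = np.zeros(8, dtype=np.uint8)
        b = np.zeros(8, dtype=np.uint8)
        a[[1, 2, 3]] = 1
        b[[2, 3, 4]] = 1
        d = tanimoto_distance_matrix(np.stack([a, b]))
        assert d[0, 1] == pytest.approx(0.5)

    def test_all_zero_rows_are_identical_by_convention(self):
        d = tanimoto_distance_matrix(np.zeros((2, 16), dtype=np.uint8))
        assert d[0, 1] == 0.0

    def test_distance_matrix_contract(self, rng):
        fps = (rng.random((6, 64)) < 0.3).astype(np.uint8)
        d = tanimoto_distance_matrix(fps)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        assert d.min() >= 0 and d.max() <= 1


class TestEmbeddings:
    def test_pca_rescaled_to_unit_box(self, rng):
        fps = (rng.random((20, 128)) < 0.3).astype(np.uint8)
        emb = zscore_pca_embed(fps)
        assert emb.coords.min() >= 0 and emb.coords.max() <= 1 + 1e-12

    def test_pca_duplicated_row_embeds_identically(self, rng):
        fps = (rng.random((10, 64)) < 0.3).astype(np.uint8)
        fps[4] = fps[2]
        emb = zscore_pca_embed(fps)
        assert np.allclose(emb.coords[4], emb.coords[2])

    def test_pca_constant_bits_do_not_produce_nan(self, rng):
        fps = (rng.random((8, 32)) < 0.5).astype(np.uint8)
        fps[:, :10] = 1
        fps[:, 10:20] = 0
        emb = zscore_pca_embed(fps)
        assert np.all(np.isfinite(emb.coords))

    def test_pca_needs_three_compounds(self):
        with pytest.raises(ValueError):
            zscore_pca_embed(np.zeros((2, 16)))

    def test_mds_recovers_planar_configuration(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = mds_embed(d, seed=0)
        d2 = np.linalg.norm(emb.coords[:, None] - emb.coords[None, :], axis=-1)
        assert emb.diagnostic < 1e-6
        assert np.abs(d2 - d).max() < 1e-4

    def test_mds_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        emb = mds_embed(d, seed=0)
        d2 = np.linalg.norm(emb.coords[:, None] - emb.coords[None, :], axis=-1)
        off = d2[np.triu_indices(3, 1)]
        assert np.allclose(off, off[0], atol=1e-6)

    def test_mds_duplicate_point_stays_coincident(self):
        pts = np.array([[0, 0], [3, 0], [3, 0], [0, 4]], float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = mds_embed(d, seed=0)
        assert np.linalg.norm(emb.coords[1] - emb.coords[2]) < 1e-6

    def test_mds_rejects_asymmetry(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            mds_embed(d)

    def test_mds_deterministic_given_seed(self, rng):
        pts = rng.random((12, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        a = mds_embed(d, seed=3).coords
        b = mds_embed(d, seed=3).coords
        assert np.array_equal(a, b)


class TestClusteringSelection:
    def test_silhouette_matches_brute_force(self, rng):
        from sklearn.metrics import silhouette_score

        for _ in range(10):
            n = int(rng.integers(8, 50))
            x = rng.normal(size=(n, 3))
            labels = rng.integers(0, 3, n)
            if len(set(labels)) < 2:
                continue
            d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
            assert silhouette_score(x, labels) == pytest.approx(
                brute_force_silhouette(d, labels), abs=1e-12
            )

    def test_three_separated_blobs_selected(self):
        x, truth = make_planted_clusters(
            PlantedClusterSpec(k_true=3, points_per_cluster=25, separation=12, seed=1)
        )
        res = select_clustering(x, k_range=range(3, 31), seed=0)
        assert res.k == 3
        assert res.mean_silhouette > 0.8

    def test_selection_never_leaves_k_range(self, rng):
        x = rng.normal(size=(40, 2))
        res = select_clustering(x, k_range=range(3, 8), seed=0)
        assert 3 <= res.k <= 7

    def test_k_range_truncated_with_warning_on_small_n(self, rng):
        x = rng.normal(size=(10, 2))
        with pytest.warns(UserWarning, match="truncated"):
            res = select_clustering(x, k_range=range(3, 31), seed=0)
        assert res.k < 10

    def test_identical_points_are_degenerate(self):
        x = np.ones((12, 2))
        with pytest.raises(ValueError, match="degenerate"):
            select_clustering(x, k_range=range(3, 5))

    def test_precomputed_distance_path(self):
        x, truth = make_planted_clusters(
            PlantedClusterSpec(k_true=3, points_per_cluster=15, separation=12, seed=2)
        )
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        res = select_clustering(
            d, methods=("hierarchical", "kmedoids"), k_range=range(3, 10),
            precomputed=True, seed=0,
        )
        assert res.k == 3


class TestKMedoids:
    def test_objective_never_increases(self, rng):
        x = rng.normal(size=(30, 2))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        labels, medoids, obj = kmedoids(d, 4, seed=1, n_restarts=3)
        # recompute the final objective from labels + medoids
        obj2 = sum(d[i, medoids[labels[i]]] for i in range(30))
        assert obj == pytest.approx(obj2)

    def test_medoid_hand_example_collinear(self):
        # points at 0, 1, 10 on a line: summed distances 11, 10, 19
        d = np.abs(np.subtract.outer([0.0, 1.0, 10.0], [0.0, 1.0, 10.0]))
        meds = medoid_representatives(d, np.zeros(3, dtype=int))
        assert meds.tolist() == [1]

    def test_singleton_cluster_is_its_own_medoid(self):
        d = np.array([[0.0, 5.0], [5.0, 0.0]])
        meds = medoid_representatives(d, np.array([0, 1]))
        assert meds.tolist() == [0, 1]

    def test_symmetric_tie_goes_to_lower_index(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        meds = medoid_representatives(d, np.array([0, 0]))
        assert meds.tolist() == [0]
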