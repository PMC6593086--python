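"""The five non-sketch-map embeddings and their contracts."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from anglescape import (
    DihedralPCA,
    ExactTSNE,
    GeodesicIsomap,
    LaplacianEigenmaps,
    StressEmbedding,
    classical_mds,
    dpca_project,
    isomap_project,
    laplacian_eigenmaps_project,
    pairwise_dissimilarity,
    sincos_embed,
    stress_minimize,
    tsne_project,
)
from anglescape.embed import _euclidean_distances, tsne_affinities

from conftest import rigid_rmsd


def euclid(points):
    return squareform(pdist(np.asarray(points, float)))


class TestDihedralPCA:
    def test_identical_frames_collapse(self):
        x = np.tile([[0.3, -0.7, 1.1]], (5, 1))
        coords = DihedralPCA(n_components=2).fit_transform(x)
        assert np.allclose(coords, coords[0], atol=1e-12)

    def test_projection_contracts_every_pair(self, rng):
        x = rng.uniform(-np.pi, np.pi, size=(80, 6))
        proj = dpca_project(x, d=2)
        R = pairwise_dissimilarity(x).values
        r = _euclidean_distances(proj.coords)
        assert (r - R).max() <= 1e-9

    def test_single_angle_antipodal_frames(self):
        # angles 0 and pi: sin/cos points (1,0) and (-1,0); the 1-D
        # projection separates them by the chord 2, not the arc pi
        x = np.array([[0.0], [-np.pi]])
        proj = dpca_project(x, d=1)
        r = abs(proj.coords[0, 0] - proj.coords[1, 0])
        assert r == pytest.approx(2.0, abs=1e-12)
        assert r < np.pi

    def test_matches_reference_pca_implementation(self, rng):
        from sklearn.decomposition import PCA

        x = rng.uniform(-np.pi, np.pi, size=(50, 4))
        ours = DihedralPCA(n_components=3).fit(x)
        ref = PCA(n_components=3).fit(sincos_embed(x))
        # same spectrum (sklearn divides by N-1, ours by N)
        assert np.allclose(ours.explained_variance_,
                           ref.explained_variance_ * 49 / 50, atol=1e-10)
        # same subspace: components agree up to sign
        dots = np.abs(np.sum(ours.components_ * ref.components_, axis=1))
        assert np.allclose(dots, 1.0, atol=1e-9)

    def test_out_of_sample_transform_is_consistent(self, rng):
        x = rng.uniform(-np.pi, np.pi, size=(40, 5))
        est = DihedralPCA(n_components=2).fit(x)
        assert np.allclose(est.transform(x), est.embedding_, atol=1e-12)

    def test_too_many_components_raises(self):
        with pytest.raises(ValueError):
            DihedralPCA(n_components=4).fit(np.zeros((10, 2)))

    def test_permutation_equivariance(self, rng):
        x = rng.uniform(-np.pi, np.pi, size=(30, 4))
        perm = rng.permutation(30)
        a = dpca_project(x, d=2).coords
        b = dpca_project(x[perm], d=2).coords
        assert np.allclose(a[perm], b, atol=1e-9)


class TestStressEmbedding:
    def test_recovers_planar_configuration_exactly(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        proj = stress_minimize(euclid(pts), d=2)
        assert proj.params["stress"] <= 1e-8
        assert rigid_rmsd(pts, proj.coords) <= 1e-4

    def test_two_points_land_exactly_apart(self):
        delta = 2.37
        proj = stress_minimize(np.array([[0, delta], [delta, 0.0]]), d=1)
        assert abs(proj.coords[0, 0] - proj.coords[1, 0]) == pytest.approx(delta)

    def test_tetrahedron_cannot_flatten(self):
        D = np.ones((4, 4)) - np.eye(4)
        proj = stress_minimize(D, d=2)
        assert proj.params["stress"] > 1e-3

    def test_loss_trace_is_non_increasing(self, rng):
        pts = rng.standard_normal((20, 5))
        proj = stress_minimize(euclid(pts), d=2, init="random", seed=1)
        assert np.all(np.diff(proj.loss_trace) <= 1e-12)

    def test_asymmetric_input_rejected(self):
        D = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            stress_minimize(D, d=1)


class TestGeodesicIsomap:
    def test_chain_geodesics_equal_line_distances(self):
        pts = np.arange(6, dtype=float)[:, None]
        D = euclid(pts)
        est = GeodesicIsomap(n_neighbors=2, n_components=1,
                             dissimilarity="precomputed").fit(D)
        assert np.allclose(est.geodesics_, D, atol=1e-12)
        spacing = np.diff(np.sort(est.embedding_[:, 0]))
        assert np.allclose(spacing, 1.0, atol=1e-8)

    def test_complete_graph_equals_classical_mds(self, rng):
        pts = rng.standard_normal((50, 5))
        D = euclid(pts)
        proj = isomap_project(D, k=49, d=2)
        ref, _ = classical_mds(D, 2)
        assert np.abs(proj.coords - ref).max() <= 1e-8

    def test_disconnected_graph_names_components(self):
        pts = np.array([[0.0], [0.1], [0.2], [50.0], [50.1], [50.2]])
        with pytest.raises(ValueError, match=r"\[3, 3\]"):
            isomap_project(euclid(pts), k=2, d=1)

    def test_permutation_equivariance(self, rng):
        pts = rng.standard_normal((25, 3))
        D = euclid(pts)
        perm = rng.permutation(25)
        a = isomap_project(D, k=5, d=2).coords
        b = isomap_project(D[np.ix_(perm, perm)], k=5, d=2).coords
        # compare geometry, not raw coordinates (eigenvector sign/order may
        # legitimately differ under permutation)
        assert rigid_rmsd(a[perm], b) <= 1e-7


class TestLaplacianEigenmaps:
    def test_constant_eigenvector_is_excluded(self, rng):
        pts = rng.standard_normal((20, 3))
        est = LaplacianEigenmaps(n_neighbors=4, n_components=2,
                                 dissimilarity="precomputed").fit(euclid(pts))
        assert np.all(est.eigenvalues_ > 1e-10)
        # no retained eigenvector is (numerically) constant
        assert np.all(est.embedding_.std(axis=0) > 1e-10)

    def test_weak_bridge_separates_clusters_by_sign(self):
        # two tight triads bridged by a moderate gap
        pts = np.array([[0.0], [0.1], [0.2], [2.0], [2.1], [2.2]])
        proj = laplacian_eigenmaps_project(euclid(pts), k=3, gamma=1.0, d=1)
        signs = np.sign(proj.coords[:, 0])
        assert len(set(signs[:3])) == 1
        assert len(set(signs[3:])) == 1
        assert signs[0] != signs[3]

    def test_complete_graph_eigenvalue_multiplicity(self):
        # equal weights on K_n: all non-trivial eigenvalues of the
        # normalized problem coincide at n / (n - 1)
        n = 6
        D = np.ones((n, n)) - np.eye(n)
        est = LaplacianEigenmaps(n_neighbors=n - 1, kernel_gamma=1e-9,
                                 n_components=3,
                                 dissimilarity="precomputed").fit(D)
        assert np.allclose(est.eigenvalues_, n / (n - 1), atol=1e-6)

    def test_invalid_gamma_raises(self):
        with pytest.raises(ValueError):
            LaplacianEigenmaps(kernel_gamma=0.0).fit(np.zeros((3, 3)))

    def test_disconnected_graph_raises(self):
        pts = np.array([[0.0], [0.1], [50.0], [50.1]])
        with pytest.raises(ValueError, match="disconnected"):
            laplacian_eigenmaps_project(euclid(pts), k=1, d=1)


class TestExactTSNE:
    def test_conditional_perplexities_hit_target(self, rng):
        D = euclid(rng.standard_normal((60, 4)))
        _, perp = tsne_affinities(D, perplexity=20.0)
        assert np.abs(perp - 20.0).max() <= 1e-3

    def test_three_equidistant_points_give_uniform_conditionals(self):
        D = np.ones((3, 3)) - np.eye(3)
        P, _ = tsne_affinities(D, perplexity=2.0)
        # symmetrized p_ij = 1/(2N) * (1/2 + 1/2) = 1/6 off-diagonal
        off = P[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0 / 6.0, atol=1e-9)

    def test_loss_decreases_after_exaggeration(self, rng):
        D = euclid(rng.standard_normal((50, 5)))
        proj = tsne_project(D, perplexity=12, d=2, seed=0, iters=300)
        assert proj.loss_trace[249] < proj.loss_trace[49]

    def test_excessive_perplexity_raises(self):
        with pytest.raises(ValueError):
            tsne_project(np.ones((5, 5)) - np.eye(5), perplexity=5.0)

    def test_same_seed_reproduces(self, rng):
        D = euclid(rng.standard_normal((30, 3)))
        a = ExactTSNE(perplexity=8, random_state=3, n_iter=50,
                      dissimilarity="precomputed").fit(D).embedding_
        b = ExactTSNE(perplexity=8, random_state=3, n_iter=50,
                      dissimilarity="precomputed").fit(D).embedding_
        assert np.array_equal(a, b)
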