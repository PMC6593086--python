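"""Grid/KDE/Quick-Shift clustering, covariance diagnostics, and the
bootstrap mode hierarchy."""

import numpy as np
import pytest

from anglescape import (
    ClusterHierarchy,
    ModeClustering,
    assign_frames,
    bootstrap_hierarchy,
    build_grid,
    cluster_stats,
    cut_macroclusters,
    effective_dimension,
    kde_on_grid,
    pairwise_dissimilarity,
    quick_shift,
    sample_torus_mixture,
    wrap_angles,
)
from anglescape.modecluster import cluster_covariance
from anglescape.synth import MixtureComponent, MixtureSpec

from conftest import majority_agreement


def two_component_spec(M=6, sep=2.5, seed_base=100):
    lam = np.array([0.04, 0.02, 0.01] + [1e-6] * (M - 3))
    return MixtureSpec(M=M, components=[
        MixtureComponent(np.zeros(M), lam, seed_base, 0.5),
        MixtureComponent(np.full(M, sep / np.sqrt(M)), lam, seed_base + 1, 0.5),
    ])


class TestBuildGrid:
    def test_full_grid_is_all_frames(self, rng):
        x = rng.uniform(-np.pi, np.pi, (20, 3))
        D = pairwise_dissimilarity(x)
        grid = build_grid(D, 20, seed=0)
        assert sorted(grid.tolist()) == list(range(20))

    def test_deterministic_given_seed(self, rng):
        x = rng.uniform(-np.pi, np.pi, (30, 3))
        D = pairwise_dissimilarity(x)
        assert np.array_equal(build_grid(D, 10, seed=5), build_grid(D, 10, seed=5))

    def test_two_blobs_get_one_point_each(self):
        x = wrap_angles(np.vstack([np.zeros((5, 2)) + 0.01 * np.arange(5)[:, None],
                                   np.full((5, 2), 2.5) + 0.01 * np.arange(5)[:, None]]))
        D = pairwise_dissimilarity(x)
        grid = build_grid(D, 2, seed=1)
        assert (grid < 5).sum() == 1 and (grid >= 5).sum() == 1

    def test_oversized_grid_rejected(self, rng):
        D = pairwise_dissimilarity(rng.uniform(-1, 1, (5, 2)))
        with pytest.raises(ValueError):
            build_grid(D, 6)


class TestKDE:
    def test_hand_evaluated_wrapped_gaussian(self):
        # M=1, frames at 0 and pi, h=1: both grid points see one frame at
        # distance 0 and one at distance pi; sum images k in {-1, 0, 1}
        x = np.array([[0.0], [-np.pi]])
        dens = kde_on_grid(x, np.array([0, 1]), bandwidth=1.0)

        def phi(d):
            return np.exp(-d ** 2 / 2) / np.sqrt(2 * np.pi)

        k_self = phi(0) + 2 * phi(2 * np.pi)
        k_far = phi(np.pi) + phi(np.pi - 2 * np.pi) + phi(np.pi + 2 * np.pi)
        expected = (k_self + k_far) / 2
        assert np.allclose(dens, expected, atol=1e-12)
        assert dens[0] == pytest.approx(dens[1])

    def test_peak_at_repeated_frame(self):
        x = wrap_angles(np.vstack([np.zeros((8, 2)), [[1.5, 1.5]]]))
        dens = kde_on_grid(x, np.array([0, 8]), bandwidth=0.3)
        assert dens[0] > dens[1]

    def test_translation_invariance(self, rng):
        x = rng.uniform(-np.pi, np.pi, (30, 4))
        grid = np.arange(10)
        d1 = kde_on_grid(x, grid, 0.5)
        d2 = kde_on_grid(wrap_angles(x + 2.0), grid, 0.5)
        assert np.allclose(d1, d2, rtol=1e-9)

    def test_positive_everywhere(self, rng):
        x = rng.uniform(-np.pi, np.pi, (40, 3))
        assert np.all(kde_on_grid(x, np.arange(40), 0.2) > 0)

    def test_invalid_bandwidth(self, rng):
        with pytest.raises(ValueError):
            kde_on_grid(rng.uniform(-1, 1, (5, 2)), np.arange(5), 0.0)


class TestQuickShift:
    def test_hand_linking(self):
        # 1-D grid at {0, 1, 2} with densities {1, 3, 2}: 0 and 2 both link
        # to the middle point, giving a single mode
        D = np.abs(np.arange(3.0)[:, None] - np.arange(3.0)[None, :])
        parent, modes = quick_shift(np.arange(3), [1.0, 3.0, 2.0], D, np.inf)
        assert parent.tolist() == [1, 1, 1]
        assert len(set(modes.tolist())) == 1

    def test_tiny_cutoff_isolates_every_point(self, rng):
        x = rng.uniform(-np.pi, np.pi, (10, 2))
        D = pairwise_dissimilarity(x).values
        dens = kde_on_grid(x, np.arange(10), 0.5)
        _, modes = quick_shift(np.arange(10), dens, D, 1e-9)
        assert len(set(modes.tolist())) == 10

    def test_two_bumps_two_modes(self, rng):
        h = 0.2
        a = wrap_angles(rng.normal(0.0, h, (50, 2)))
        b = wrap_angles(rng.normal(2.0, h, (50, 2)))  # 10h apart
        x = np.vstack([a, b])
        D = pairwise_dissimilarity(x).values
        grid = np.arange(100)
        dens = kde_on_grid(x, grid, h)
        _, modes = quick_shift(grid, dens, D, 3 * h)
        assert len(set(modes.tolist())) == 2

    def test_parent_graph_is_a_forest(self, rng):
        x = rng.uniform(-np.pi, np.pi, (40, 3))
        D = pairwise_dissimilarity(x).values
        dens = kde_on_grid(x, np.arange(40), 0.6)
        parent, modes = quick_shift(np.arange(40), dens, D, 1.5)
        roots = np.flatnonzero(parent == np.arange(40))
        assert len(roots) == len(set(modes.tolist()))
        for i in range(40):  # following parents terminates at a root
            j, steps = i, 0
            while parent[j] != j:
                j = parent[j]
                steps += 1
                assert steps <= 40
            assert j in roots


class TestAssignFrames:
    def test_grid_frames_keep_their_own_mode(self, rng):
        x = rng.uniform(-np.pi, np.pi, (30, 3))
        D = pairwise_dissimilarity(x)
        grid = build_grid(D, 10, seed=0)
        dens = kde_on_grid(x, grid, 0.5)
        _, modes = quick_shift(grid, dens, D.values, 2.0)
        labels = assign_frames(x, grid, modes, D.values)
        for gi, g in enumerate(grid):
            assert labels[g] == modes[gi]

    def test_every_frame_gets_a_label(self, rng):
        x = rng.uniform(-np.pi, np.pi, (25, 2))
        D = pairwise_dissimilarity(x)
        grid = build_grid(D, 5, seed=0)
        dens = kde_on_grid(x, grid, 0.5)
        _, modes = quick_shift(grid, dens, D.values, 2.0)
        labels = assign_frames(x, grid, modes, D.values)
        assert labels.shape == (25,)
        assert np.all(labels >= 0)


class TestEffectiveDimension:
    @pytest.mark.parametrize("spectrum,expected", [
        ((1, 1, 1, 1), 4.0),
        ((1, 0, 0), 1.0),
        ((5, 5), 2.0),
    ])
    def test_exact_values(self, spectrum, expected):
        assert effective_dimension(spectrum) == pytest.approx(expected, abs=1e-12)

    def test_against_arbitrary_precision_evaluation(self):
        import sympy

        etas = [sympy.Rational(7, 10), sympy.Rational(2, 10), sympy.Rational(1, 10)]
        expected = float(sympy.N(sympy.exp(-sum(e * sympy.log(e) for e in etas)), 30))
        assert effective_dimension((0.7, 0.2, 0.1)) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(2.229592, abs=1e-6)

    def test_bounds(self, rng):
        for _ in range(20):
            lam = rng.uniform(0, 1, size=rng.integers(2, 10))
            lam[rng.random(lam.size) < 0.3] = 0.0
            if lam.sum() == 0:
                continue
            d = effective_dimension(lam)
            nnz = (lam > 0).sum()
            assert 1.0 - 1e-9 <= d <= nnz + 1e-9

    def test_flat_spectrum_saturates_rank(self):
        assert effective_dimension([0.3] * 7 + [0.0] * 3) == pytest.approx(7.0)


class TestClusterStats:
    def test_circular_covariance_recovery(self):
        # one concentrated component near the wrap point: minimal-image
        # residuals about the circular mean recover the planted covariance
        M = 4
        lam = np.array([0.02, 0.01, 0.005, 0.002])
        comp = MixtureComponent(np.full(M, np.pi - 0.05), lam, 7, 1.0)
        spec = MixtureSpec(M=M, components=[comp])
        traj, _ = sample_torus_mixture(spec, 10_000, seed=3)
        C, wide = cluster_covariance(traj.angles)
        assert not wide
        rel = np.linalg.norm(C - comp.covariance()) / np.linalg.norm(comp.covariance())
        assert rel <= 0.05

    def test_eff_dimension_converges_to_planted_value(self):
        M = 6
        lam = np.array([0.03, 0.02, 0.012, 0.008, 0.004, 0.002])
        comp = MixtureComponent(np.zeros(M), lam, 9, 1.0)
        traj, _ = sample_torus_mixture(MixtureSpec(M=M, components=[comp]),
                                       10_000, seed=4)
        stats = cluster_stats(traj, np.zeros(traj.n_frames, dtype=int))
        planted = effective_dimension(lam)
        assert abs(stats.eff_dimension[0] - planted) / planted <= 0.05

    def test_largest_cluster_scaled_determinant_is_one(self, rng):
        x = rng.uniform(-np.pi, np.pi, (200, 3))
        labels = (np.arange(200) >= 120).astype(int)
        stats = cluster_stats(x, labels)
        assert np.max(stats.scaled_determinant) == 1.0
        assert (stats.scaled_determinant == 1.0).sum() == 1

    def test_tiny_cluster_is_flagged_with_missing_stats(self, rng):
        x = rng.uniform(-np.pi, np.pi, (20, 3))
        labels = np.zeros(20, dtype=int)
        labels[0] = 1  # singleton cluster
        stats = cluster_stats(x, labels)
        i = list(stats.labels).index(1)
        assert stats.flagged[i]
        assert np.isnan(stats.eff_dimension[i])


class TestRecovery:
    def test_planted_components_recovered(self):
        from anglescape import reference_scenario

        spec = reference_scenario("well_separated", seed=0)
        traj, planted = sample_torus_mixture(spec, 2000, seed=1)
        est = ModeClustering(grid_size=300, random_state=0).fit(traj.angles)
        assert est.n_modes_ == 5
        assert majority_agreement(est.labels_, planted) >= 0.95


class TestBootstrapHierarchy:
    def test_split_labels_merge_and_distant_components_do_not(self):
        spec = two_component_spec()
        traj, planted = sample_torus_mixture(spec, 400, seed=5)
        ref = np.where(planted == 0, 0, 2)
        idx0 = np.flatnonzero(planted == 0)
        ref[idx0[::2]] = 1  # artificial split of component 0
        h = bootstrap_hierarchy(traj, ref, n_boot=8, seed=3, grid_size=60)
        assert h.merge_distance[0, 1] <= 0.2
        assert h.merge_distance[0, 2] >= 0.8
        assert h.merge_distance[1, 2] >= 0.8

    def test_fixed_seed_reproduces_hierarchy(self):
        spec = two_component_spec()
        traj, planted = sample_torus_mixture(spec, 200, seed=6)
        a = bootstrap_hierarchy(traj, planted, n_boot=4, seed=9, grid_size=40)
        b = bootstrap_hierarchy(traj, planted, n_boot=4, seed=9, grid_size=40)
        assert np.array_equal(a.merge_distance, b.merge_distance)
        assert np.array_equal(a.linkage, b.linkage)

    def test_invalid_replicate_count(self, rng):
        with pytest.raises(ValueError):
            bootstrap_hierarchy(rng.uniform(-1, 1, (10, 2)),
                                np.zeros(10, dtype=int), n_boot=0)

    def test_newick_export_names_all_clusters(self):
        import scipy.cluster.hierarchy as sch

        dist = np.array([[0, 0.1, 1.0], [0.1, 0, 1.0], [1.0, 1.0, 0]])
        link = sch.linkage(dist[np.triu_indices(3, 1)], method="average")
        h = ClusterHierarchy(dist, link)
        nwk = h.to_newick()
        assert nwk.endswith(";")
        for c in ("c0", "c1", "c2"):
            assert c in nwk


class TestCutMacroclusters:
    def _hierarchy(self):
        import scipy.cluster.hierarchy as sch

        # two sub-modes of one funnel (distance 0.1) plus a distant mode
        dist = np.array([[0, 0.1, 1.0], [0.1, 0, 1.0], [1.0, 1.0, 0]])
        link = sch.linkage(dist[np.triu_indices(3, 1)], method="average")
        return ClusterHierarchy(dist, link)

    def test_zero_threshold_keeps_everything_separate(self):
        labels = cut_macroclusters(self._hierarchy(), 0.0)
        assert len(set(labels.tolist())) == 3

    def test_unit_threshold_merges_everything(self):
        labels = cut_macroclusters(self._hierarchy(), 1.0)
        assert len(set(labels.tolist())) == 1

    def test_intermediate_threshold_finds_two_macroclusters(self):
        labels = cut_macroclusters(self._hierarchy(), 0.5)
        assert labels[0] == labels[1] != labels[2]
        assert sorted(set(labels.tolist())) == [0, 1]

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            cut_macroclusters(self._hierarchy(), 1.5)
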