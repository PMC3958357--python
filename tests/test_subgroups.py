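"""Tests of similarity construction, data-driven thresholding and subgrouping."""

import numpy as np
import pytest

from gimmesub.subgroups import (binarize, build_similarity,
                                detect_subgroups_from_betas,
                                find_reachability_drop, matched_accuracy,
                                reachability, scan_thresholds,
                                select_threshold, vectorize_betas)


def block_betas(rng, n_per=12, sep=0.2, noise=0.03):
    """Two clearly separated beta blocks around distinct 9-path profiles."""
    base = np.full(9, 0.5)
    d1 = base.copy()
    d1[:3] += [sep, -sep, sep]
    d2 = base.copy()
    d2[4:7] += [-sep, sep, -sep]
    rows = [d1 + rng.normal(0, noise, 9) for _ in range(n_per)]
    rows += [d2 + rng.normal(0, noise, 9) for _ in range(n_per)]
    return np.array(rows), np.repeat([0, 1], n_per)


class TestVectorizeAndSimilarity:
    def test_beta_matrix_shape_and_order(self, small_run):
        _design, _panel, _truth, maps = small_run
        B = vectorize_betas(maps)
        k = int(maps.group.group_A.sum())
        assert B.shape == (maps.n_individuals, k)
        paths = maps.group.contemporaneous_paths()
        assert paths == sorted(paths)  # canonical row-major order

    def test_lagged_only_group_map_rejected(self):
        from gimmesub.gimme import ConnectivityMapSet, GroupMap
        gmap = GroupMap(group_A=np.zeros((4, 4), bool),
                        group_Phi=np.eye(4, dtype=bool))
        maps = ConnectivityMapSet(group=gmap, individuals=[])
        with pytest.raises(ValueError, match="contemporaneous"):
            vectorize_betas(maps)

    def test_identical_rows_correlate_perfectly(self):
        B = np.vstack([[0.1, 0.5, 0.9], [0.1, 0.5, 0.9]])
        net = build_similarity(B)
        assert net.X[0, 1] == pytest.approx(1.0)

    def test_negative_linear_rows_anticorrelate(self):
        row = np.array([0.1, 0.5, 0.9])
        net = build_similarity(np.vstack([row, 1.0 - row]))
        assert net.X[0, 1] == pytest.approx(-1.0)

    def test_orthogonalized_pair_uncorrelated(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])  # centered, orthogonal
        net = build_similarity(np.vstack([a, b]))
        assert net.X[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_row_flagged(self):
        B = np.vstack([[0.5, 0.5, 0.5], [0.1, 0.4, 0.8]])
        with pytest.warns(UserWarning, match="zero-variance"):
            net = build_similarity(B)
        assert net.flagged == [0]
        assert np.isnan(net.X[0, 1])

    def test_too_few_paths_rejected(self):
        with pytest.raises(ValueError):
            build_similarity(np.array([[0.5], [0.4]]))


class TestBinarizeAndReachability:
    def test_binarize_closed_boundary(self):
        X = np.array([[np.nan, 0.7, 0.6], [0.7, np.nan, 0.2],
                      [0.6, 0.2, np.nan]])
        A = binarize(X, 0.6)
        assert A[0, 1] == 1 and A[0, 2] == 1 and A[1, 2] == 0
        assert np.all(np.diag(A) == 0)

    def test_binarize_r_zero_connects_nonnegative(self):
        X = np.array([[np.nan, 0.0, -0.3], [0.0, np.nan, 0.5],
                      [-0.3, 0.5, np.nan]])
        A = binarize(X, 0.0)
        assert A[0, 1] == 1 and A[1, 2] == 1 and A[0, 2] == 0

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.eye(3), 1.5)

    def test_reachability_complete_empty_and_path(self):
        full = 1 - np.eye(5)
        assert reachability(full) == pytest.approx(4.0)
        assert reachability(np.zeros((4, 4))) == 0.0
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1  # path 0-1-2, isolate 3
        assert reachability(A) == pytest.approx(1.5)

    def test_reachability_monotone_in_threshold(self, rng):
        B = rng.normal(0.5, 0.1, size=(15, 9))
        X = build_similarity(B).X
        reach = [reachability(binarize(X, r)) for r in np.arange(0, 1.01, 0.05)]
        assert all(b <= a + 1e-12 for a, b in zip(reach, reach[1:]))


class TestReachabilityDrop:
    def test_step_curve_elbow(self):
        assert find_reachability_drop(np.array([10, 10, 10, 0, 0])) == 2

    def test_two_point_cliff(self):
        assert find_reachability_drop(np.array([99, 99, 0])) == 1

    def test_linear_curve_has_no_drop(self):
        with pytest.warns(UserWarning, match="no drop"):
            idx = find_reachability_drop(np.linspace(10, 0, 11))
        assert idx == 10

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            find_reachability_drop(np.array([1.0, 0.0]))


class TestScanAndSelect:
    def test_perfect_similarity_is_stable_everywhere(self, rng):
        X = np.ones((10, 10))
        np.fill_diagonal(X, np.nan)
        scan = scan_thresholds(X, runs=10, rng=rng)
        assert np.all(scan.q_std == 0.0)

    def test_block_structure_stable_and_exact(self, rng):
        B, labels = block_betas(rng)
        part, scan, net = detect_subgroups_from_betas(B, runs=30, rng=rng)
        assert part.n_communities == 2
        assert matched_accuracy(labels, part.labels) == 1.0
        gi = int(np.where(np.isclose(scan.grid, scan.selected_r))[0][0])
        assert scan.q_std[gi] == 0.0
        # stability of Q implies stability of the community structure
        canon = {p.canonical() for p in scan.partitions[gi]}
        assert len(canon) == 1

    def test_homogeneous_sample_forms_single_community(self, rng):
        # one shared beta profile (a varied pattern, as estimated maps have)
        profile = np.array([0.7, 0.3, 0.7, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5])
        B = profile + rng.normal(0, 0.03, size=(16, 9))
        part, scan, _net = detect_subgroups_from_betas(B, runs=30, rng=rng)
        sizes = np.bincount(part.canonical())
        assert sizes.max() >= 15  # essentially one community at r*

    def test_selection_prefers_highest_stable_r(self, rng):
        from gimmesub.subgroups import STABILITY_TOL
        B, _labels = block_betas(rng)
        net = build_similarity(B)
        scan = scan_thresholds(net.X, runs=20, rng=rng)
        r = select_threshold(scan)
        snapped = np.where(scan.q_std < STABILITY_TOL, 0.0, scan.q_std)
        stable = [scan.grid[i] for i in range(scan.drop_index)
                  if snapped[i] == snapped.min() and not scan.edgeless[i]]
        assert r == pytest.approx(max(stable))

    def test_float_noise_does_not_break_stability_ties(self):
        """std(Q) of ~1e-16 (identical partitions, different summation
        order) must not lose to an exactly-zero coarser threshold."""
        from gimmesub.subgroups import ThresholdScan
        scan = ThresholdScan(
            grid=np.array([0.1, 0.2, 0.3, 0.4, 0.5]),
            Q=np.zeros((5, 10)),
            q_std=np.array([0.0, 0.0, 5e-3, 1.1e-16, 3e-16]),
            reach=np.array([20.0, 20.0, 20.0, 20.0, 2.0]),
            edgeless=np.zeros(5, bool))
        scan.drop_index = 4
        assert select_threshold(scan) == pytest.approx(0.4)

    def test_no_eligible_threshold_errors(self):
        from gimmesub.subgroups import ThresholdScan
        scan = ThresholdScan(
            grid=np.array([0.0, 0.01, 0.02]), Q=np.zeros((3, 5)),
            q_std=np.zeros(3), reach=np.array([5.0, 5.0, 0.0]),
            edgeless=np.array([True, True, False]))
        scan.drop_index = 1
        with pytest.raises(ValueError, match="no eligible"):
            select_threshold(scan)

    def test_scan_grid_must_increase(self, rng):
        X = np.ones((4, 4))
        with pytest.raises(ValueError, match="increasing"):
            scan_thresholds(X, runs=2, rng=rng, grid=np.array([0.2, 0.1]))


class TestMatchedAccuracy:
    def test_relabeled_partition_scores_perfect(self):
        t = np.array([0, 0, 1, 1, 2, 2])
        assert matched_accuracy(t, np.array([2, 2, 0, 0, 1, 1])) == 1.0

    def test_one_moved_individual(self):
        t = np.repeat([0, 1], 10)
        p = t.copy()
        p[0] = 1
        assert matched_accuracy(t, p) == pytest.approx(1 - 1 / 20)

    def test_unmatched_extra_community_counts_wrong(self):
        t = np.array([0, 0, 0, 0])
        p = np.array([0, 0, 1, 2])
        assert matched_accuracy(t, p) == pytest.approx(0.5)
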