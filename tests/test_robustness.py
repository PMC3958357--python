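"""Tests of degree-preserving perturbation and variation of information."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gimmesub.modularity import Partition, modularity_partition, modularity_q
from gimmesub.robustness import (fraction_changed, perturb_network,
                                 random_baseline, robustness_curve,
                                 variation_of_information)

labels8 = st.lists(st.integers(0, 2), min_size=8, max_size=8).map(np.array)


def random_graph(seed, n=20, p=0.3):
    g = np.random.default_rng(seed)
    A = np.triu((g.random((n, n)) < p), 1).astype(np.int8)
    return A + A.T


class TestVariationOfInformation:
    def test_identical_partitions_zero(self):
        lab = np.array([0, 0, 1, 1, 2])
        assert variation_of_information(lab, lab) == 0.0

    def test_crossed_pairs_two_bits(self):
        """{12|34} vs {13|24}: H = 1 bit each, I = 0, so VI = 2 bits."""
        vi = variation_of_information(np.array([0, 0, 1, 1]),
                                      np.array([0, 1, 0, 1]))
        assert vi == pytest.approx(2.0)

    def test_split_from_whole_one_bit(self):
        vi = variation_of_information(np.zeros(4, int), np.array([0, 0, 1, 1]))
        assert vi == pytest.approx(1.0)

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError):
            variation_of_information(np.zeros(4, int), np.zeros(5, int))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(labels8, labels8, labels8)
    def test_metric_axioms(self, a, b, c):
        vab = variation_of_information(a, b)
        # symmetry
        assert vab == pytest.approx(variation_of_information(b, a))
        # identity of indiscernibles (equal as partitions)
        same = (Partition(a, 0.0).canonical() == Partition(b, 0.0).canonical())
        assert (vab < 1e-12) == same
        # triangle inequality
        assert vab <= (variation_of_information(a, c)
                       + variation_of_information(c, b) + 1e-9)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(labels8, labels8)
    def test_bounded_by_log2_n(self, a, b):
        assert variation_of_information(a, b) <= np.log2(a.size) + 1e-12


class TestFractionChanged:
    def test_identical_zero(self):
        lab = np.array([0, 0, 1, 1])
        assert fraction_changed(lab, lab) == 0.0

    def test_pure_relabeling_zero(self):
        assert fraction_changed(np.array([0, 0, 1, 1]),
                                np.array([7, 7, 3, 3])) == 0.0

    def test_one_moved_individual(self):
        t = np.repeat([0, 1], 10)
        p = t.copy()
        p[3] = 1
        assert fraction_changed(t, p) == pytest.approx(1 / 20)


class TestPerturbation:
    def test_level_zero_identity(self, rng):
        A = random_graph(0)
        assert np.array_equal(perturb_network(A, 0.0, rng), A)

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0])
    def test_degree_sequence_preserved(self, alpha, rng):
        for seed in range(3):
            A = random_graph(seed)
            Ap = perturb_network(A, alpha, rng)
            assert np.array_equal(Ap.sum(0), A.sum(0))
            assert np.array_equal(Ap, Ap.T)
            assert not np.any(np.diag(Ap))
            assert set(np.unique(Ap)) <= {0, 1}

    def test_sparse_graph_returned_unchanged(self, rng):
        A = np.zeros((4, 4), np.int8)
        A[0, 1] = A[1, 0] = 1
        with pytest.warns(UserWarning, match="too sparse"):
            Ap = perturb_network(A, 1.0, rng)
        assert np.array_equal(Ap, A)

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            perturb_network(random_graph(0), 1.5, rng)
        with pytest.raises(ValueError):
            perturb_network(np.triu(np.ones((4, 4))), 0.5, rng)

    def test_full_perturbation_near_configuration_model(self, rng):
        """At level 1 the edge overlap with the original matches a
        well-mixed degree-preserving randomization (reference: many more
        swaps), not the original structure."""
        A = random_graph(1, n=24, p=0.25)
        m = A.sum() / 2

        def overlap(B):
            return (A * B).sum() / 2 / m

        ours = np.mean([overlap(perturb_network(A, 1.0, rng))
                        for _ in range(30)])
        import networkx as nx
        ref = []
        for _ in range(30):
            G = nx.from_numpy_array(A)
            nx.double_edge_swap(G, nswap=int(10 * m), max_tries=10**5, seed=rng)
            ref.append(overlap(nx.to_numpy_array(G)))
        assert ours == pytest.approx(np.mean(ref), abs=0.1)
        assert ours < 0.75  # far from the original graph


class TestRobustnessCurve:
    def test_level_zero_vi_identically_zero(self, rng):
        A = random_graph(2)
        part = modularity_partition(A, rng)
        curve = robustness_curve(A, part, rng=rng, levels=np.array([0.0]),
                                 reps=5, detection_runs=5)
        assert np.all(curve.vi[0] == 0.0)
        assert np.all(curve.frac_changed[0] == 0.0)

    def test_structured_network_flat_then_rising(self, rng):
        """Two dense blocks: VI stays near zero at light perturbation and
        rises by full randomization."""
        A = np.zeros((20, 20), np.int8)
        A[:10, :10] = 1
        A[10:, 10:] = 1
        np.fill_diagonal(A, 0)
        part = modularity_partition(A, rng)
        curve = robustness_curve(A, part, rng=rng,
                                 levels=np.array([0.05, 1.0]), reps=10,
                                 detection_runs=10)
        assert curve.vi_mean[0] < 0.1
        assert curve.vi_mean[1] > curve.vi_mean[0]

    def test_random_baseline_shape_and_fragility(self, rng):
        A = np.zeros((20, 20), np.int8)
        A[:10, :10] = 1
        A[10:, 10:] = 1
        np.fill_diagonal(A, 0)
        B = random_baseline(A, rng)
        assert B.sum() == A.sum()
        assert B.shape == A.shape
        part_b = modularity_partition(B, rng)
        curve_b = robustness_curve(B, part_b, rng=rng,
                                   levels=np.array([0.05]), reps=10,
                                   detection_runs=10,
                                   is_random_baseline=True)
        part_a = modularity_partition(A, rng)
        curve_a = robustness_curve(A, part_a, rng=rng,
                                   levels=np.array([0.05]), reps=10,
                                   detection_runs=10)
        assert curve_b.vi_mean[0] > curve_a.vi_mean[0]
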