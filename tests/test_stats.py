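"""Group statistics against independent oracles and their invariants.

Oracles: full-enumeration relabeling for the MRPP expectation, hand-computed
rank/variance arithmetic for ANOSIM and the pseudo-F, and scikit-bio's
anosim/permanova as an independent implementation on random instances.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from delsieve.reads import Allele, ReadGroupAssignment, Strand
from delsieve.signals import NotEvaluatedError
from delsieve.stats import (
    accumulative_difference,
    adonis_f,
    anosim_r,
    group_compare,
    mrpp_a,
    mrpp_permutation_mean,
    qscore_index,
)
from delsieve.variants import FlankWindow


def rand_instance(rng, max_rows=9, dim=3):
    n = int(rng.integers(4, max_rows + 1))
    n1 = int(rng.integers(2, n - 1))
    values = rng.normal(size=(n, dim))
    labels = np.zeros(n, dtype=bool)
    labels[:n1] = True
    rng.shuffle(labels)
    return values, labels


class TestMrpp:
    def test_fully_separated_pairs_give_a_of_one(self):
        # {0,0} vs {1,1}: delta_obs=0, delta_exp=4/6 -> A = 1
        values = np.array([[0.0], [0.0], [1.0], [1.0]])
        assert mrpp_a(values, [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_identical_rows_return_zero_by_convention(self):
        values = np.ones((6, 4))
        assert mrpp_a(values, [1, 1, 1, 0, 0, 0]) == 0.0

    def test_analytic_equals_full_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            values, labels = rand_instance(rng)
            a = mrpp_a(values, labels, mode="analytic")
            b = mrpp_a(values, labels, mode="enumerate")
            assert abs(a - b) < 1e-12

    def test_permutation_mode_approaches_analytic(self):
        rng = np.random.default_rng(8)
        values, labels = rand_instance(rng, max_rows=12)
        a = mrpp_a(values, labels, mode="analytic")
        b = mrpp_a(values, labels, mode="permutation", n_perm=4000, seed=0)
        assert abs(a - b) < 0.05

    def test_permutation_mean_near_zero_for_exchangeable_rows(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(20, 5))
        labels = np.array([True] * 10 + [False] * 10)
        m = mrpp_permutation_mean(values, labels, n_perm=2000, seed=1)
        assert abs(m) < 0.02

    def test_too_small_group_is_not_evaluated(self):
        with pytest.raises(NotEvaluatedError):
            mrpp_a(np.zeros((4, 2)), [1, 0, 0, 0])


class TestAnosim:
    def test_perfect_separation_reaches_one(self):
        values = np.array([[0.0], [0.1], [3.0], [4.0]])
        assert anosim_r(values, [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_all_equal_distances_give_zero(self):
        # regular tetrahedron: all pairwise distances identical
        values = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        assert anosim_r(values, [1, 1, 0, 0]) == pytest.approx(0.0)

    def test_hand_ranked_interleaved_instance(self):
        # {0,3 | 1,4}: within ranks {4.5, 4.5}, between {1.5, 6, 3, 1.5}
        # R = (3.0 - 4.5) / 3 = -0.5
        values = np.array([[0.0], [3.0], [1.0], [4.0]])
        assert anosim_r(values, [1, 1, 0, 0]) == pytest.approx(-0.5)

    def test_matches_scikit_bio_on_random_instances(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import anosim as skbio_anosim
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(10)
        for _ in range(10):
            values, labels = rand_instance(rng, max_rows=12)
            dm = DistanceMatrix(squareform(pdist(values)))
            expected = skbio_anosim(dm, labels.astype(str), permutations=0)
            assert anosim_r(values, labels) == pytest.approx(
                expected["test statistic"], abs=1e-12
            )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounded_in_minus_one_one(self, seed):
        values, labels = rand_instance(np.random.default_rng(seed))
        r = anosim_r(values, labels)
        assert -1.0 <= r <= 1.0


class TestAdonisF:
    def test_hand_computed_one_dimensional_instance(self):
        # {0,1 | 3,4}: SS_total=10, SS_within=1 -> F = 9/(1/2) / ... = 18
        values = np.array([[0.0], [1.0], [3.0], [4.0]])
        assert adonis_f(values, [1, 1, 0, 0]) == pytest.approx(18.0)

    def test_identical_groups_give_zero(self):
        values = np.array([[0.0], [1.0], [0.0], [1.0]])
        assert adonis_f(values, [1, 1, 0, 0]) == pytest.approx(0.0)

    def test_separated_points_with_no_within_spread_give_inf(self):
        values = np.array([[0.0], [0.0], [5.0], [5.0]])
        assert adonis_f(values, [1, 1, 0, 0]) == np.inf

    def test_all_identical_rows_give_zero(self):
        assert adonis_f(np.ones((4, 2)), [1, 1, 0, 0]) == 0.0

    def test_matches_scikit_bio_permanova(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(11)
        for _ in range(10):
            values, labels = rand_instance(rng, max_rows=12)
            dm = DistanceMatrix(squareform(pdist(values)))
            expected = permanova(dm, labels.astype(str), permutations=0)
            assert adonis_f(values, labels) == pytest.approx(
                expected["test statistic"], abs=1e-10
            )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_non_negative(self, seed):
        values, labels = rand_instance(np.random.default_rng(seed))
        assert adonis_f(values, labels) >= 0.0


class TestAccumulativeDifference:
    def test_identical_profiles_give_zero(self):
        values = np.vstack([np.arange(5.0)] * 4)
        assert accumulative_difference(values, [1, 1, 0, 0]) == 0.0

    def test_direct_arithmetic(self):
        values = np.array([[1.0, 2.0, 3.0], [2.0, 2.0, 5.0]])
        assert accumulative_difference(values, [1, 0]) == pytest.approx(3.0)


class TestSymmetryAndMonotonicity:
    def test_label_swap_leaves_all_four_unchanged(self):
        rng = np.random.default_rng(12)
        values, labels = rand_instance(rng, max_rows=10)
        for fn in (mrpp_a, anosim_r, adonis_f, accumulative_difference):
            assert fn(values, labels) == pytest.approx(fn(values, ~labels))

    def test_all_indexes_non_decreasing_in_group_shift(self):
        rng = np.random.default_rng(13)
        deltas = [0.0, 0.5, 1.0, 2.0, 4.0]
        medians = {fn.__name__: [] for fn in
                   (mrpp_a, anosim_r, adonis_f, accumulative_difference)}
        for delta in deltas:
            per_rep = {k: [] for k in medians}
            for rep in range(7):
                rng_rep = np.random.default_rng(1000 + rep)
                base = rng_rep.normal(size=(30, 8))
                values = base.copy()
                values[:15] += delta
                labels = np.array([True] * 15 + [False] * 15)
                for fn in (mrpp_a, anosim_r, adonis_f, accumulative_difference):
                    per_rep[fn.__name__].append(fn(values, labels))
            for k, vals in per_rep.items():
                medians[k].append(float(np.median(vals)))
        for k, curve in medians.items():
            assert np.all(np.diff(curve) >= -1e-9), (k, curve)


class TestQScoreIndex:
    WINDOW = FlankWindow(contig="c", left=(5, 6, 7, 8, 9),
                         right=(11, 12, 13, 14, 15), k=5)

    def _read(self, rid, quals, allele=Allele.DEL):
        return ReadGroupAssignment(read_id=rid, strand=Strand.FWD, allele=allele,
                                   read_window=(), window_quals=tuple(quals))

    def test_constant_qualities(self):
        reads = [self._read("a", [20.0] * 10), self._read("b", [20.0] * 10)]
        idx = qscore_index(reads, self.WINDOW)
        assert idx.mean_q == 20.0
        assert idx.n_reads == 2
        assert idx.window_len == 10

    def test_upstream_downstream_average(self):
        reads = [self._read("a", [10.0] * 5 + [30.0] * 5)]
        assert qscore_index(reads, self.WINDOW).mean_q == pytest.approx(20.0)

    def test_missing_bases_are_skipped_per_read(self):
        quals = [20.0] * 5 + [float("nan")] * 3 + [26.0] * 2
        reads = [self._read("a", quals)]
        assert qscore_index(reads, self.WINDOW).mean_q == pytest.approx(
            (20.0 * 5 + 26.0 * 2) / 7
        )

    def test_only_the_requested_group_contributes(self):
        reads = [
            self._read("a", [10.0] * 10, allele=Allele.DEL),
            self._read("b", [40.0] * 10, allele=Allele.NODEL),
        ]
        assert qscore_index(reads, self.WINDOW).mean_q == 10.0

    def test_no_usable_reads_is_not_evaluated(self):
        reads = [self._read("a", [float("nan")] * 10)]
        with pytest.raises(NotEvaluatedError):
            qscore_index(reads, self.WINDOW)


def test_group_compare_bundles_all_indexes():
    rng = np.random.default_rng(14)
    from delsieve.signals import NormalizedSignalMatrix

    values = rng.normal(size=(8, 6))
    labels = [Allele.DEL] * 4 + [Allele.NODEL] * 4
    m = NormalizedSignalMatrix(values=values, labels=labels,
                               read_ids=[f"r{i}" for i in range(8)],
                               bins=6, window_bases=3)
    res = group_compare(m)
    assert res.n_del == 4 and res.n_nodel == 4
    assert -1.0 <= res.anosim_r <= 1.0
    assert res.accum_diff >= 0.0
    assert res.mrpp_a == pytest.approx(mrpp_a(values, [1, 1, 1, 1, 0, 0, 0, 0]))
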