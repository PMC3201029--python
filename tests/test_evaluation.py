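import numpy as np
import pytest
from scipy import stats

from famalign.core_io import DataError, GapPenalties, PairwiseAlignment, ReferenceGroup
from famalign.aligner import global_align
from famalign.evaluation import (
    ScoringSpec,
    compare_matrices_on_groups,
    grid_search_penalties,
    make_cv_plan,
    overlap_analysis,
    paired_t_test,
    quality,
    run_cross_validation,
)
from famalign.synthetic import sample_reference_group

from _oracles import (
    affine_alignment_score,
    enumerate_global_alignments,
    two_sided_t_pvalue,
)

REDUCED_ALPHA = range(1, 21)
REDUCED_BETA = range(1, 9)


class TestQuality:
    def test_identical_alignments_score_100(self):
        ref = PairwiseAlignment("a", "b", "AC-EW", "ACDEW")
        q = quality(ref, ref)
        assert q.f_d == q.f_m == q.q == 100.0

    def test_forced_construction_45_percent(self):
        # n_I = 4, l_R = 10, l_T = 8 -> f_D = 40, f_M = 50, Q = 45
        seq = "ARNDCQEGHI"
        ref = PairwiseAlignment("a", "b", seq, seq)  # 10 aligned residue pairs
        test = PairwiseAlignment("a", "b", "ARNDCQEGHI--", "ARND--CQEGHI")
        assert len(ref.aligned_pairs()) == 10 and len(test.aligned_pairs()) == 8
        assert ref.seq_a == test.seq_a and ref.seq_b == test.seq_b
        n_i = len(ref.aligned_pairs() & test.aligned_pairs())
        assert n_i == 4
        q = quality(test, ref)
        assert q.f_d == pytest.approx(40.0)
        assert q.f_m == pytest.approx(50.0)
        assert q.q == pytest.approx(45.0)

    def test_disjoint_alignments_score_0(self):
        ref = PairwiseAlignment("a", "b", "AC-", "ACD")
        test = PairwiseAlignment("a", "b", "-AC", "ACD")
        assert not (ref.aligned_pairs() & test.aligned_pairs())
        assert quality(test, ref).q == 0.0

    def test_mismatched_sequences_rejected(self):
        ref = PairwiseAlignment("a", "b", "ACE", "ACE")
        test = PairwiseAlignment("a", "b", "WWW", "WWW")
        with pytest.raises(DataError):
            quality(test, ref)

    def test_bounds_on_random_fixtures(self, benchmark3, vtml200):
        groups, _, _ = benchmark3
        for ref in groups[0].alignments[:5]:
            test, _ = global_align(ref.seq_a, ref.seq_b, vtml200, GapPenalties(15, 1))
            q = quality(test, ref)
            assert 0 <= q.f_d <= 100 and 0 <= q.f_m <= 100
            n_rr_ref = len(ref.aligned_pairs())
            n_rr_test = len(test.aligned_pairs())
            n_i = len(ref.aligned_pairs() & test.aligned_pairs())
            assert n_i <= min(n_rr_ref, n_rr_test)


class TestGridSearch:
    def test_empty_training_set_rejected(self, vtml200):
        with pytest.raises(DataError):
            grid_search_penalties([], vtml200)

    def test_tie_break_lexicographic(self, vtml200):
        # gap-free identical-sequence references: every combo scores Q=100,
        # so the declared tie-break gives the smallest (alpha, beta)
        refs = [PairwiseAlignment("a", "b", "ARNDCQEGHI", "ARNDCQEGHI")]
        g = grid_search_penalties(refs, vtml200, REDUCED_ALPHA, REDUCED_BETA)
        assert (g.alpha, g.beta) == (1, 1)

    def test_enumeration_order_invariance(self, vtml200):
        refs = [PairwiseAlignment("a", "b", "ACWWE", "ACDDE")]
        g1 = grid_search_penalties(refs, vtml200, range(1, 16), range(1, 7))
        g2 = grid_search_penalties(refs, vtml200, reversed(range(1, 16)), reversed(range(1, 7)))
        assert g1 == g2

    def test_planted_reference_recovered(self, vtml200):
        # Oracle: enumerate every alignment of the two sequences and find the
        # combos where the reference is the *unique* optimum.
        ref = PairwiseAlignment("a", "b", "ACWWE", "ACDDE")
        alns = list(enumerate_global_alignments(ref.seq_a, ref.seq_b))
        unique_perfect = []
        for alpha in range(1, 16):
            for beta in range(1, 7):
                scores = [
                    affine_alignment_score(c, vtml200.score, alpha, beta) for c in alns
                ]
                best = max(scores)
                winners = [k for k, s in enumerate(scores) if s == best]
                if len(winners) == 1:
                    cols = alns[winners[0]]
                    row_a = "".join(x if x else "-" for x, _ in cols)
                    row_b = "".join(y if y else "-" for _, y in cols)
                    if (row_a, row_b) == (ref.row_a, ref.row_b):
                        unique_perfect.append((alpha, beta))
        assert unique_perfect, "fixture must be recoverable somewhere on the grid"
        g = grid_search_penalties([ref], vtml200, range(1, 16), range(1, 7))
        # the returned combo reproduces the reference exactly...
        aln, _ = global_align(ref.seq_a, ref.seq_b, vtml200, g)
        assert quality(aln, ref).q == 100.0
        # ...and is never later than the first unique-optimum combo
        assert (g.alpha, g.beta) <= min(unique_perfect)
        assert (g.alpha, g.beta) == (4, 3)  # frozen regression value

    def test_long_gap_geometry_beats_default(self, benchmark3, vtml200):
        # references with long indels: the optimum must be at least as good
        # as the paper's default (15, 1) on training data
        from famalign.synthetic import FamilyModel

        groups, _, truth = benchmark3
        model = FamilyModel(
            name="gappy",
            joint_sub_probs=truth.joint_probs["fam0"],
            indel_open_prob=0.08,
            indel_extend_prob=0.75,
            seed=11,
        )
        refs = sample_reference_group(model, 6, 60).alignments

        def mean_q(pen):
            qs = []
            for ref in refs:
                aln, _ = global_align(ref.seq_a, ref.seq_b, vtml200, pen)
                qs.append(quality(aln, ref).q)
            return float(np.mean(qs))

        g = grid_search_penalties(refs, vtml200, REDUCED_ALPHA, REDUCED_BETA)
        assert mean_q(g) >= mean_q(GapPenalties(15, 1))
        assert g.beta <= g.alpha


class TestCrossValidation:
    def test_fold_partition_arithmetic(self, benchmark3):
        groups, _, _ = benchmark3
        plan = make_cv_plan(groups[0], seed=5)
        sizes = sorted(len(f) for f in plan.folds)
        assert sizes == [4, 4, 4]
        flat = sorted(i for f in plan.folds for i in f)
        assert flat == list(range(12))

    def test_plan_deterministic(self, benchmark3):
        groups, _, _ = benchmark3
        assert make_cv_plan(groups[0], seed=5) == make_cv_plan(groups[0], seed=5)
        assert make_cv_plan(groups[0], seed=5) != make_cv_plan(groups[0], seed=6)

    def test_too_small_group_rejected(self):
        g = ReferenceGroup(
            name="tiny",
            alignments=[
                PairwiseAlignment("a", "b", "ACDEFGHIKL", "ACDEFGHIKL"),
                PairwiseAlignment("c", "d", "ACDEFGHIKL", "ACDEFGHIKL"),
            ],
        )
        with pytest.raises(DataError):
            make_cv_plan(g, seed=1)

    def test_every_pair_scored_once_and_deterministic(self, benchmark3, vtml200):
        groups, _, _ = benchmark3
        spec = ScoringSpec("vtml", matrix=vtml200)
        r1 = run_cross_validation(
            groups[0], [spec], seed=3, alpha_range=REDUCED_ALPHA, beta_range=REDUCED_BETA
        )
        r2 = run_cross_validation(
            groups[0], [spec], seed=3, alpha_range=REDUCED_ALPHA, beta_range=REDUCED_BETA
        )
        assert r1 == r2
        assert len(r1["vtml"]) == 12
        assert all(0 <= q <= 100 for q in r1["vtml"])

    def test_no_test_fold_leakage(self, benchmark3, vtml200):
        groups, _, _ = benchmark3
        seen = []
        spec = ScoringSpec("fam", group_specific=True, fallback=vtml200)
        run_cross_validation(
            groups[0],
            [spec],
            seed=9,
            alpha_range=range(5, 16, 5),
            beta_range=range(1, 4),
            train_observer=lambda name, fold, train, test: seen.append((fold, train, test)),
        )
        assert len(seen) == 3
        covered = set()
        for fold, train, test in seen:
            assert not (set(train) & set(test))
            assert sorted(set(train) | set(test)) == list(range(12))
            covered |= set(test)
        assert covered == set(range(12))

    def test_family_matrix_beats_scrambled(self, benchmark3, vtml200, rng):
        # references reproducible by the true family statistics score at
        # least as well as a deliberately scrambled matrix
        from famalign.core_io import SimilarityMatrix

        groups, _, _ = benchmark3
        perm = rng.permutation(20)
        scrambled = SimilarityMatrix(
            "scrambled", vtml200.scores[np.ix_(perm, perm)]
        )
        res = run_cross_validation(
            groups[0],
            [
                ScoringSpec("fam", group_specific=True, fallback=vtml200),
                ScoringSpec("scrambled", matrix=scrambled),
            ],
            seed=13,
            alpha_range=REDUCED_ALPHA,
            beta_range=REDUCED_BETA,
        )
        assert np.mean(res["fam"]) >= np.mean(res["scrambled"])


class TestPairedTTest:
    def test_zero_differences(self):
        assert paired_t_test([50.0, 60.0, 70.0], [50.0, 60.0, 70.0]) == (0.0, 1.0)

    def test_antisymmetry(self, rng):
        a = list(rng.uniform(0, 100, 10))
        b = list(rng.uniform(0, 100, 10))
        t_ab, p_ab = paired_t_test(a, b)
        t_ba, p_ba = paired_t_test(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_known_case(self):
        # d = [1..5]: t = 3 / (1.5811.../sqrt(5)) ~ 4.2426, p ~ 0.0132 (df=4)
        b = [10.0, 20.0, 30.0, 40.0, 50.0]
        a = [11.0, 22.0, 33.0, 44.0, 55.0]
        t, p = paired_t_test(a, b)
        assert t == pytest.approx(3.0 / (np.std([1, 2, 3, 4, 5], ddof=1) / np.sqrt(5)))
        assert t == pytest.approx(4.242640687, rel=1e-8)
        assert p == pytest.approx(two_sided_t_pvalue(t, 4), rel=1e-5)
        assert p == pytest.approx(0.0132, abs=2e-4)

    def test_matches_scipy_reference(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 30))
            a = rng.normal(50, 10, n)
            b = a + rng.normal(0.5, 3, n)
            t, p = paired_t_test(list(a), list(b))
            t_ref, p_ref = stats.ttest_rel(a, b)
            assert t == pytest.approx(t_ref, rel=1e-6)
            assert p == pytest.approx(p_ref, rel=1e-6)

    def test_errors(self):
        with pytest.raises(DataError):
            paired_t_test([1.0], [2.0])
        with pytest.raises(DataError):
            paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCompareMatrices:
    def test_self_comparison_all_ties(self, benchmark3, vtml200):
        groups, _, _ = benchmark3
        spec_a = ScoringSpec("A", matrix=vtml200)
        spec_b = ScoringSpec("B", matrix=vtml200)
        counts, comps = compare_matrices_on_groups(
            groups[:2], spec_a, spec_b, seed=4,
            alpha_range=range(5, 16, 5), beta_range=range(1, 4),
        )
        assert counts == {"a_better": 0, "b_better": 0, "no_difference": 2}
        assert all(c.verdict == "no-significant-difference" for c in comps)

    def test_antisymmetric_counts(self, benchmark3, vtml200, blosum50):
        groups, _, _ = benchmark3
        sa = ScoringSpec("A", matrix=vtml200)
        sb = ScoringSpec("B", matrix=blosum50)
        c_ab, _ = compare_matrices_on_groups(
            groups, sa, sb, seed=4, alpha_range=range(5, 16, 5), beta_range=range(1, 4)
        )
        c_ba, _ = compare_matrices_on_groups(
            groups, ScoringSpec("A", matrix=blosum50), ScoringSpec("B", matrix=vtml200),
            seed=4, alpha_range=range(5, 16, 5), beta_range=range(1, 4),
        )
        assert c_ab["a_better"] == c_ba["b_better"]
        assert c_ab["b_better"] == c_ba["a_better"]
        assert c_ab["no_difference"] == c_ba["no_difference"]


class TestOverlapAnalysis:
    def test_identical_sets(self):
        part = overlap_analysis([{1, 2}, {1, 2}])
        assert part == {frozenset({0, 1}): 2}

    def test_disjoint_sets(self):
        part = overlap_analysis([{1}, {2}, {3}])
        assert part == {
            frozenset({0}): 1,
            frozenset({1}): 1,
            frozenset({2}): 1,
        }

    def test_triple_overlap(self):
        part = overlap_analysis([{1, 2, 3}, {3, 4}, {3, 5}])
        assert part[frozenset({0, 1, 2})] == 1
        assert part[frozenset({0})] == 2  # elements 1, 2
        assert part[frozenset({1})] == 1  # element 4
        assert part[frozenset({2})] == 1  # element 5

    def test_needs_two_sets(self):
        with pytest.raises(DataError):
            overlap_analysis([{1}])
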