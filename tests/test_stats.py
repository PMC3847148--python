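"""Class-comparison statistics: t/F tests, permutation p, BH FDR.

scipy.stats and statsmodels act as independent oracles throughout; the
permutation machinery is additionally checked against a literal
enumeration built on scipy's t test.
"""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from synlethscreen import (
    ExpressionDataset,
    PermutationScheme,
    UntestableGeneError,
    bh_fdr,
    f_test,
    permutation_p,
    run_class_comparison,
    t_test_two_sided,
)
from synlethscreen.stats import UP_IN_C1, UP_IN_C2


def brute_force_permutation_p(values, mask, variance_mode="pooled"):
    """Literal enumeration of every distinct c1 assignment (scipy t test)."""
    values = np.asarray(values, float)
    mask = np.asarray(mask, bool)
    n, n1 = values.size, int(mask.sum())
    equal_var = variance_mode == "pooled"
    obs = sps.ttest_ind(values[mask], values[~mask], equal_var=equal_var).pvalue
    count = total = 0
    for combo in itertools.combinations(range(n), n1):
        m = np.zeros(n, bool)
        m[list(combo)] = True
        p = sps.ttest_ind(values[m], values[~m], equal_var=equal_var).pvalue
        count += p <= obs + 1e-12
        total += 1
    return count / total


class TestTTest:
    def test_identical_groups_give_zero_statistic_unit_p(self):
        assert t_test_two_sided([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_frozen_pooled_oracle(self):
        # closed form: pooled variance 5/3, se = sqrt(5/6), df = 6
        stat, p = t_test_two_sided([1, 2, 3, 4], [3, 4, 5, 6], "pooled")
        assert stat == pytest.approx(-2.1908902300206643, abs=1e-12)
        assert p == pytest.approx(0.0709876543209876, abs=1e-12)

    @pytest.mark.parametrize("variance_mode", ["pooled", "welch"])
    def test_matches_scipy_on_random_vectors(self, variance_mode):
        rng = np.random.default_rng(42)
        for _ in range(50):
            x1 = rng.normal(size=rng.integers(2, 12))
            x2 = rng.normal(1.0, 2.0, size=rng.integers(2, 12))
            stat, p = t_test_two_sided(x1, x2, variance_mode)
            ref = sps.ttest_ind(x1, x2, equal_var=variance_mode == "pooled")
            assert stat == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=8),
        st.lists(st.floats(-50, 50), min_size=2, max_size=8),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_swapping_groups_negates_statistic_keeps_p(self, x1, x2):
        s12, p12 = t_test_two_sided(x1, x2)
        s21, p21 = t_test_two_sided(x2, x1)
        assert s12 == pytest.approx(-s21, abs=1e-9) or (s12 == 0 and s21 == 0)
        assert p12 == pytest.approx(p21, abs=1e-9)

    def test_missing_values_dropped_then_small_class_untestable(self):
        stat, _ = t_test_two_sided([1.0, np.nan, 2.0, 3.0], [4.0, 5.0])
        assert stat == t_test_two_sided([1.0, 2.0, 3.0], [4.0, 5.0])[0]
        with pytest.raises(UntestableGeneError):
            t_test_two_sided([1.0, np.nan], [4.0, 5.0])


class TestFTest:
    def test_two_group_f_equals_squared_pooled_t(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            x1 = rng.normal(size=6)
            x2 = rng.normal(0.5, 1.5, size=9)
            t, p_t = t_test_two_sided(x1, x2, "pooled")
            f, p_f = f_test([x1, x2])
            assert f == pytest.approx(t * t, rel=1e-10, abs=1e-10)
            assert p_f == pytest.approx(p_t, abs=1e-10)

    def test_three_identical_groups(self):
        assert f_test([(1, 2), (1, 2), (1, 2)]) == (0.0, 1.0)

    def test_matches_scipy_anova(self):
        groups = [(1.0, 2.0), (1.0, 2.0), (10.0, 11.0)]
        f, p = f_test(groups)
        ref = sps.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_degenerate_zero_variance_unequal_means(self):
        f, p = f_test([(1.0, 1.0), (2.0, 2.0)])
        assert math.isinf(f) and p == 0.0


class TestPermutationP:
    def test_exhaustive_hand_case_two_of_six(self):
        """Only the observed split and its mirror reach the observed p
        among the C(4,2)=6 assignments."""
        p = permutation_p(
            [5, 6, 1, 2], [True, True, False, False],
            PermutationScheme(mode="exhaustive"),
        )
        assert p == pytest.approx(2 / 6, abs=1e-15)

    def test_constant_gene_has_permutation_p_one(self):
        scheme = PermutationScheme(n_permutations=200, seed=1, mode="monte_carlo")
        p = permutation_p([3.0] * 8, [True] * 4 + [False] * 4, scheme)
        assert p == 1.0

    @pytest.mark.parametrize("variance_mode", ["pooled", "welch"])
    def test_exhaustive_matches_brute_force_enumeration(self, variance_mode):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n1, n2 = rng.integers(2, 5, size=2)
            values = rng.normal(size=n1 + n2)
            mask = np.array([True] * n1 + [False] * n2)
            ours = permutation_p(
                values, mask, PermutationScheme(mode="exhaustive"), variance_mode
            )
            assert ours == pytest.approx(
                brute_force_permutation_p(values, mask, variance_mode), abs=1e-15
            )

    def test_monte_carlo_within_three_se_of_exhaustive(self):
        rng = np.random.default_rng(17)
        n_perm = 4000
        for _ in range(8):
            values = rng.normal(size=10)
            values[:5] += rng.uniform(0, 2)
            mask = np.array([True] * 5 + [False] * 5)
            exact = permutation_p(values, mask, PermutationScheme(mode="exhaustive"))
            mc = permutation_p(
                values, mask,
                PermutationScheme(n_permutations=n_perm, seed=99, mode="monte_carlo"),
            )
            se = math.sqrt(exact * (1 - exact) / n_perm)
            assert abs(mc - exact) <= 3 * se + 1.0 / (n_perm + 1)

    def test_monte_carlo_is_deterministic_given_seed_and_never_zero(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=12)
        values[:6] += 5.0  # extreme effect: smallest achievable p
        mask = np.array([True] * 6 + [False] * 6)
        scheme = PermutationScheme(n_permutations=500, seed=21, mode="monte_carlo")
        first = permutation_p(values, mask, scheme)
        second = permutation_p(values, mask, scheme)
        assert first == second
        assert first >= 1.0 / 501

    def test_auto_mode_uses_exhaustive_for_small_spaces(self):
        values = np.array([5.0, 6.0, 1.0, 2.0])
        mask = np.array([True, True, False, False])
        auto = permutation_p(values, mask, PermutationScheme(n_permutations=100, mode="auto"))
        assert auto == pytest.approx(2 / 6, abs=1e-15)

    def test_untestable_gene_raises(self):
        with pytest.raises(UntestableGeneError):
            permutation_p([1.0, np.nan, 2.0, 3.0], [True, True, False, False],
                          PermutationScheme())

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            PermutationScheme(n_permutations=0)
        with pytest.raises(ValueError):
            PermutationScheme(mode="bootstrap")


class TestBhFdr:
    def test_hand_worked_step_up_case(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5], atol=1e-15
        )

    def test_single_p_is_identity(self):
        assert bh_fdr([0.5]) == pytest.approx([0.5])

    def test_empty_input_gives_empty_output(self):
        assert bh_fdr([]).size == 0

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.random(rng.integers(1, 80))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_fdr(p), ref, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_step_up_properties(self, pvals):
        q = bh_fdr(pvals)
        p = np.asarray(pvals)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()  # monotone along sorted p

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])


class TestRunClassComparison:
    def test_planted_gene_detected_and_directional(self, small_bundle, small_labels):
        result = run_class_comparison(
            small_bundle.datasets[0], small_labels,
            scheme=PermutationScheme(n_permutations=1000, seed=2),
        )
        by_gene = {r.gene: r for r in result}
        for gene in small_bundle.truth.planted_genes:
            r = by_gene[gene]
            assert r.direction == UP_IN_C1
            assert r.permutation_p <= result.alpha
            assert r.mean1 > r.mean2

    def test_f_and_t_agree_for_two_classes(self, small_bundle, small_labels):
        dataset = small_bundle.datasets[0]
        result = run_class_comparison(dataset, small_labels, scheme=None)
        mask = small_labels.mask(dataset.samples)
        for r in list(result)[:40]:
            row = dataset.values[dataset.genes.index(r.gene)]
            f, p_f = f_test([row[mask], row[~mask]])
            assert f == pytest.approx(r.statistic**2, rel=1e-10, abs=1e-10)
            assert p_f == pytest.approx(r.parametric_p, abs=1e-10)

    def test_single_gene_q_equals_p(self, small_labels, small_bundle):
        samples = small_bundle.datasets[0].samples
        rng = np.random.default_rng(0)
        ds = ExpressionDataset("one", ("G1",), samples, rng.normal(size=(1, len(samples))))
        result = run_class_comparison(ds, small_labels, scheme=None)
        assert result.results[0].q_value == pytest.approx(result.results[0].parametric_p)

    def test_gene_with_sparse_class_is_untestable_and_outside_fdr(self, small_labels, small_bundle):
        samples = small_bundle.datasets[0].samples
        mask = small_labels.mask(samples)
        rng = np.random.default_rng(1)
        values = rng.normal(size=(3, len(samples)))
        values[1, mask] = np.nan  # one value left in c1? none: all c1 missing
        values[1, np.flatnonzero(mask)[:-1]] = np.nan
        ds = ExpressionDataset("sparse", ("A", "B", "C"), samples, values)
        result = run_class_comparison(ds, small_labels, scheme=None)
        assert result.untestable_genes == ("B",)
        assert {r.gene for r in result} == {"A", "C"}

    def test_no_testable_genes_is_an_error(self, small_labels, small_bundle):
        samples = small_bundle.datasets[0].samples
        values = np.full((2, len(samples)), np.nan)
        ds = ExpressionDataset("void", ("A", "B"), samples, values)
        with pytest.raises(ValueError, match="no testable genes"):
            run_class_comparison(ds, small_labels, scheme=None)

    def test_kinase_universe_restricts_fdr_and_results(self, small_bundle, small_labels):
        dataset = small_bundle.datasets[0]
        full = run_class_comparison(dataset, small_labels, scheme=None)
        restricted = run_class_comparison(
            dataset, small_labels, scheme=None, universe=small_bundle.kinases
        )
        assert {r.gene for r in restricted} == set(small_bundle.kinases)
        # parametric p's are unchanged; q's are BH over the smaller universe
        full_p = {r.gene: r.parametric_p for r in full}
        assert all(r.parametric_p == full_p[r.gene] for r in restricted)
        np.testing.assert_allclose(
            [r.q_value for r in restricted],
            bh_fdr([r.parametric_p for r in restricted]),
            atol=1e-15,
        )

    def test_permutation_stage_skippable(self, small_bundle, small_labels):
        result = run_class_comparison(small_bundle.datasets[0], small_labels, scheme=None)
        assert all(math.isnan(r.permutation_p) for r in result)

    def test_results_table_sorted_by_permutation_p_then_gene(self, small_bundle, small_labels):
        result = run_class_comparison(
            small_bundle.datasets[0], small_labels,
            scheme=PermutationScheme(n_permutations=200, seed=4),
        )
        frame = result.to_frame()
        keys = list(zip(frame["permutation_p"], frame["gene"]))
        assert keys == sorted(keys)

    def test_identical_seed_gives_bit_identical_permutation_p(self, small_bundle, small_labels):
        scheme = PermutationScheme(n_permutations=300, seed=12)
        a = run_class_comparison(small_bundle.datasets[0], small_labels, scheme=scheme)
        b = run_class_comparison(small_bundle.datasets[0], small_labels, scheme=scheme)
        assert [r.permutation_p for r in a] == [r.permutation_p for r in b]
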