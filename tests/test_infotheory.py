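"""Plug-in entropies, the closed-form MI identities and the coefficients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kendalltau as scipy_kendalltau
from scipy.stats import mannwhitneyu

from kendalltrans import (
    auroc,
    conditional_mi,
    contingency_table,
    interaction_information,
    joint_mi,
    kendall_tau,
    kendall_transform,
    mi_from_auroc,
    mi_from_rho,
    mi_from_tau,
    ml_entropy,
    mutual_information,
    quantise,
)

LOG2 = np.log(2.0)
LOG3 = np.log(3.0)


class TestMlEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [((6, 6), LOG2), ((4, 4, 4), LOG3), ((12,), 0.0)],
    )
    def test_reference_values(self, counts, expected):
        assert ml_entropy(counts) == pytest.approx(expected, abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ml_entropy([])

    def test_contingency_table_marginal(self):
        table = contingency_table(["a", "b", "a", "b"])
        assert table.total == 4
        assert ml_entropy(table) == pytest.approx(LOG2)

    def test_tie_free_transform_has_entropy_log2(self, rng):
        for n in (2, 5, 23):
            k = kendall_transform(rng.permutation(n))
            _, counts = np.unique(k.states, return_counts=True)
            assert ml_entropy(counts) == pytest.approx(LOG2, abs=1e-12)


class TestMutualInformation:
    def test_self_mi_of_tie_free_transform_is_log2(self, rng):
        k = kendall_transform(rng.permutation(8))
        assert mutual_information(k, k) == pytest.approx(LOG2, abs=1e-12)

    def test_single_swap_example(self):
        k1 = kendall_transform([1, 2, 3, 4])
        k2 = kendall_transform([1, 2, 4, 3])
        assert mutual_information(k1, k2) == pytest.approx(0.242586, abs=1e-6)

    def test_constant_feature_carries_no_information(self, rng):
        k = kendall_transform(rng.permutation(6))
        const = kendall_transform(np.ones(6))
        assert mutual_information(k, const) == 0.0

    def test_missing_pairs_dropped(self):
        k1 = kendall_transform([1.0, 2.0, np.nan, 4.0])
        k2 = kendall_transform([1.0, 2.0, 3.0, 4.0])
        assert mutual_information(k1, k2) == pytest.approx(LOG2, abs=1e-12)

    def test_all_missing_rejected(self):
        k = kendall_transform([np.nan, np.nan, 1.0])
        with pytest.raises(ValueError, match="complete"):
            mutual_information(k, k)


class TestMultivariateScores:
    def test_conditioning_on_either_argument_kills_cmi(self, rng):
        k1 = kendall_transform(rng.normal(size=10))
        k2 = kendall_transform(rng.normal(size=10))
        assert conditional_mi(k1, k2, k2) == pytest.approx(0.0, abs=1e-12)

    def test_chain_rule_identity_on_random_tables(self, rng):
        for _ in range(20):
            a, b, c = rng.integers(0, 3, size=(3, 30))
            lhs = mutual_information(a, b) + conditional_mi(a, c, b)
            rhs = joint_mi(b, c, a)
            assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_joint_mi_with_itself_is_entropy(self, rng):
        k = kendall_transform(rng.permutation(7))
        assert joint_mi(k, k, k) == pytest.approx(LOG2, abs=1e-12)

    def test_interaction_of_identical_transforms(self, rng):
        k = kendall_transform(rng.permutation(9))
        assert interaction_information(k, k, k) == pytest.approx(LOG2, abs=1e-12)

    def test_independent_triple_scores_are_small(self, rng):
        n = 400
        ks = [kendall_transform(rng.normal(size=n)) for _ in range(3)]
        assert conditional_mi(*ks) < 0.01
        assert joint_mi(*ks) < 0.01
        assert abs(interaction_information(*ks)) < 0.01


class TestKendallTau:
    def test_perfect_agreement_and_reversal(self, rng):
        x = rng.permutation(11)
        assert kendall_tau(x, x) == 1.0
        assert kendall_tau(x, -x) == -1.0

    def test_matches_reference_implementation_when_tie_free(self, rng):
        for _ in range(25):
            x = rng.normal(size=rng.integers(3, 30))
            y = rng.normal(size=x.size)
            assert kendall_tau(x, y) == pytest.approx(
                scipy_kendalltau(x, y).statistic, abs=1e-12
            )

    def test_quantisation_into_m_half_plus_one_states(self):
        from itertools import permutations

        n = 5
        x = np.arange(n)
        taus = {kendall_tau(x, np.array(p)) for p in permutations(range(n))}
        assert len(taus) == n * (n - 1) // 2 + 1  # 11 for n = 5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 2, 3], [1, 2])


class TestClosedForms:
    def test_mi_from_tau_reference_points(self):
        assert mi_from_tau(0.0) == 0.0
        assert mi_from_tau(0.5) == pytest.approx(0.130812, abs=1e-6)
        assert mi_from_tau(1.0) == pytest.approx(LOG2, abs=1e-12)
        assert mi_from_tau(-1.0) == pytest.approx(LOG2, abs=1e-12)

    def test_mi_from_tau_even_and_increasing(self):
        grid = np.linspace(0.0, 0.999, 50)
        vals = [mi_from_tau(t) for t in grid]
        assert all(np.diff(vals) > 0)
        assert all(
            mi_from_tau(-t) == pytest.approx(mi_from_tau(t), abs=1e-15) for t in grid
        )

    def test_mi_from_tau_domain(self):
        with pytest.raises(ValueError):
            mi_from_tau(1.01)

    def test_mi_from_rho_reference_points(self):
        assert mi_from_rho(0.0) == 0.0
        assert mi_from_rho(0.9) == pytest.approx(0.830366, abs=1e-6)
        assert mi_from_rho(0.99) > LOG2  # the Gaussian form exceeds the cap

    def test_mi_from_rho_domain(self):
        for bad in (1.0, -1.0, 1.5):
            with pytest.raises(ValueError):
                mi_from_rho(bad)

    @given(st.integers(3, 50), st.integers(0, 10_000))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_tau_identity_is_exact_not_asymptotic(self, n, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, n))
        empirical = mutual_information(kendall_transform(x), kendall_transform(y))
        assert empirical == pytest.approx(mi_from_tau(kendall_tau(x, y)), abs=1e-12)


class TestAuroc:
    def test_perfect_separation(self):
        res = auroc([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        assert res.auroc == 1.0 and res.u == 0.0 and (res.a, res.b) == (2, 2)

    def test_random_scores_near_half(self, rng):
        res = auroc(rng.normal(size=2000), np.repeat([0, 1], 1000))
        assert res.auroc == pytest.approx(0.5, abs=0.05)

    def test_u_matches_rank_sum_implementation(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 40))
            x = rng.normal(size=n)
            y = np.zeros(n, dtype=int)
            y[rng.choice(n, size=int(rng.integers(2, n - 1)), replace=False)] = 1
            res = auroc(x, y)
            # scipy's statistic counts pairs where the first sample wins;
            # with the negative class first that is exactly ab(1-A) = U
            u_ref = mannwhitneyu(x[y == 0], x[y == 1], alternative="two-sided")
            assert res.u == pytest.approx(u_ref.statistic, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            auroc([1.0, 2.0, 3.0], [1, 1, 1])

    def test_tied_scores_rejected(self):
        with pytest.raises(ValueError, match="tie-free"):
            auroc([1.0, 1.0, 2.0], [0, 1, 1])


class TestMiFromAuroc:
    def test_uninformative_auroc_gives_zero(self):
        assert mi_from_auroc(0.5, 5, 5) == 0.0

    def test_perfect_separation_limit(self):
        assert mi_from_auroc(1.0, 2, 2) == pytest.approx(2 / 3 * LOG2, abs=1e-12)
        direct = mutual_information(
            kendall_transform([1, 2, 3, 4]), kendall_transform([0, 0, 1, 1])
        )
        assert direct == pytest.approx(2 / 3 * LOG2, abs=1e-12)

    def test_identity_with_empirical_mi(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            y = np.zeros(n, dtype=int)
            y[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if len(np.unique(y)) < 2:
                continue
            res = auroc(x, y)
            empirical = mutual_information(kendall_transform(x), kendall_transform(y))
            assert empirical == pytest.approx(
                mi_from_auroc(res.auroc, res.a, res.b), abs=1e-12
            )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            mi_from_auroc(1.2, 2, 2)
        with pytest.raises(ValueError):
            mi_from_auroc(0.7, 0, 4)


class TestQuantise:
    def test_equal_width_interval_arithmetic(self):
        labels = quantise(np.array([0.0, 0.1, 0.5, 0.9, 1.0]), 5, "equal-width")
        assert labels.tolist() == [1, 1, 3, 5, 5]

    def test_equal_frequency_balanced_groups(self):
        labels = quantise(np.arange(9.0), 3, "equal-frequency")
        assert np.array_equal(np.bincount(labels)[1:], [3, 3, 3])

    def test_monotone_transform_moves_width_bins_not_frequency_bins(self, rng):
        x = rng.lognormal(size=40)
        f = np.log  # strictly increasing, strongly non-affine
        assert not np.array_equal(
            quantise(x, 4, "equal-width"), quantise(f(x), 4, "equal-width")
        )
        assert np.array_equal(
            quantise(x, 4, "equal-frequency"), quantise(f(x), 4, "equal-frequency")
        )

    def test_constant_input_warns_single_category(self):
        with pytest.warns(UserWarning, match="constant"):
            labels = quantise(np.full(5, 2.0), 3)
        assert np.array_equal(labels, np.ones(5, dtype=int))

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            quantise(np.arange(5.0), 1)
        with pytest.raises(ValueError):
            quantise(np.arange(5.0), 3, "fancy")
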