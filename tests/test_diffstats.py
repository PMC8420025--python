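import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tpakit.diffstats import (
    anova_permutation_fdr,
    mann_whitney,
    moderated_t,
    permutation_fdr_two_sample,
)

from conftest import make_annotation, make_log_matrix


def mann_whitney_exact_oracle(a, b):
    """Two-sided p by exhaustive enumeration of all C(n1+n2, n1) assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)

    def u_of(first):
        second = [x for i, x in enumerate(pooled) if i not in set(first)]
        xs = [pooled[i] for i in first]
        return sum(1 for x in xs for y in second if x > y) + 0.5 * sum(
            1 for x in xs for y in second if x == y
        )

    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    mu = n1 * len(b) / 2
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n1)]
    extreme = sum(1 for u in us if abs(u - mu) >= abs(u_obs - mu) - 1e-12)
    return extreme / len(us)


class TestModeratedT:
    def test_reduces_to_classical_t_at_s0_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(0, 1, 5)
            y = rng.normal(0.5, 1, 7)
            d, p = moderated_t(x, y, s0=0.0)
            ref = stats.ttest_ind(x, y, equal_var=True)
            assert abs(d - ref.statistic) < 1e-12
            assert abs(p - ref.pvalue) < 1e-12

    def test_equal_means_give_zero(self):
        d, _ = moderated_t([1.0, 2.0, 3.0], [3.0, 2.0, 1.0], s0=0.1)
        assert d == 0.0

    def test_identical_samples_give_zero(self):
        d, p = moderated_t([10, 12, 11], [10, 12, 11], s0=0.1)
        assert d == 0.0
        assert abs(p - 1.0) < 1e-12

    def test_zero_variance_both_groups_s0_zero_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            moderated_t([5.0, 5.0], [3.0, 3.0], s0=0.0)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        st.lists(st.floats(-10, 10), min_size=2, max_size=8),
        st.lists(st.floats(-10, 10), min_size=2, max_size=8),
    )
    def test_antisymmetric_under_group_swap(self, x, y):
        if np.std(x + y) == 0:
            return
        d_xy, _ = moderated_t(x, y, s0=0.1)
        d_yx, _ = moderated_t(y, x, s0=0.1)
        assert math.isclose(d_xy, -d_yx, rel_tol=1e-10, abs_tol=1e-12)

    def test_s0_monotone_shrinkage(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        prev = math.inf
        for s0 in (0.0, 0.05, 0.1, 0.5, 1.0):
            d, _ = moderated_t(x, y, s0=s0)
            assert abs(d) <= prev + 1e-12
            prev = abs(d)


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert abs(p - 0.1) < 1e-12  # 2 of 20 assignments this extreme

    def test_identical_multisets_p_one(self):
        _, p = mann_whitney([1, 2, 3], [2, 1, 3])
        assert p > 0.99

    def test_u_statistics_sum_to_product(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 5), rng.normal(0, 1, 4)
        ua, _ = mann_whitney(a, b)
        ub, _ = mann_whitney(b, a)
        assert ua + ub == len(a) * len(b)

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 4), (5, 5), (4, 6)])
    def test_exact_p_equals_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            a = rng.normal(0, 1, n1)
            b = rng.normal(0.8, 1, n2)
            _, p = mann_whitney(a, b)
            assert abs(p - mann_whitney_exact_oracle(a, b)) < 1e-10

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


def _two_group_setup(seed, n_proteins=200, shift_first=0):
    rng = np.random.default_rng(seed)
    ann = make_annotation({"A": 5, "B": 5}, n_tech=2)
    X = rng.normal(20, 0.3, (n_proteins, 20))
    if shift_first:
        a_cols = [ann.run_ids.index(r) for r in ann.runs_in_group("A")]
        X[:shift_first, a_cols] += 2.0
    return make_log_matrix(X, run_ids=ann.run_ids), ann


class TestPermutationFdrTwoSample:
    def test_null_calibration(self):
        fracs = []
        for seed in range(10):
            lm, ann = _two_group_setup(seed)
            res = permutation_fdr_two_sample(lm, ann, "A", "B", seed=seed)
            fracs.append(res["significant"].mean())
        assert np.mean(fracs) <= 0.02

    def test_power_on_planted_effects(self):
        hits = []
        for seed in range(5):
            lm, ann = _two_group_setup(seed, shift_first=50)
            res = permutation_fdr_two_sample(lm, ann, "A", "B", seed=seed)
            hits.append(res["significant"].iloc[:50].mean())
        assert np.mean(hits) >= 0.9

    def test_log2_fc_is_mean_difference(self):
        lm, ann = _two_group_setup(3, n_proteins=20, shift_first=5)
        res = permutation_fdr_two_sample(lm, ann, "A", "B", seed=0)
        a_cols = ann.runs_in_group("A")
        b_cols = ann.runs_in_group("B")
        expected = lm.values[a_cols].mean(axis=1) - lm.values[b_cols].mean(axis=1)
        np.testing.assert_allclose(res["log2_fc"], expected, rtol=1e-12)

    def test_small_case_enumerates_all_relabelings(self):
        ann = make_annotation({"A": 2, "B": 2}, n_tech=1)
        rng = np.random.default_rng(4)
        lm = make_log_matrix(rng.normal(20, 1, (30, 4)), run_ids=ann.run_ids)
        with pytest.warns(UserWarning, match="distinct permutations"):
            res = permutation_fdr_two_sample(lm, ann, "A", "B", n_perm=250, seed=0)
        # C(4,2)=6 distinct relabelings -> estimate deterministic
        res2 = permutation_fdr_two_sample(lm, ann, "A", "B", n_perm=6, seed=99)
        np.testing.assert_allclose(res["q_value"], res2["q_value"])

    def test_seeded_bit_reproducibility(self):
        lm, ann = _two_group_setup(5, shift_first=10)
        r1 = permutation_fdr_two_sample(lm, ann, "A", "B", seed=42)
        r2 = permutation_fdr_two_sample(lm, ann, "A", "B", seed=42)
        pd.testing.assert_frame_equal(r1, r2)

    def test_significant_implies_q_below_target(self):
        lm, ann = _two_group_setup(6, shift_first=30)
        res = permutation_fdr_two_sample(lm, ann, "A", "B", seed=1, target_fdr=0.05)
        assert (res.loc[res["significant"], "q_value"] <= 0.05).all()


class TestAnovaPermutationFdr:
    def _cohort(self, seed, n_proteins=150, planted=0):
        ann = make_annotation({"A": 3, "B": 3, "C": 3}, n_tech=2)
        rng = np.random.default_rng(seed)
        X = rng.normal(20, 0.3, (n_proteins, 18))
        if planted:
            cols = [ann.run_ids.index(r) for r in ann.runs_in_group("A")]
            X[:planted, cols] += 2.0
        return make_log_matrix(X, run_ids=ann.run_ids), ann

    def test_null_calibration(self):
        fracs = []
        for seed in range(10):
            lm, ann = self._cohort(seed)
            res = anova_permutation_fdr(lm, ann, seed=seed)
            fracs.append(res["significant"].mean())
        assert np.mean(fracs) <= 0.02

    def test_recovers_planted_group_shifts(self):
        # five-group design: with few groups the plain FDR ratio saturates,
        # because random permutations reconstruct the true grouping too often
        ann = make_annotation({g: 4 for g in "ABCDE"}, n_tech=2)
        hits = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(20, 0.3, (150, 40))
            cols = [ann.run_ids.index(r) for r in ann.runs_in_group("A")]
            X[:20, cols] += 2.0
            lm = make_log_matrix(X, run_ids=ann.run_ids)
            res = anova_permutation_fdr(lm, ann, seed=seed)
            hits.append(res["significant"].iloc[:20].mean())
        assert np.mean(hits) >= 0.9

    def test_f_invariant_to_within_sample_replicate_swap(self):
        lm, ann = self._cohort(7, n_proteins=40)
        res1 = anova_permutation_fdr(lm, ann, seed=0)
        # swap the two technical replicate columns of one sample
        cols = list(lm.values.columns)
        i, j = cols.index("A1.1"), cols.index("A1.2")
        cols[i], cols[j] = cols[j], cols[i]
        swapped = make_log_matrix(
            lm.values[cols].to_numpy(), run_ids=lm.values.columns.tolist()
        )
        res2 = anova_permutation_fdr(swapped, ann, seed=0)
        np.testing.assert_allclose(res1["statistic"], res2["statistic"], rtol=1e-12)

    def test_group_with_one_sample_rejected(self):
        ann = make_annotation({"A": 1, "B": 3}, n_tech=2)
        rng = np.random.default_rng(8)
        lm = make_log_matrix(rng.normal(20, 1, (10, 8)), run_ids=ann.run_ids)
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_permutation_fdr(lm, ann, seed=0)

    def test_f_matches_scipy_oneway(self):
        lm, ann = self._cohort(9, n_proteins=25)
        res = anova_permutation_fdr(lm, ann, seed=0)
        for i in range(25):
            groups = [
                lm.values.loc[lm.values.index[i], ann.runs_in_group(g)].to_numpy()
                for g in ("A", "B", "C")
            ]
            expected = stats.f_oneway(*groups).statistic
            assert abs(res["statistic"].iloc[i] - expected) < 1e-10
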