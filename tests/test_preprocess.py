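import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tpakit import preprocess
from tpakit.preprocess import (
    LogMatrix,
    filter_by_group_presence,
    impute_downshifted_gaussian,
    log2_transform,
    pearson_correlation_matrix,
    zscore_rows,
)

from conftest import make_annotation, make_intensity_matrix, make_log_matrix


class TestLog2Transform:
    def test_exact_power_and_missing_preserved(self):
        raw = np.array([[1024.0, np.nan], [2.0, 8.0]])
        lm = log2_transform(make_intensity_matrix(raw), basis="lfq")
        assert lm.values.iloc[0, 0] == 10.0
        assert np.isnan(lm.values.iloc[0, 1])
        assert lm.values.iloc[1, 1] == 3.0

    def test_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(1, 1e8, (20, 5))
        raw[rng.random((20, 5)) < 0.2] = np.nan
        lm = log2_transform(make_intensity_matrix(raw), basis="raw")
        expected = np.log2(raw)
        np.testing.assert_allclose(lm.values.to_numpy(), expected, rtol=1e-14)


class TestFilterByGroupPresence:
    def _matrix_with_presence(self, presence):
        """presence: proteins x runs boolean, True = observed."""
        vals = np.where(presence, 20.0, np.nan)
        return make_log_matrix(
            vals, run_ids=[f"{g}{s}.{r}" for g in "AB" for s in (1, 2, 3) for r in (1, 2)][: presence.shape[1]]
        )

    def test_kept_when_one_group_reaches_threshold(self):
        ann = make_annotation({"A": 5, "B": 5}, n_tech=1)
        presence = np.zeros((1, 10), dtype=bool)
        presence[0, :8] = True  # 5/5 in A... columns are A1..A5,B1..B5
        lm = make_log_matrix(np.where(presence, 20.0, np.nan), run_ids=ann.run_ids)
        out = filter_by_group_presence(lm, ann, 0.70)
        assert list(out.values.index) == ["P000"]

    def test_removed_when_below_everywhere(self):
        ann = make_annotation({"A": 5, "B": 5}, n_tech=1)
        presence = np.zeros((1, 10), dtype=bool)
        presence[0, [0, 1, 2, 5, 6, 7]] = True  # 3/5 per group = 0.6
        lm = make_log_matrix(np.where(presence, 20.0, np.nan), run_ids=ann.run_ids)
        out = filter_by_group_presence(lm, ann, 0.70)
        assert len(out.values) == 0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        ann = make_annotation({"A": 3, "B": 2, "C": 2}, n_tech=2)
        presence = rng.random((20, 14)) < 0.6
        lm = make_log_matrix(np.where(presence, 20.0, np.nan), run_ids=ann.run_ids)
        out = filter_by_group_presence(lm, ann, 0.70)

        expected = []
        for i in range(20):
            keep = False
            for g in ("A", "B", "C"):
                cols = [ann.run_ids.index(r) for r in ann.runs_in_group(g)]
                frac = presence[i, cols].sum() / len(cols)
                keep = keep or frac >= 0.70
            if keep:
                expected.append(f"P{i:03d}")
        assert list(out.values.index) == expected

    def test_monotone_in_min_fraction(self):
        rng = np.random.default_rng(2)
        ann = make_annotation({"A": 3, "B": 3}, n_tech=2)
        presence = rng.random((30, 12)) < 0.5
        lm = make_log_matrix(np.where(presence, 20.0, np.nan), run_ids=ann.run_ids)
        prev = None
        for frac in (0.9, 0.7, 0.5, 0.3):
            kept = set(filter_by_group_presence(lm, ann, frac).values.index)
            if prev is not None:
                assert prev <= kept
            prev = kept

    def test_invalid_fraction_rejected(self):
        ann = make_annotation({"A": 2}, n_tech=1)
        lm = make_log_matrix(np.ones((2, 2)), run_ids=ann.run_ids)
        with pytest.raises(ValueError):
            filter_by_group_presence(lm, ann, 1.2)


class TestImputation:
    def test_no_missing_is_identity(self):
        lm = make_log_matrix(np.arange(12.0).reshape(3, 4) + 10)
        out = impute_downshifted_gaussian(lm, seed=0)
        pd.testing.assert_frame_equal(out.values, lm.values)
        assert not out.imputed_mask.any().any()

    def test_observed_never_altered_and_mask_records(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(22, 3, (50, 4))
        vals[rng.random((50, 4)) < 0.3] = np.nan
        lm = make_log_matrix(vals)
        out = impute_downshifted_gaussian(lm, seed=1)
        observed = ~np.isnan(vals)
        np.testing.assert_array_equal(
            out.values.to_numpy()[observed], vals[observed]
        )
        np.testing.assert_array_equal(out.imputed_mask.to_numpy(), np.isnan(vals))
        assert out.is_complete

    def test_moments_match_downshifted_normal(self):
        # column observed moments mu=20, sd=2 -> imputed ~ N(16.4, 1.0^2)
        n_miss = 100_000
        col = np.full(n_miss + 2, np.nan)
        col[:2] = [20 - np.sqrt(2), 20 + np.sqrt(2)]  # mean 20, sample SD 2
        lm = make_log_matrix(col.reshape(-1, 1))
        out = impute_downshifted_gaussian(lm, width=0.5, downshift=1.8, seed=11)
        imputed = out.values.to_numpy()[2:, 0]
        assert abs(imputed.mean() - 16.4) < 0.02
        assert abs(imputed.std(ddof=0) - 1.0) < 0.02

    def test_imputed_distribution_passes_ks(self):
        n_miss = 10_000
        col = np.full(n_miss + 2, np.nan)
        col[:2] = [20 - np.sqrt(2), 20 + np.sqrt(2)]
        lm = make_log_matrix(col.reshape(-1, 1))
        out = impute_downshifted_gaussian(lm, seed=5)
        imputed = out.values.to_numpy()[2:, 0]
        p = stats.kstest(imputed, stats.norm(16.4, 1.0).cdf).pvalue
        assert p > 0.001

    def test_seeded_reproducibility(self):
        vals = np.array([[20.0, np.nan], [22.0, 21.0], [np.nan, 19.0]])
        a = impute_downshifted_gaussian(make_log_matrix(vals), seed=9)
        b = impute_downshifted_gaussian(make_log_matrix(vals), seed=9)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_column_with_single_observed_value_errors(self):
        vals = np.array([[20.0, np.nan], [21.0, np.nan], [np.nan, 19.0]])
        with pytest.raises(ValueError, match="run1"):
            impute_downshifted_gaussian(make_log_matrix(vals), seed=0)

    def test_whole_matrix_mode(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(25, 2, (200, 3))
        vals[rng.random((200, 3)) < 0.2] = np.nan
        out = impute_downshifted_gaussian(
            make_log_matrix(vals), seed=2, per_column=False
        )
        assert out.is_complete


class TestZscore:
    def test_closed_form_row(self):
        out = zscore_rows(make_log_matrix([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(
            out.values.to_numpy()[0], [-1.224744871, 0.0, 1.224744871], atol=1e-9
        )

    def test_constant_row_errors(self):
        with pytest.raises(ValueError, match="P001"):
            zscore_rows(make_log_matrix([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50),
            min_size=3,
            max_size=12,
        ).filter(lambda xs: max(xs) - min(xs) > 1e-6)
    )
    def test_rows_have_zero_mean_unit_population_sd(self, row):
        out = zscore_rows(make_log_matrix([row]))
        vals = out.values.to_numpy()[0]
        assert abs(vals.mean()) < 1e-10
        assert abs(vals.std(ddof=0) - 1.0) < 1e-10


class TestPearsonCorrelation:
    def test_self_and_affine_copy_give_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(20, 3, 30)
        vals = np.column_stack([x, 2 * x + 3])
        corr = pearson_correlation_matrix(make_log_matrix(vals))
        assert corr.iloc[0, 0] == 1.0
        assert abs(corr.iloc[0, 1] - 1.0) < 1e-12

    def test_pairwise_complete_matches_brute_force(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(20, 2, (10, 4))
        for i, j in [(0, 0), (3, 1), (5, 2), (7, 3), (9, 0)]:
            vals[i, j] = np.nan
        corr = pearson_correlation_matrix(make_log_matrix(vals))
        for a in range(4):
            for b in range(4):
                shared = ~np.isnan(vals[:, a]) & ~np.isnan(vals[:, b])
                expected = stats.pearsonr(vals[shared, a], vals[shared, b]).statistic
                assert abs(corr.iloc[a, b] - expected) < 1e-12

    def test_entries_bounded(self):
        rng = np.random.default_rng(7)
        corr = pearson_correlation_matrix(make_log_matrix(rng.normal(0, 1, (40, 6))))
        assert (corr.to_numpy() <= 1 + 1e-12).all()
        assert (corr.to_numpy() >= -1 - 1e-12).all()

    def test_too_few_shared_proteins_warns(self):
        vals = np.array(
            [[1.0, np.nan], [2.0, np.nan], [3.0, np.nan], [np.nan, 1.0], [np.nan, 2.0]]
        )
        with pytest.warns(UserWarning, match="fewer than"):
            corr = pearson_correlation_matrix(make_log_matrix(vals))
        assert np.isnan(corr.iloc[0, 1])
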