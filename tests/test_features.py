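"""Outlier masking, correlation filtering, imputation, ranking, splitting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ecglvh import features


class TestIqrFilter:
    def test_tukey_fence_removes_extreme(self):
        s = pd.Series(list(range(1, 10)) + [100.0])
        out = features.iqr_outlier_filter(s)
        assert np.isnan(out.iloc[-1])
        assert out.iloc[:-1].notna().all()

    def test_constant_feature_untouched(self):
        s = pd.Series([5.0] * 20)
        assert features.iqr_outlier_filter(s).notna().all()

    def test_symmetric_data_symmetric_removal(self):
        s = pd.Series(np.concatenate([np.linspace(-1, 1, 50), [-30, 30]]))
        out = features.iqr_outlier_filter(s)
        assert np.isnan(out.iloc[-1]) and np.isnan(out.iloc[-2])
        assert out.iloc[:-2].notna().all()

    def test_training_fences_apply_to_new_data(self):
        train = pd.Series(np.linspace(0, 1, 100))
        fences = features.iqr_fences(train)
        test = pd.Series([0.5, 5.0])
        out = features.iqr_outlier_filter(test, fences)
        assert out.iloc[0] == 0.5 and np.isnan(out.iloc[1])


class TestCorrelationFilter:
    def test_duplicate_feature_dropped(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=200)
        df = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=200)})
        kept = features.correlation_filter(df)
        assert "c" in kept and len(kept) == 2

    def test_below_threshold_pair_kept(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=2000)
        b = 0.89 * a + np.sqrt(1 - 0.89 ** 2) * rng.normal(size=2000)
        df = pd.DataFrame({"a": a, "b": b})
        assert abs(df.corr().loc["a", "b"]) < 0.9
        assert len(features.correlation_filter(df)) == 2

    def test_retained_set_has_no_high_pair_exhaustive(self):
        # brute-force verification on <= 8 features: the retained set
        # must contain no pair at |r| >= 0.9, and must be maximal in the
        # sense that every dropped feature conflicts with a retained one
        rng = np.random.default_rng(2)
        base = rng.normal(size=(300, 3))
        df = pd.DataFrame({
            "x1": base[:, 0],
            "x2": base[:, 0] * 0.98 + rng.normal(0, 0.02, 300),
            "x3": base[:, 0] * 0.97 + rng.normal(0, 0.03, 300),
            "y1": base[:, 1],
            "y2": base[:, 1] + rng.normal(0, 0.01, 300),
            "z": base[:, 2],
        })
        kept = features.correlation_filter(df)
        corr = df.corr().abs()
        for f1, f2 in itertools.combinations(kept, 2):
            assert corr.loc[f1, f2] < 0.9
        for dropped in set(df.columns) - set(kept):
            assert any(corr.loc[dropped, k] >= 0.9 for k in kept)


class TestImpute:
    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        out = features.impute(df, seed=0)
        pd.testing.assert_frame_equal(out, df)

    def test_heavily_missing_feature_dropped(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        df.loc[:14, "c"] = np.nan  # 15 % missing
        out = features.impute(df, seed=0)
        assert "c" not in out.columns and {"a", "b"} <= set(out.columns)

    def test_chained_equations_beat_mean_imputation(self):
        # correlated features, 5 % MCAR masking: regression imputation
        # must reconstruct better than the column mean
        rng = np.random.default_rng(5)
        latent = rng.normal(size=400)
        df_true = pd.DataFrame({
            "a": latent + rng.normal(0, 0.3, 400),
            "b": 2 * latent + rng.normal(0, 0.3, 400),
            "c": -latent + rng.normal(0, 0.3, 400),
        })
        df = df_true.copy()
        mask = rng.random(df.shape) < 0.05
        df[mask] = np.nan
        out = features.impute(df, seed=0)
        mice_rmse = np.sqrt(np.nanmean(
            (out.to_numpy() - df_true.to_numpy())[mask] ** 2))
        mean_filled = df.fillna(df.mean())
        mean_rmse = np.sqrt(np.nanmean(
            (mean_filled.to_numpy() - df_true.to_numpy())[mask] ** 2))
        assert mice_rmse < mean_rmse


class TestChi2Rank:
    def test_label_defining_feature_ranks_first(self):
        rng = np.random.default_rng(6)
        y = pd.Series(rng.integers(0, 2, 500))
        df = pd.DataFrame({"oracle": y.astype(float),
                           "noise1": rng.normal(size=500),
                           "noise2": rng.normal(size=500)})
        ranked = features.chi2_rank(df, y)
        assert ranked.index[0] == "oracle"

    def test_qrs_amplitude_tops_ecg_ranking_on_default_cohort(self):
        # the generative model makes QRS amplitude the strongest ECG
        # correlate of LVH, so it must lead the chi-square ranking
        from ecglvh import synth
        cohort = synth.generate_cohort(synth.CohortSpec(n=20_000, seed=1))
        ranked = features.chi2_rank(cohort[synth.ECG_FEATURES],
                                    cohort["lvh"])
        assert ranked.index[0] == "ecg_qrs_amp"

    def test_informative_above_independent(self):
        rng = np.random.default_rng(7)
        y = pd.Series(rng.integers(0, 2, 2000))
        df = pd.DataFrame({
            "signal": y + rng.normal(0, 0.8, 2000),
            "junk": rng.normal(size=2000),
        })
        ranked = features.chi2_rank(df, y)
        assert ranked["signal"] > ranked["junk"]
        assert ranked.index[0] == "signal"


class TestSplitAndBalance:
    def _df(self, n=1000, n_pos=15, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"x": rng.normal(size=n), "lvh": 0})
        df.loc[rng.choice(n, n_pos, replace=False), "lvh"] = 1
        return df

    def test_counting_example(self):
        df = self._df(1000, 15)
        train, test = features.split_and_balance(df, "lvh", seed=0)
        y_tr = df.loc[train, "lvh"]
        y_te = df.loc[test, "lvh"]
        assert y_te.sum() == 3           # stratified 20 % of 15
        assert y_tr.sum() == 12
        assert (y_tr == 0).sum() == 12   # majority down-sampled to match

    def test_balanced_input_untouched(self):
        df = self._df(100, 40)
        train, _ = features.split_and_balance(df, "lvh", seed=0)
        y_tr = df.loc[train, "lvh"]
        assert abs(int((y_tr == 1).sum()) - int((y_tr == 0).sum())) <= 0

    def test_same_seed_identical_split(self):
        df = self._df()
        t1 = features.split_and_balance(df, "lvh", seed=3)
        t2 = features.split_and_balance(df, "lvh", seed=3)
        assert t1[0].equals(t2[0]) and t1[1].equals(t2[1])

    def test_test_set_untouched(self):
        df = self._df()
        _, test = features.split_and_balance(df, "lvh", seed=1)
        assert len(test) == 200  # full 20 %, no balancing


class TestFeaturePreprocessor:
    def test_fit_transform_shapes_and_scaling(self, small_cohort):
        from ecglvh import synth
        X = small_cohort[synth.ECG_FEATURES]
        y = small_cohort["lvh"]
        prep = features.FeaturePreprocessor(seed=0).fit(X, y)
        Z = prep.transform(X)
        assert set(Z.columns) == set(prep.retained_)
        means = Z.mean()
        assert np.abs(means).max() < 0.2  # roughly centred
        assert prep.ranking_ is not None

    def test_zero_variance_feature_dropped(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame({"a": rng.normal(size=100), "const": 1.0})
        prep = features.FeaturePreprocessor(seed=0).fit(X)
        assert "const" not in prep.retained_
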