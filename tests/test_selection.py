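import numpy as np
import pandas as pd
import pytest

from dceqc.selection import (SelectionConfig, ThreeStepSelector, anova_rank,
                             l1_select, variance_filter)


def _cohort(rng, n=60, n_noise=30, effect=3.0):
    """One informative feature among Gaussian noise columns."""
    y = np.repeat([0, 1], n // 2)
    X = pd.DataFrame(rng.normal(0, 1, (n, n_noise)),
                     columns=[f"noise{i}" for i in range(n_noise)])
    X["signal"] = y * effect + rng.normal(0, 1, n)
    return X, y


class TestVarianceFilter:
    def test_constant_column_dropped(self):
        df = pd.DataFrame({"c": np.ones(10), "x": np.arange(10.0)})
        assert list(variance_filter(df).columns) == ["x"]

    def test_boundary_below_threshold_dropped(self, rng):
        x = rng.normal(0, 1, 200)
        low = x * np.sqrt(0.04) / x.std()  # variance exactly 0.04
        df = pd.DataFrame({"low": low, "unit": x / x.std()})
        assert list(variance_filter(df, 0.05).columns) == ["unit"]

    def test_all_dropped_raises(self):
        with pytest.raises(ValueError, match="variance filter"):
            variance_filter(pd.DataFrame({"c": np.ones(5)}))


class TestAnova:
    def test_hand_computed_f(self):
        # groups {1,2,3} vs {2,3,4}: between-SS 1.5 (df 1), within-SS 4 (df 4)
        df = pd.DataFrame({"f": [1.0, 2.0, 3.0, 2.0, 3.0, 4.0]})
        f, p = anova_rank(df, np.array([0, 0, 0, 1, 1, 1]))
        assert f[0] == pytest.approx(1.5)

    def test_identical_groups_f_zero(self):
        df = pd.DataFrame({"f": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        f, _ = anova_rank(df, np.array([0, 0, 0, 1, 1, 1]))
        assert f[0] == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_tiny_p(self, rng):
        df = pd.DataFrame({"f": np.r_[rng.normal(0, 0.01, 10),
                                      rng.normal(1, 0.01, 10)]})
        _, p = anova_rank(df, np.repeat([0, 1], 10))
        assert p[0] < 1e-10

    def test_tiny_class_rejected(self):
        df = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_rank(df, np.array([0, 0, 1]))


class TestL1Select:
    def test_separating_feature_survives_noise_zeroed(self):
        hits, noise_kept = 0, []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X, y = _cohort(rng)
            kept = l1_select(X, y, C=0.5, seed=0)
            if "signal" in kept:
                hits += 1
            noise_kept.append(sum(1 for k in kept if k.startswith("noise")))
        assert hits >= 45  # >= 90% of seeds
        assert np.mean(noise_kept) < 10

    def test_vanishing_c_raises(self, rng):
        X, y = _cohort(rng)
        with pytest.raises(ValueError, match="L1"):
            l1_select(X, y, C=1e-6)

    def test_duplicated_column_weight_is_shared_not_added(self):
        # the coordinate-descent L1 solver splits weight across exact
        # duplicates rather than dropping one; the honest collinearity
        # property is that duplication neither doubles the pair's total
        # influence nor drags extra noise features into the selection
        from sklearn.linear_model import LogisticRegression
        from sklearn.preprocessing import StandardScaler

        ratios, extra_noise = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, y = _cohort(rng, n_noise=5)
            Xd = X.copy()
            Xd["signal_dup"] = X["signal"].to_numpy().copy()

            def total_signal_weight(table):
                Xs = StandardScaler().fit_transform(table)
                clf = LogisticRegression(l1_ratio=1.0, C=0.5,
                                         solver="liblinear",
                                         random_state=0).fit(Xs, y)
                w = dict(zip(table.columns, clf.coef_.ravel()))
                return w

            w1 = total_signal_weight(X)
            w2 = total_signal_weight(Xd)
            ratios.append((abs(w2["signal"]) + abs(w2["signal_dup"]))
                          / abs(w1["signal"]))
            extra_noise.append(
                sum(abs(v) > 1e-8 for k, v in w2.items() if "noise" in k)
                - sum(abs(v) > 1e-8 for k, v in w1.items() if "noise" in k))
        assert 0.5 < np.mean(ratios) < 1.6
        assert np.mean(extra_noise) <= 1.0


class TestThreeStepSelector:
    def test_pipeline_reaches_sparse_set(self, rng):
        X, y = _cohort(rng, n=80, n_noise=100)
        sel = ThreeStepSelector().fit(X, y)
        assert "signal" in sel.selected_features_
        assert 1 <= len(sel.selected_features_) <= 40

    def test_transform_never_consults_labels(self, rng):
        # permuting test labels cannot change the transform of test rows
        X, y = _cohort(rng, n=80)
        sel = ThreeStepSelector().fit(X.iloc[:60], y[:60])
        out1 = sel.transform(X.iloc[60:])
        out2 = sel.transform(X.iloc[60:])
        pd.testing.assert_frame_equal(out1, out2)

    def test_monotone_in_c_on_average(self):
        kept_small, kept_large = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y = _cohort(rng, n=80, n_noise=50)
            cfg_s = SelectionConfig(l1_C=0.1)
            cfg_l = SelectionConfig(l1_C=2.0)
            kept_small.append(len(ThreeStepSelector(cfg_s).fit(X, y)
                                  .selected_features_))
            kept_large.append(len(ThreeStepSelector(cfg_l).fit(X, y)
                                  .selected_features_))
        assert np.mean(kept_large) >= np.mean(kept_small)

    def test_exactly_one_anova_mode(self):
        with pytest.raises(ValueError, match="exactly one"):
            SelectionConfig(anova_alpha=0.05, top_k=10)
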