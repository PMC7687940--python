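import numpy as np
import pytest
from scipy import stats

from fibrekit import LabelledDataset, anova_stars, lda_cv, preprocess, rfecv
from fibrekit.stats_classify import significance_stars


def gaussian_dataset(rng, n_per_class=60, separation=10.0, n_features=5):
    """Two well-separated Gaussian classes."""
    a = rng.normal(0.0, 1.0, (n_per_class, n_features))
    b = rng.normal(separation, 1.0, (n_per_class, n_features))
    return LabelledDataset(
        matrix=np.vstack([a, b]),
        labels=np.array(["normal"] * n_per_class + ["carcinoma"] * n_per_class),
        feature_names=[f"f{i}" for i in range(n_features)],
    )


class TestPreprocess:
    def test_minmax_arithmetic(self):
        data = LabelledDataset(
            matrix=np.array([[0.0], [5.0], [10.0]]),
            labels=np.array(["a", "a", "b"]),
            feature_names=["x"],
        )
        from fibrekit.stats_classify import _Gaussianizer

        gz = _Gaussianizer().fit(data.matrix)
        scaled = gz.scaler_.transform(data.matrix)
        np.testing.assert_allclose(scaled.ravel(), [-1.0, 0.0, 1.0])

    def test_normal_feature_stays_symmetric(self, rng):
        x = rng.normal(3.0, 2.0, (500, 1))
        data = LabelledDataset(x, np.array(["a"] * 250 + ["b"] * 250), ["x"])
        out = preprocess(data)
        assert abs(stats.skew(out.matrix[:, 0])) < 0.1

    def test_constant_feature_maps_to_zeros(self):
        data = LabelledDataset(
            matrix=np.column_stack([np.ones(10), np.arange(10.0)]),
            labels=np.array(["a"] * 5 + ["b"] * 5),
            feature_names=["const", "ramp"],
        )
        out = preprocess(data)
        np.testing.assert_array_equal(out.matrix[:, 0], 0.0)

    def test_missing_values_imputed(self):
        m = np.arange(12, dtype=float).reshape(6, 2)
        m[0, 0] = np.nan
        data = LabelledDataset(m, np.array(["a"] * 3 + ["b"] * 3), ["x", "y"])
        out = data.impute_missing()
        assert not np.isnan(out.matrix).any()


class TestLdaCv:
    def test_separable_classes_perfect_accuracy(self, rng):
        data = gaussian_dataset(rng)
        report = lda_cv(data, k_folds=6, seed=0)
        assert report.accuracy_mean == 100.0
        assert len(report.fold_accuracies) == 6

    def test_shuffled_labels_give_chance_accuracy(self, rng):
        data = gaussian_dataset(rng, separation=10.0)
        accs = []
        for s in range(20):
            labels = data.labels.copy()
            rng.shuffle(labels)
            shuffled = LabelledDataset(data.matrix, labels, data.feature_names)
            accs.append(lda_cv(shuffled, k_folds=6, seed=s).accuracy_mean)
        assert abs(np.mean(accs) - 50.0) < 10.0

    def test_class_smaller_than_folds_named_in_error(self):
        data = LabelledDataset(
            matrix=np.random.default_rng(0).random((10, 3)),
            labels=np.array(["big"] * 8 + ["tiny"] * 2),
            feature_names=["a", "b", "c"],
        )
        with pytest.raises(ValueError, match="tiny"):
            lda_cv(data, k_folds=6)

    def test_stratification_proportions(self, rng):
        from sklearn.model_selection import StratifiedKFold

        labels = np.array(["a"] * 30 + ["b"] * 60)
        skf = StratifiedKFold(n_splits=6, shuffle=True, random_state=0)
        for _, test in skf.split(np.zeros((90, 1)), labels):
            frac = np.mean(labels[test] == "a")
            assert abs(frac * len(test) - len(test) / 3) <= 1.0

    def test_deterministic_given_seed(self, rng):
        data = gaussian_dataset(rng, separation=2.0)
        a = lda_cv(data, k_folds=6, seed=4)
        b = lda_cv(data, k_folds=6, seed=4)
        assert a.fold_accuracies == b.fold_accuracies
        np.testing.assert_array_equal(a.projection["ld1"], b.projection["ld1"])

    def test_leakage_canary(self, rng):
        """A canary feature that equals the label on ONE fold's test rows
        (pure noise everywhere else) must not lift that fold above chance: a
        fit that never sees its own test rows cannot learn the canary."""
        n = 120
        labels = np.array(["normal", "carcinoma"] * (n // 2))
        noise = rng.normal(0, 1, (n, 4))
        canary = rng.normal(0, 1, n)
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=6, shuffle=True, random_state=0)
        _, planted_test = next(iter(skf.split(noise, labels)))
        canary[planted_test] = (labels[planted_test] == "carcinoma").astype(float)
        data = LabelledDataset(
            np.column_stack([noise, canary]),
            labels,
            ["n1", "n2", "n3", "n4", "canary"],
        )
        report = lda_cv(data, k_folds=6, seed=0)
        # chance is 50%; a model or preprocessing fitted on test-fold data
        # would learn canary == label and score ~100% on the planted fold
        assert report.accuracy_mean < 65.0

    def test_preprocessing_fitted_on_training_folds_only(self, rng, monkeypatch):
        """Spy on the Gaussianizer: inside CV it must only ever be fitted on
        training-fold row counts, never the full cohort (the one full-cohort
        fit is the plotting projection, after scoring)."""
        from fibrekit import stats_classify as sc

        fit_sizes = []
        orig_fit = sc._Gaussianizer.fit

        def spy(self, x):
            fit_sizes.append(len(x))
            return orig_fit(self, x)

        monkeypatch.setattr(sc._Gaussianizer, "fit", spy)
        data = gaussian_dataset(rng, n_per_class=30)
        lda_cv(data, k_folds=6, seed=0)
        per_fold = fit_sizes[:-1]  # last fit is the full-cohort projection
        assert all(size == 50 for size in per_fold)  # 60 samples, 6 folds

    def test_binary_regrouping_on_four_classes(self, rng):
        n = 30
        centers = {"normal": 0.0, "insitu": 6.0, "mixed": 9.0, "solid": 12.0}
        mats, labels = [], []
        for lbl, c in centers.items():
            mats.append(rng.normal(c, 1.0, (n, 4)))
            labels += [lbl] * n
        data = LabelledDataset(np.vstack(mats), np.array(labels), list("abcd"))
        report = lda_cv(data, k_folds=6, seed=0, normal_label="normal")
        # carcinoma subtypes may confuse each other, but normal-vs-rest is easy
        assert report.binary_mean >= report.accuracy_mean
        assert report.binary_refit_mean > 90.0
        assert report.confusion.to_numpy().sum() == 4 * n


class TestRfecv:
    def test_noise_features_eliminated_first(self, rng):
        n = 60
        informative = np.vstack(
            [rng.normal(0, 1, (n, 2)), rng.normal(8, 1, (n, 2))]
        )
        noise = rng.normal(0, 1, (2 * n, 8))
        data = LabelledDataset(
            np.hstack([informative, noise]),
            np.array(["a"] * n + ["b"] * n),
            [f"inf{i}" for i in range(2)] + [f"noise{i}" for i in range(8)],
        )
        curve = rfecv(data, k_folds=5, seed=0)
        assert len(curve) == 10  # one entry per feature count, down to 1
        assert curve["n_features"].tolist() == list(range(10, 0, -1))
        # plateau reached at <= 5 features
        small = curve[curve["n_features"] <= 5]["cv_score_mean"].max()
        assert small >= curve["cv_score_mean"].max() - 2.0

    def test_single_feature_rejected(self, rng):
        data = LabelledDataset(
            rng.random((20, 1)), np.array(["a", "b"] * 10), ["only"]
        )
        with pytest.raises(ValueError):
            rfecv(data)


class TestAnova:
    def two_group_data(self, a_vals, b_vals):
        return LabelledDataset(
            matrix=np.concatenate([a_vals, b_vals])[:, None],
            labels=np.array(["a"] * len(a_vals) + ["b"] * len(b_vals)),
            feature_names=["m"],
        )

    def test_identical_groups_no_stars(self, rng):
        vals = rng.normal(0, 1, 20)
        data = self.two_group_data(vals, vals)
        out = anova_stars(data, "a", "b")
        assert out.loc["m", "F"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["m", "stars"] == ""

    def test_strong_separation_three_stars(self, rng):
        data = self.two_group_data(rng.normal(0, 1, 30), rng.normal(5, 1, 30))
        out = anova_stars(data, "a", "b")
        assert out.loc["m", "p"] < 1e-10
        assert out.loc["m", "stars"] == "***"

    def test_f_equals_t_squared(self, rng):
        """Two-group one-way ANOVA F must equal the squared pooled-variance
        two-sample t statistic."""
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.8, 1.2, 30)
        data = self.two_group_data(a, b)
        f_val = anova_stars(data, "a", "b").loc["m", "F"]
        t_val, _ = stats.ttest_ind(a, b)
        assert f_val == pytest.approx(t_val**2, rel=1e-9)

    def test_constant_equal_groups_p_one(self):
        data = self.two_group_data(np.ones(5), np.ones(5))
        out = anova_stars(data, "a", "b")
        assert out.loc["m", "p"] == 1.0

    @pytest.mark.parametrize(
        "p,expected",
        [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.2, "")],
    )
    def test_star_thresholds(self, p, expected):
        assert significance_stars(p) == expected
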