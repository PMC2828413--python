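import numpy as np
import pandas as pd
import pytest

from anchorsig import classify
from anchorsig.classify import (
    EmptySelectionError,
    confusion_metrics,
    fit,
    loocv,
    metrics_table,
    predict,
    predict_posterior,
    select_features,
)
from anchorsig.simulate import SimulationConfig, simulate_cohort

from conftest import make_matrix, random_matrix

CLASSES = ("c1", "c2")


def _labels(ids, n_first):
    return pd.Series(
        [CLASSES[0] if i < n_first else CLASSES[1] for i in range(len(ids))], index=ids
    )


@pytest.fixture
def separable(rng):
    """One perfectly separating feature among pure noise, n = 10 per class."""
    n = 20
    noise = rng.normal(size=(19, n))
    signal = np.r_[np.zeros(10), np.ones(10) * 4] + rng.normal(0, 0.1, n)
    m = make_matrix(np.vstack([signal, noise]), feature_ids=["sig"] + [f"n{i}" for i in range(19)])
    return m, _labels(m.sample_ids, 10)


class TestSelectFeatures:
    def test_separating_feature_found(self, separable):
        m, labels = separable
        feats, t = select_features(m, labels, alpha=0.001, classes=CLASSES)
        assert feats[0] == "sig"
        assert t.loc["sig"] < 0  # class1 mean is lower

    def test_alpha_one_selects_everything(self, separable):
        m, labels = separable
        feats, _ = select_features(m, labels, alpha=1.0, classes=CLASSES)
        assert len(feats) == 20

    def test_empty_selection_raises(self, rng):
        m = random_matrix(rng, 5, 12)
        with pytest.raises(EmptySelectionError):
            select_features(m, _labels(m.sample_ids, 6), alpha=1e-12)

    def test_permuted_labels_select_at_type_one_rate(self, rng):
        n_hits = 0
        n_tests = 0
        alpha = 0.01
        for _ in range(30):
            m = random_matrix(rng, 200, 40)
            labels = _labels(m.sample_ids, 20)
            labels[:] = rng.permutation(labels.to_numpy())
            try:
                feats, _ = select_features(m, labels, alpha=alpha, classes=CLASSES)
                n_hits += len(feats)
            except EmptySelectionError:
                pass
            n_tests += 200
        rate = n_hits / n_tests
        se = np.sqrt(alpha * (1 - alpha) / n_tests)
        assert abs(rate - alpha) < 4 * se


class TestFitPredict:
    def test_ccp_weighted_sum_example(self):
        # weights t = (2, -1): sample (1, 1) scores 2 - 1 = 1
        model = classify.ClassifierModel(
            "ccp",
            CLASSES,
            ["a", "b"],
            params=dict(t=np.array([2.0, -1.0]), mean_c=(3.0, -3.0), threshold=0.0),
        )
        test = make_matrix([[1.0], [1.0]], feature_ids=["a", "b"], sample_ids=["x"])
        c = classify._compound_scores(model.params["t"], test.values)
        assert c[0] == pytest.approx(1.0)
        assert predict(model, test).iloc[0] == "c1"  # 1 > threshold 0, class1 mean higher

    def test_ccp_symmetric_classes_threshold_zero(self):
        # class2 mirrors class1 -> compound covariate means are opposite
        m = make_matrix([[1.0, 2.0, -1.0, -2.0], [0.5, 1.5, -0.5, -1.5]], feature_ids=["a", "b"])
        labels = _labels(m.sample_ids, 2)
        model = fit("ccp", m, labels, ["a", "b"], classes=CLASSES)
        assert model.params["threshold"] == pytest.approx(0.0, abs=1e-9)

    def test_ccp_and_bcc_share_compound_covariate(self, separable):
        m, labels = separable
        feats, _ = select_features(m, labels, classes=CLASSES)
        ccp = fit("ccp", m, labels, feats, classes=CLASSES)
        bcc = fit("bcc", m, labels, feats, classes=CLASSES)
        np.testing.assert_allclose(ccp.params["t"], bcc.params["t"], atol=0)
        assert ccp.params["mean_c"] == bcc.params["mean_c"]

    def test_dlda_squared_distance_example(self):
        # one feature, class means 0 and 4, pooled var 1: x=1 -> d1=1 < d2=9
        m = make_matrix([[-1.0, 1.0, 3.0, 5.0]], feature_ids=["g"])
        labels = _labels(m.sample_ids, 2)
        model = fit("dlda", m, labels, ["g"], classes=CLASSES)
        test = make_matrix([[1.0]], feature_ids=["g"], sample_ids=["t"])
        assert predict(model, test).iloc[0] == "c1"

    def test_nc_euclidean_example(self):
        # centroids (0,0) and (4,4): x=(1,1) is closer to the first
        m = make_matrix(
            [[-1.0, 1.0, 3.0, 5.0], [1.0, -1.0, 5.0, 3.0]], feature_ids=["a", "b"]
        )
        labels = _labels(m.sample_ids, 2)
        model = fit("nc", m, labels, ["a", "b"], classes=CLASSES)
        np.testing.assert_allclose(model.params["centroids"][0], [0.0, 0.0])
        np.testing.assert_allclose(model.params["centroids"][1], [4.0, 4.0])
        test = make_matrix([[1.0], [1.0]], feature_ids=["a", "b"], sample_ids=["t"])
        assert predict(model, test).iloc[0] == "c1"

    def test_dlda_equals_nc_under_equal_variances(self, rng):
        """With equal pooled variances the DLDA rule reduces to nearest centroid."""
        base = rng.normal(size=(6, 16))
        base[:, 8:] += 1.5
        # force every feature to share the same pooled within-class variance
        X = base.copy()
        for i in range(6):
            for half in (slice(0, 8), slice(8, 16)):
                col = X[i, half]
                X[i, half] = (col - col.mean()) / col.std(ddof=0) + col.mean()
        m = make_matrix(X)
        labels = _labels(m.sample_ids, 8)
        feats = m.feature_ids
        dlda = fit("dlda", m, labels, feats, classes=CLASSES)
        nc = fit("nc", m, labels, feats, classes=CLASSES)
        test = random_matrix(rng, 6, 30)
        pd.testing.assert_series_equal(predict(dlda, test), predict(nc, test))

    def test_svm_separable_training_errors_zero(self):
        m = make_matrix([[-2.0, -1.5, -1.0, 1.0, 1.5, 2.0]], feature_ids=["g"])
        labels = _labels(m.sample_ids, 3)
        model = fit("svm", m, labels, ["g"], classes=CLASSES)
        pd.testing.assert_series_equal(
            predict(model, m), labels.rename("predicted"), check_names=False
        )

    def test_bcc_equal_class_means_posterior_half_tie_to_class1(self):
        # degenerate Gaussian classes with identical means: posterior is 0.5
        # everywhere and the tie resolves to class1
        model = classify.ClassifierModel(
            "bcc", CLASSES, ["a"], params=dict(t=np.array([1.0]), mean_c=(1.0, 1.0), var_c=1.0)
        )
        test = make_matrix(np.random.default_rng(0).normal(size=(1, 5)), feature_ids=["a"])
        post = predict_posterior(model, test)
        np.testing.assert_allclose(post, 0.5, atol=1e-12)
        assert (predict(model, test) == "c1").all()

    def test_bcc_zero_pooled_variance_rejected(self):
        # the two features cancel: c = t*(a+b) is constant within each class
        m = make_matrix([[0.0, 1.0, 3.0, 4.0], [1.0, 0.0, 4.0, 3.0]], feature_ids=["a", "b"])
        labels = _labels(m.sample_ids, 2)
        with pytest.raises(ValueError, match="pooled variance"):
            fit("bcc", m, labels, ["a", "b"], classes=CLASSES)

    def test_missing_features_listed(self, separable):
        m, labels = separable
        model = fit("nc", m, labels, ["sig", "n0"], classes=CLASSES)
        test = make_matrix([[1.0]], feature_ids=["sig"], sample_ids=["t"])
        with pytest.raises(KeyError, match="n0"):
            predict(model, test)

    @pytest.mark.parametrize("method", classify.METHODS)
    def test_label_symmetry(self, method, separable):
        """Training with swapped class labels swaps every prediction."""
        m, labels = separable
        feats, _ = select_features(m, labels, classes=CLASSES)
        swapped = labels.map({CLASSES[0]: CLASSES[1], CLASSES[1]: CLASSES[0]})
        mod = fit(method, m, labels, feats, classes=CLASSES)
        mod_sw = fit(method, m, swapped, feats, classes=(CLASSES[1], CLASSES[0]))
        p = predict(mod, m)
        p_sw = predict(mod_sw, m)
        assert (p != p_sw).all()


class TestLOOCV:
    def test_separable_data_perfect_accuracy(self, separable):
        m, labels = separable
        for method in classify.METHODS:
            cv = loocv(method, m, labels, alpha=0.001, classes=CLASSES)
            assert cv.accuracy == 1.0

    def test_null_labels_accuracy_near_majority_rate(self, rng):
        m = random_matrix(rng, 100, 30)
        labels = _labels(m.sample_ids, 18)  # majority rate 0.6
        cv = loocv("nc", m, labels, alpha=0.05, classes=CLASSES)
        assert cv.accuracy < 0.85  # no signal: nothing close to separable

    def test_class_minimum_enforced(self, rng):
        m = random_matrix(rng, 5, 8)
        with pytest.raises(ValueError, match="3 samples"):
            loocv("nc", m, _labels(m.sample_ids, 2), classes=CLASSES)

    @pytest.mark.parametrize("method", classify.METHODS)
    def test_held_out_sample_cannot_leak(self, method, rng):
        """Perturbing the held-out sample leaves its fold's model untouched."""
        cfg = SimulationConfig(n_samples=16, n_features=120, n_module_features=30, seed=9)
        cohort = simulate_cohort(cfg)
        labels = cohort.true_labels
        m = cohort.expression
        cv = loocv(method, m, labels, alpha=0.01, classes=("HSC", "LSC"), store_models=True)
        for s in list(labels.index)[:4]:
            corrupted = m.data.copy()
            corrupted[s] = rng.normal(0, 50, size=len(m.feature_ids))
            cv2 = loocv(
                method,
                type(m)(corrupted),
                labels,
                alpha=0.01,
                classes=("HSC", "LSC"),
                store_models=True,
            )
            a, b = cv.fold_models[s], cv2.fold_models[s]
            assert a.features == b.features
            for key, val in a.params.items():
                np.testing.assert_array_equal(
                    np.asarray(val, dtype=float), np.asarray(b.params[key], dtype=float)
                )


class TestConfusionMetrics:
    def test_published_style_counts(self):
        # TP=48 FN=2 TN=51 FP=2 -> sens 0.96, spec 51/53, PPV 0.96, NPV 51/53
        truth = pd.Series(["P"] * 50 + ["N"] * 53)
        pred = pd.Series(["P"] * 48 + ["N"] * 2 + ["P"] * 2 + ["N"] * 51)
        out = confusion_metrics(truth, pred, ("P", "N"))
        assert out.loc["P", "Sensitivity"] == pytest.approx(0.96)
        assert out.loc["P", "Specificity"] == pytest.approx(51 / 53)
        assert out.loc["P", "PPV"] == pytest.approx(0.96)
        assert out.loc["P", "NPV"] == pytest.approx(51 / 53)
        # two-class duality: sensitivity of one class is specificity of the other
        assert out.loc["N", "Sensitivity"] == out.loc["P", "Specificity"]

    def test_balanced_counts_give_half(self):
        truth = pd.Series(["P", "P", "N", "N"])
        pred = pd.Series(["P", "N", "P", "N"])
        out = confusion_metrics(truth, pred, ("P", "N"))
        assert (out.to_numpy() == 0.5).all()

    def test_undefined_ppv_reported_missing(self):
        truth = pd.Series(["P", "N"])
        pred = pd.Series(["N", "N"])  # nothing predicted positive
        out = confusion_metrics(truth, pred, ("P", "N"))
        assert np.isnan(out.loc["P", "PPV"])

    def test_perfect_precision(self):
        truth = pd.Series(["P", "P", "N"])
        pred = pd.Series(["P", "N", "N"])
        assert confusion_metrics(truth, pred, ("P", "N")).loc["P", "PPV"] == 1.0

    def test_metrics_table_has_one_block_per_method(self):
        truth = pd.Series(["P", "P", "N", "N"])
        pred = pd.Series(["P", "P", "N", "N"])
        tbl = metrics_table({m: (truth, pred, ("P", "N")) for m in classify.METHODS})
        assert list(tbl.index.get_level_values("Method").unique()) == [
            m.upper() for m in classify.METHODS
        ]
        assert tbl.shape == (10, 4)
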