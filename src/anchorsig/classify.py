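"""Two-class expression classifiers with in-fold gene selection and LOOCV.

Implements the five classical class-prediction statistics used for
signature validation:

* **CCP** — compound covariate predictor: per-sample score
  ``c_j = sum_i t_i x_ij`` over the selected genes, with t the two-sample
  t statistics from the selection step; classify by the midpoint of the two
  class means of c.
* **BCC** — Bayesian compound covariate: the same score with Gaussian
  class-conditional densities (class means of c, pooled variance) and equal
  priors; classification by posterior probability.
* **DLDA** — diagonal linear discriminant analysis: per-feature class means
  and pooled within-class variances; classify by minimal standardized
  squared distance.
* **NC** — nearest centroid in plain Euclidean geometry.
* **SVM** — linear soft-margin support vector machine (hinge loss, C = 1).

Gene selection is a pooled-variance two-sample t-test at p < alpha, and in
leave-one-out cross-validation the entire procedure — selection included —
is repeated in every fold, so the held-out sample never influences its own
fold's model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .io import ExpressionMatrix
from .screen import two_group_ttest

__all__ = [
    "METHODS",
    "ClassifierModel",
    "CVResult",
    "select_features",
    "fit",
    "predict",
    "predict_posterior",
    "loocv",
    "confusion_counts",
    "confusion_metrics",
    "metrics_table",
]

METHODS = ("ccp", "bcc", "dlda", "nc", "svm")


class EmptySelectionError(ValueError):
    """No feature passed the selection threshold; raise alpha or accept a failed fold."""


def select_features(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    alpha: float = 0.001,
    classes: tuple | None = None,
):
    """Select differentially expressed features on the training samples.

    Returns ``(ordered_features, t_stats)`` where features with p < alpha are
    ordered by ascending p, ties by descending |t|, then identifier.

    Raises
    ------
    EmptySelectionError
        If no feature passes; callers running LOOCV record the fold as failed.
    """
    train = matrix.subset_samples(list(labels.index))
    tt = two_group_ttest(train, labels, classes=classes)
    hits = tt[tt["p"] < alpha].copy()
    if hits.empty:
        raise EmptySelectionError(
            f"no feature with p < {alpha}; increase alpha or treat this fold as uninformative"
        )
    hits["_abst"] = -hits["t"].abs()
    hits["_id"] = hits.index.astype(str)
    hits = hits.sort_values(["p", "_abst", "_id"], kind="mergesort")
    return list(hits.index), hits["t"]


@dataclass
class ClassifierModel:
    """A fitted two-class model over a fixed ordered feature set.

    ``classes = (class1, class2)``; every tie rule resolves to class1.
    ``params`` holds the method-specific fitted quantities.
    """

    method: str
    classes: tuple
    features: list
    params: dict = field(default_factory=dict)


def _training_arrays(matrix, labels, features, classes):
    X = matrix.subset_features(features).data[list(labels.index)].to_numpy(dtype=float)
    y1 = (labels == classes[0]).to_numpy()
    if y1.sum() == 0 or (~y1).sum() == 0:
        raise ValueError("both classes must be present in the training labels")
    return X, y1


def _compound_scores(t: np.ndarray, X: np.ndarray) -> np.ndarray:
    return t @ X


def fit(
    method: str,
    matrix: ExpressionMatrix,
    labels: pd.Series,
    features,
    classes: tuple | None = None,
) -> ClassifierModel:
    """Fit one of the five classifiers on the labelled training samples."""
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if len(features) == 0:
        raise ValueError("feature set must be non-empty")
    if classes is None:
        classes = tuple(sorted(pd.unique(labels)))
    X, y1 = _training_arrays(matrix, labels, list(features), classes)
    n1, n2 = int(y1.sum()), int((~y1).sum())
    params: dict = {}

    if method in ("ccp", "bcc"):
        train = matrix.subset_features(list(features)).subset_samples(list(labels.index))
        t = two_group_ttest(train, labels, classes=classes)["t"].to_numpy(dtype=float)
        if not np.isfinite(t).all():
            raise ValueError("non-finite t statistic among selected features")
        c = _compound_scores(t, X)
        mu1, mu2 = c[y1].mean(), c[~y1].mean()
        params.update(t=t, mean_c=(mu1, mu2))
        if method == "ccp":
            params["threshold"] = 0.5 * (mu1 + mu2)
        else:
            ss = ((c[y1] - mu1) ** 2).sum() + ((c[~y1] - mu2) ** 2).sum()
            pooled = ss / (n1 + n2 - 2)
            if pooled == 0:
                raise ValueError("BCC: pooled variance of the compound covariate is zero")
            params["var_c"] = pooled
    elif method == "dlda":
        m1, m2 = X[:, y1].mean(axis=1), X[:, ~y1].mean(axis=1)
        ss = ((X[:, y1] - m1[:, None]) ** 2).sum(axis=1) + (
            (X[:, ~y1] - m2[:, None]) ** 2
        ).sum(axis=1)
        var = ss / (n1 + n2 - 2)
        keep = var > 0
        if not keep.all():
            dropped = [f for f, k in zip(features, keep) if not k]
            warnings.warn(f"DLDA: dropping zero-variance feature(s): {dropped[:10]}")
            if not keep.any():
                raise ValueError("DLDA: all selected features have zero pooled variance")
        features = [f for f, k in zip(features, keep) if k]
        params.update(means=(m1[keep], m2[keep]), var=var[keep])
    elif method == "nc":
        params["centroids"] = (X[:, y1].mean(axis=1), X[:, ~y1].mean(axis=1))
    elif method == "svm":
        y_num = np.where(y1, 1, -1)
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(X.T, y_num)
        params.update(w=clf.coef_.ravel().copy(), b=float(clf.intercept_[0]))
    return ClassifierModel(method=method, classes=classes, features=list(features), params=params)


def _test_array(model: ClassifierModel, matrix: ExpressionMatrix) -> np.ndarray:
    missing = [f for f in model.features if f not in matrix.data.index]
    if missing:
        raise KeyError(f"matrix lacks model feature(s): {missing[:10]}")
    return matrix.data.loc[model.features].to_numpy(dtype=float)


def predict(model: ClassifierModel, matrix: ExpressionMatrix) -> pd.Series:
    """Predict a class label for every sample in the matrix.

    Every exact tie (threshold hit, equal posterior, equal distance, zero SVM
    margin) resolves deterministically to class1.
    """
    X = _test_array(model, matrix)
    c1, c2 = model.classes
    p = model.params
    if model.method == "ccp":
        c = _compound_scores(p["t"], X)
        mu1, mu2 = p["mean_c"]
        thr = p["threshold"]
        if mu1 > mu2:
            pick1 = c > thr  # a score exactly at the threshold -> lower-mean class2
        elif mu1 < mu2:
            pick1 = c <= thr  # threshold ties go to the lower-mean class, class1
        else:
            pick1 = np.ones_like(c, dtype=bool)  # degenerate: default class1
    elif model.method == "bcc":
        post = _bcc_posterior(model, X)
        pick1 = post >= 0.5
    elif model.method == "dlda":
        m1, m2 = p["means"]
        var = p["var"]
        d1 = (((X - m1[:, None]) ** 2) / var[:, None]).sum(axis=0)
        d2 = (((X - m2[:, None]) ** 2) / var[:, None]).sum(axis=0)
        pick1 = d1 <= d2
    elif model.method == "nc":
        m1, m2 = p["centroids"]
        d1 = ((X - m1[:, None]) ** 2).sum(axis=0)
        d2 = ((X - m2[:, None]) ** 2).sum(axis=0)
        pick1 = d1 <= d2
    else:  # svm
        score = p["w"] @ X + p["b"]
        pick1 = score >= 0
    labels = np.where(pick1, c1, c2)
    return pd.Series(labels, index=matrix.sample_ids, name="predicted")


def _bcc_posterior(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    p = model.params
    c = _compound_scores(p["t"], X)
    mu1, mu2 = p["mean_c"]
    var = p["var_c"]
    # equal priors; shared variance cancels up to the two exponents
    log1 = -0.5 * (c - mu1) ** 2 / var
    log2 = -0.5 * (c - mu2) ** 2 / var
    m = np.maximum(log1, log2)
    e1, e2 = np.exp(log1 - m), np.exp(log2 - m)
    return e1 / (e1 + e2)


def predict_posterior(model: ClassifierModel, matrix: ExpressionMatrix) -> pd.Series:
    """Posterior probability of class1 (BCC only)."""
    if model.method != "bcc":
        raise ValueError("posterior probabilities are defined for the BCC model only")
    X = _test_array(model, matrix)
    return pd.Series(_bcc_posterior(model, X), index=matrix.sample_ids, name="posterior_class1")


# ---------------------------------------------------------------------------
# Cross-validation and reporting
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Leave-one-out cross-validation outcome for one method."""

    method: str
    classes: tuple
    truth: pd.Series
    predicted: pd.Series
    n_features_per_fold: pd.Series
    failed_folds: list
    fold_models: dict | None = None

    @property
    def accuracy(self) -> float:
        return float((self.truth == self.predicted).mean())

    def confusion(self, positive) -> dict:
        return confusion_counts(self.truth, self.predicted, positive)

    def metrics(self) -> pd.DataFrame:
        return confusion_metrics(self.truth, self.predicted, self.classes)


def loocv(
    method: str,
    matrix: ExpressionMatrix,
    labels: pd.Series,
    alpha: float = 0.001,
    classes: tuple | None = None,
    store_models: bool = False,
) -> CVResult:
    """Leave-one-out cross-validation with gene selection repeated per fold.

    Each fold removes one sample, reruns :func:`select_features` and
    :func:`fit` on the remainder, and predicts the held-out sample.  A fold
    whose selection comes up empty is recorded as failed and predicted as the
    training majority class.
    """
    if classes is None:
        classes = tuple(sorted(pd.unique(labels)))
    samples = list(labels.index)
    n = len(samples)
    if n < 6:
        raise ValueError("LOOCV needs at least 6 samples")
    counts = labels.value_counts()
    if (counts < 3).any():
        raise ValueError("LOOCV needs at least 3 samples per class")

    preds = {}
    nfeat = {}
    failed = []
    models = {} if store_models else None
    full = matrix.subset_samples(samples)
    for s in samples:
        train_labels = labels.drop(index=s)
        if train_labels.value_counts().min() < 2:
            raise ValueError(f"class collapse in fold holding out {s!r}")
        train = full.subset_samples(list(train_labels.index))
        try:
            feats, _ = select_features(train, train_labels, alpha=alpha, classes=classes)
        except EmptySelectionError:
            failed.append(s)
            nfeat[s] = 0
            preds[s] = train_labels.value_counts().idxmax()
            if store_models:
                models[s] = None
            continue
        model = fit(method, train, train_labels, feats, classes=classes)
        nfeat[s] = len(model.features)
        preds[s] = predict(model, full.subset_samples([s])).iloc[0]
        if store_models:
            models[s] = model
    return CVResult(
        method=method,
        classes=classes,
        truth=labels.copy(),
        predicted=pd.Series(preds, name="predicted").loc[samples],
        n_features_per_fold=pd.Series(nfeat, name="n_features").loc[samples],
        failed_folds=failed,
        fold_models=models,
    )


def confusion_counts(truth: pd.Series, predicted: pd.Series, positive) -> dict:
    """TP/FP/TN/FN treating ``positive`` as the positive class."""
    truth, predicted = truth.align(predicted, join="inner")
    tpos = truth == positive
    ppos = predicted == positive
    return {
        "TP": int((tpos & ppos).sum()),
        "FP": int((~tpos & ppos).sum()),
        "TN": int((~tpos & ~ppos).sum()),
        "FN": int((tpos & ~ppos).sum()),
    }


def _safe_ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(truth: pd.Series, predicted: pd.Series, classes) -> pd.DataFrame:
    """Sensitivity / specificity / PPV / NPV with each class as positive.

    Undefined ratios (empty denominator) are reported as NaN, never as 0.
    """
    rows = {}
    for cls in classes:
        c = confusion_counts(truth, predicted, cls)
        rows[cls] = {
            "Sensitivity": _safe_ratio(c["TP"], c["TP"] + c["FN"]),
            "Specificity": _safe_ratio(c["TN"], c["TN"] + c["FP"]),
            "PPV": _safe_ratio(c["TP"], c["TP"] + c["FP"]),
            "NPV": _safe_ratio(c["TN"], c["TN"] + c["FN"]),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "Class"
    return out


def metrics_table(results: dict) -> pd.DataFrame:
    """Stack per-method confusion metrics into one report table.

    ``results`` maps a method name to either a :class:`CVResult` or a
    ``(truth, predicted, classes)`` triple; the output has a (method, class)
    MultiIndex and the four standard columns.
    """
    blocks = []
    for method, res in results.items():
        if isinstance(res, CVResult):
            tbl = res.metrics()
        else:
            truth, predicted, classes = res
            tbl = confusion_metrics(truth, predicted, classes)
        tbl = tbl.copy()
        tbl.index = pd.MultiIndex.from_product(
            [[method.upper()], tbl.index], names=["Method", "Class"]
        )
        blocks.append(tbl)
    return pd.concat(blocks)
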