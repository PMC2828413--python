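"""Anchor-gene dichotomization, correlation screening, and two-group t-tests.

The screen follows the classical anchor-signature recipe: dichotomize the
cohort at the anchor gene's median, then select every feature whose Pearson
correlation with the anchor passes both a significance threshold (two-sided
p < alpha from the t transform of r) and an effect-size threshold
(|r| > r_threshold).  The anchor itself is excluded from screening but is
always part of the resulting signature feature list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

__all__ = [
    "median_dichotomize",
    "pearson_screen",
    "two_group_ttest",
    "CorrelationScreenResult",
]

logger = logging.getLogger(__name__)


def median_dichotomize(matrix: ExpressionMatrix, anchor_id) -> pd.Series:
    """Split samples at the median anchor expression.

    Samples strictly above the median are labelled ``"high"``; samples at or
    below the median are labelled ``"low"``.  With an odd number of samples
    the median sample therefore joins the low group (52/51 at n = 103).
    """
    anchor = matrix.feature(anchor_id)
    if len(anchor) < 2:
        raise ValueError("median_dichotomize needs at least 2 samples")
    if anchor.nunique() == 1:
        raise ValueError(f"anchor {anchor_id!r} is constant; dichotomy is degenerate")
    med = float(anchor.median())
    labels = pd.Series(
        np.where(anchor.to_numpy() > med, "high", "low"),
        index=anchor.index,
        name="label",
    )
    return labels


@dataclass
class CorrelationScreenResult:
    """Per-feature anchor correlations and the selected signature.

    ``table`` has one row per screened (non-anchor, non-constant) feature with
    columns ``r``, ``p`` and ``selected``.  ``selected`` features satisfy
    ``p < alpha`` and ``|r| > r_threshold``; ``signature_features`` prepends
    the anchor.
    """

    anchor_id: object
    table: pd.DataFrame
    alpha: float
    r_threshold: float
    n_samples: int
    n_zero_variance: int = 0

    @property
    def selected(self) -> list:
        return list(self.table.index[self.table["selected"]])

    @property
    def signature_features(self) -> list:
        return [self.anchor_id] + self.selected

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def pearson_screen(
    matrix: ExpressionMatrix,
    anchor_id,
    alpha: float = 0.001,
    r_threshold: float = 0.3,
) -> CorrelationScreenResult:
    """Screen all non-anchor features for correlation with the anchor.

    For each feature, r is the Pearson correlation with the anchor across all
    samples and p is the two-sided p-value from ``t = r sqrt((n-2)/(1-r^2))``
    on n-2 degrees of freedom.  Constant (zero-variance) features have no
    defined correlation and are excluded, with the count logged and recorded.
    """
    n = len(matrix.sample_ids)
    if n < 4:
        raise ValueError("pearson_screen needs at least 4 samples (n-2 >= 2 df)")
    anchor = matrix.feature(anchor_id).to_numpy(dtype=float)
    if np.ptp(anchor) == 0:
        raise ValueError(f"anchor {anchor_id!r} is constant")

    others = matrix.data.drop(index=anchor_id)
    X = others.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    ac = anchor - anchor.mean()
    x_ss = (Xc**2).sum(axis=1)
    nonconstant = x_ss > 0
    n_zero_var = int((~nonconstant).sum())
    if n_zero_var:
        logger.info("pearson_screen: excluded %d zero-variance feature(s)", n_zero_var)

    Xc = Xc[nonconstant]
    x_ss = x_ss[nonconstant]
    r = (Xc @ ac) / np.sqrt(x_ss * (ac**2).sum())
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)

    table = pd.DataFrame(
        {"r": r, "p": p, "selected": (p < alpha) & (np.abs(r) > r_threshold)},
        index=others.index[nonconstant],
    )
    return CorrelationScreenResult(
        anchor_id=anchor_id,
        table=table,
        alpha=alpha,
        r_threshold=r_threshold,
        n_samples=n,
        n_zero_variance=n_zero_var,
    )


def two_group_ttest(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    classes: tuple | None = None,
) -> pd.DataFrame:
    """Pooled-variance two-sample t-test per feature.

    Parameters
    ----------
    labels
        Per-sample group label covering a subset of the matrix samples; the
        test runs on exactly the labelled samples.
    classes
        Pair fixing the sign convention, ``t ~ mean(class1) - mean(class2)``.
        Defaults to the sorted pair of observed labels.

    Returns
    -------
    DataFrame indexed by feature with columns ``t``, ``p``, ``mean_diff`` and
    ``zero_var`` (True where the pooled variance vanished).  Zero pooled
    variance with equal means gives t = 0, p = 1; with unequal means it gives
    p = 0 and the ``zero_var`` flag marks the degenerate call.
    """
    labels = labels.dropna()
    observed = pd.unique(labels)
    if classes is None:
        classes = tuple(sorted(observed))
    if len(classes) != 2 or set(observed) - set(classes):
        raise ValueError(f"labels must take exactly the two classes {classes}")
    g1 = labels.index[labels == classes[0]]
    g2 = labels.index[labels == classes[1]]
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 samples")

    X1 = matrix.data[list(g1)].to_numpy(dtype=float)
    X2 = matrix.data[list(g2)].to_numpy(dtype=float)
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    ss1 = ((X1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((X2 - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    sp2 = (ss1 + ss2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2

    zero_var = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, 0.0, diff / np.where(zero_var, 1.0, se))
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    # degenerate features: no within-group variance
    sep = zero_var & (diff != 0)
    t = np.where(sep, np.where(diff > 0, np.inf, -np.inf), t)
    p = np.where(sep, 0.0, np.where(zero_var & (diff == 0), 1.0, p))

    return pd.DataFrame(
        {"t": t, "p": p, "mean_diff": diff, "zero_var": zero_var},
        index=matrix.data.index,
    )
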