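"""Model/Results facade for the anchor-gene signature analysis.

:class:`AnchorSignatureModel` bundles the whole derivation — correlation
screen around the anchor gene, Eisen-style clustering of samples on the
signature features, survival statistics for the two clusters, and
cross-validated classifier validation — behind a statsmodels-like
``model.fit() -> results`` interface.  The results object carries every
intermediate artifact (screen table, dendrogram, cluster labels, KM curves,
log-rank and Cox fits, per-classifier LOOCV confusion metrics), can predict
cluster membership for an external cohort, and writes the standard TSV
bundle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify
from .classify import CVResult, loocv, metrics_table, select_features
from .cluster import ClusterAssignment, average_linkage, cut_two, uncentered_correlation_distance
from .io import ClinicalTable, ExpressionMatrix, read_clinical, read_expression
from .screen import CorrelationScreenResult, pearson_screen
from .survival import (
    CoxFit,
    KMCurve,
    LogRankResult,
    build_cox_design,
    cox_fit,
    cox_table,
    km_fit,
    logrank_two_group,
)

__all__ = ["AnchorSignatureModel", "AnchorSignatureResults"]

CLASSES = ("HSC", "LSC")


class AnchorSignatureModel:
    """Anchor-gene signature model over an expression cohort.

    Parameters
    ----------
    expression
        Preprocessed (log2-scale) features x samples matrix.
    clinical
        Optional clinical table covering the same samples; enables the
        survival analyses.
    anchor_id
        Feature whose correlated module defines the signature.
    alpha, r_threshold
        Correlation-screen thresholds (p < alpha and |r| > r_threshold).
    methods
        Classifiers to validate (subset of ``classify.METHODS``).
    cv_alpha
        Gene-selection threshold used inside classification folds
        (defaults to ``alpha``).
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        clinical: ClinicalTable | None = None,
        anchor_id: str = "S100A8",
        alpha: float = 0.001,
        r_threshold: float = 0.3,
        methods: tuple = classify.METHODS,
        cv_alpha: float | None = None,
    ) -> None:
        if anchor_id not in expression.data.index:
            raise KeyError(f"anchor {anchor_id!r} not in expression matrix")
        unknown = set(m.lower() for m in methods) - set(classify.METHODS)
        if unknown:
            raise ValueError(f"unknown method(s) {sorted(unknown)}; choose from {classify.METHODS}")
        if clinical is not None:
            expr_samples = set(expression.sample_ids)
            clin_samples = set(clinical.sample_ids)
            if expr_samples != clin_samples:
                raise ValueError(
                    "expression and clinical tables must cover the same samples "
                    f"({len(expr_samples - clin_samples)} expression-only, "
                    f"{len(clin_samples - expr_samples)} clinical-only)"
                )
        self.expression = expression
        self.clinical = clinical
        self.anchor_id = anchor_id
        self.alpha = alpha
        self.r_threshold = r_threshold
        self.methods = tuple(m.lower() for m in methods)
        self.cv_alpha = alpha if cv_alpha is None else cv_alpha

    @classmethod
    def from_files(cls, expression_path, clinical_path=None, **kwargs) -> "AnchorSignatureModel":
        expr = read_expression(expression_path)
        clin = read_clinical(clinical_path) if clinical_path is not None else None
        return cls(expr, clin, **kwargs)

    def fit(self, run_loocv: bool = True) -> "AnchorSignatureResults":
        """Run the full derivation and return the results bundle."""
        screen = pearson_screen(
            self.expression, self.anchor_id, alpha=self.alpha, r_threshold=self.r_threshold
        )
        signature = self.expression.subset_features(screen.signature_features)
        dist = uncentered_correlation_distance(signature)
        dendrogram = average_linkage(dist)
        clusters = cut_two(dendrogram, self.expression, self.anchor_id)
        labels = clusters.labels

        km_curves: dict[str, KMCurve] = {}
        logrank: LogRankResult | None = None
        cox: CoxFit | None = None
        if self.clinical is not None:
            clin = self.clinical.data
            for cls_ in CLASSES:
                members = labels.index[labels == cls_]
                if len(members):
                    km_curves[cls_] = km_fit(
                        clin.loc[members, "time_months"], clin.loc[members, "event"]
                    )
            logrank = logrank_two_group(
                clin["time_months"], clin["event"], labels.loc[clin.index]
            )
            design = build_cox_design(self.clinical, labels)
            # drop covariates without contrast in this cohort (e.g. a level never drawn)
            keep = [c for c in design.columns if design[c].nunique() > 1]
            cox = cox_fit(clin["time_months"], clin["event"], design[keep])

        cv_results: dict[str, CVResult] = {}
        if run_loocv:
            for method in self.methods:
                cv_results[method] = loocv(
                    method, signature, labels, alpha=self.cv_alpha, classes=CLASSES
                )

        full_models = {}
        feats, _ = select_features(signature, labels, alpha=self.cv_alpha, classes=CLASSES)
        for method in self.methods:
            full_models[method] = classify.fit(method, signature, labels, feats, classes=CLASSES)

        return AnchorSignatureResults(
            model=self,
            screen=screen,
            clusters=clusters,
            km_curves=km_curves,
            logrank=logrank,
            cox=cox,
            cv_results=cv_results,
            full_models=full_models,
        )


@dataclass
class AnchorSignatureResults:
    """Everything the signature derivation produced."""

    model: AnchorSignatureModel
    screen: CorrelationScreenResult
    clusters: ClusterAssignment
    km_curves: dict
    logrank: LogRankResult | None
    cox: CoxFit | None
    cv_results: dict
    full_models: dict

    # -- views -------------------------------------------------------------
    @property
    def signature_features(self) -> list:
        return self.screen.signature_features

    @property
    def labels(self) -> pd.Series:
        return self.clusters.labels

    def cv_metrics(self) -> pd.DataFrame:
        """Per-classifier LOOCV sensitivity/specificity/PPV/NPV table."""
        if not self.cv_results:
            raise ValueError("model was fitted with run_loocv=False")
        return metrics_table(self.cv_results)

    # -- external cohort ---------------------------------------------------
    def predict(self, expression: ExpressionMatrix) -> pd.DataFrame:
        """Predict HSC/LSC for an external cohort with every fitted classifier."""
        out = {}
        for method, mod in self.full_models.items():
            out[method.upper()] = classify.predict(mod, expression)
        return pd.DataFrame(out)

    def validate(self, expression: ExpressionMatrix, reference_labels: pd.Series) -> pd.DataFrame:
        """Confusion metrics of external predictions against reference labels."""
        preds = self.predict(expression)
        results = {
            m: (reference_labels, preds[m.upper()], CLASSES) for m in self.full_models
        }
        return metrics_table(results)

    # -- reporting ---------------------------------------------------------
    def km_frame(self) -> pd.DataFrame:
        frames = []
        for cls_, curve in self.km_curves.items():
            f = curve.to_frame()
            f.insert(0, "group", cls_)
            frames.append(f)
        if not frames:
            return pd.DataFrame(columns=["group", "time", "n_at_risk", "n_events", "survival", "greenwood_var"])
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        """Human-readable run summary."""
        m = self.model
        lines = []
        lines.append("Anchor-gene signature analysis")
        lines.append("=" * 64)
        lines.append(f"Anchor feature:        {m.anchor_id}")
        lines.append(f"Cohort size:           {len(m.expression.sample_ids)} samples, "
                     f"{len(m.expression.feature_ids)} features")
        lines.append(
            f"Correlation screen:    p < {m.alpha:g}, |r| > {m.r_threshold:g} -> "
            f"{len(self.screen.selected)} correlated features"
        )
        counts = self.labels.value_counts()
        lines.append(
            "Clusters:              "
            + ", ".join(f"{c} n={counts.get(c, 0)}" for c in CLASSES)
            + "  (mean anchor "
            + ", ".join(f"{c}={self.clusters.anchor_means[c]:.3f}" for c in CLASSES)
            + ")"
        )
        if self.logrank is not None:
            lines.append(
                f"Log-rank (HSC vs LSC): chi2 = {self.logrank.chi_square:.3f}, "
                f"p = {self.logrank.p:.4g}"
            )
        if self.cox is not None:
            lines.append("")
            lines.append("Multivariate Cox regression (progression)")
            lines.append("-" * 64)
            summ = self.cox.summary()
            lines.append(summ.to_string())
            if not self.cox.converged:
                lines.append(f"  [warning] {self.cox.message}")
        if self.cv_results:
            lines.append("")
            lines.append("Leave-one-out cross-validated class prediction")
            lines.append("-" * 64)
            lines.append(self.cv_metrics().round(3).to_string())
        return "\n".join(lines)

    def plot_km(self, ax=None):
        """Kaplan-Meier step curves per cluster (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for cls_, curve in self.km_curves.items():
            x = np.r_[0.0, np.repeat(curve.event_times, 2)]
            y = np.r_[1.0, 1.0, np.repeat(curve.survival, 2)[:-1]]
            ax.plot(x, y, label=cls_)
        ax.set_xlabel("months")
        ax.set_ylabel("progression-free fraction")
        ax.set_ylim(0, 1.05)
        ax.legend()
        return ax

    # -- persistence -------------------------------------------------------
    def to_bundle(self, outdir) -> dict:
        """Write the standard TSV bundle; returns {name: path}."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        sig = self.screen.to_frame()
        sig.insert(0, "feature_id", sig.index)
        sig.to_csv(outdir / "signature.tsv", sep="\t", index=False, float_format="%.6g")
        paths["signature"] = outdir / "signature.tsv"

        self.clusters.to_frame().to_csv(outdir / "clusters.tsv", sep="\t", index_label="sample_id")
        paths["clusters"] = outdir / "clusters.tsv"

        if self.cv_results:
            self.cv_metrics().to_csv(outdir / "metrics.tsv", sep="\t", float_format="%.6g")
            paths["metrics"] = outdir / "metrics.tsv"
        if self.cox is not None:
            cox_table(self.cox).to_csv(outdir / "cox_table.tsv", sep="\t", index=False, float_format="%.6g")
            paths["cox_table"] = outdir / "cox_table.tsv"
        if self.km_curves:
            self.km_frame().to_csv(outdir / "km_curves.tsv", sep="\t", index=False, float_format="%.6g")
            paths["km_curves"] = outdir / "km_curves.tsv"
        return paths
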