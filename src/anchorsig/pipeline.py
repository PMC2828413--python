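"""Config-driven end-to-end orchestration.

``run_pipeline`` drives the whole analysis — simulate (or load), preprocess,
derive the signature, cluster, validate classifiers, survival statistics —
and writes one TSV report bundle plus a run log.  Every stage is a pure
function of (inputs, config, seed), so an identical config and seed
reproduce the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .classify import METHODS
from .io import read_clinical, read_expression, write_expression
from .model import AnchorSignatureModel
from .preprocess import log2_median_center, quantile_normalize
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Either ``simulate`` holds :class:`SimulationConfig` overrides (synthetic
    mode, optionally with ``test_simulate`` for an independent validation
    cohort) or ``expression_path``/``clinical_path`` point at input TSVs.
    Thresholds default to the standard derivation settings: correlation
    screen at p < 0.001 and |r| > 0.3, in-fold gene selection at p < 0.001,
    median split at the anchor, two clusters from the dendrogram root.
    """

    simulate: dict | None = None
    test_simulate: dict | None = None
    expression_path: str | None = None
    clinical_path: str | None = None
    anchor_id: str = "S100A8"
    alpha: float = 0.001
    r_threshold: float = 0.3
    methods: tuple = METHODS
    run_loocv: bool = True
    quantile_normalize: bool = False
    log2_transform: bool = False
    median_center: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.methods = tuple(m.lower() for m in self.methods)
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")
        if self.simulate is None and self.expression_path is None:
            raise ValueError("config needs either 'simulate' or 'expression_path'")
        if self.simulate is not None and self.expression_path is not None:
            raise ValueError("'simulate' and 'expression_path' are mutually exclusive")
        for path_attr in ("expression_path", "clinical_path"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{path_attr}: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _preprocess(config: PipelineConfig, expr):
    if config.quantile_normalize:
        expr = quantile_normalize(expr)
    if config.log2_transform or config.median_center:
        expr = log2_median_center(expr, already_log2=not config.log2_transform)
    return expr


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage and write the report bundle to ``outdir``.

    Returns ``{"results": AnchorSignatureResults, "paths": {...}, ...}``.
    Stage failures propagate with the stage name; whatever was already
    written stays on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"anchorsig {__version__}", f"seed: {config.seed}"]

    stage = "simulate" if config.simulate is not None else "load"
    try:
        if config.simulate is not None:
            sim_cfg = SimulationConfig(**{**config.simulate, "seed": config.seed})
            cohort = simulate_cohort(sim_cfg)
            expr, clinical = cohort.expression, cohort.clinical
            cohort.write(outdir / "cohort")
            log_lines.append(
                f"simulated cohort: n={sim_cfg.n_samples}, features={sim_cfg.n_features}, "
                f"module={sim_cfg.n_module_features}"
            )
        else:
            cohort = None
            expr = read_expression(config.expression_path)
            clinical = read_clinical(config.clinical_path) if config.clinical_path else None
            log_lines.append(f"loaded expression: {config.expression_path}")

        stage = "preprocess"
        expr = _preprocess(config, expr)
        if config.quantile_normalize or config.log2_transform or config.median_center:
            write_expression(expr, outdir / "expression_preprocessed.tsv")
        log_lines.append(
            "preprocess: "
            f"quantile={config.quantile_normalize}, log2={config.log2_transform}, "
            f"median_center={config.median_center}"
        )

        stage = "derive"
        model = AnchorSignatureModel(
            expr,
            clinical,
            anchor_id=config.anchor_id,
            alpha=config.alpha,
            r_threshold=config.r_threshold,
            methods=config.methods,
        )
        results = model.fit(run_loocv=config.run_loocv)
        log_lines.append(
            f"screen: alpha={config.alpha}, r_threshold={config.r_threshold}, "
            f"selected={len(results.screen.selected)} features "
            f"(+anchor {config.anchor_id}), zero_variance_excluded={results.screen.n_zero_variance}"
        )
        counts = results.labels.value_counts()
        log_lines.append(
            f"clusters: HSC={counts.get('HSC', 0)}, LSC={counts.get('LSC', 0)}"
        )
        if results.logrank is not None:
            log_lines.append(
                f"log-rank: chi2={results.logrank.chi_square:.6g}, p={results.logrank.p:.6g}"
            )
        if results.cox is not None:
            log_lines.append(
                f"cox: converged={results.cox.converged}, iterations={results.cox.n_iter}, "
                f"events={results.cox.n_events}"
            )
        if config.run_loocv:
            for method, cv in results.cv_results.items():
                log_lines.append(
                    f"loocv[{method}]: accuracy={cv.accuracy:.4f}, "
                    f"median_features={int(cv.n_features_per_fold.median())}, "
                    f"failed_folds={len(cv.failed_folds)}"
                )

        stage = "report"
        paths = results.to_bundle(outdir)

        external = None
        if config.test_simulate is not None:
            stage = "external-validation"
            # the validation cohort shares the training cohort's gene-level
            # structure but none of its samples
            test_cfg = SimulationConfig(
                **{
                    "structure_seed": config.seed,
                    **config.test_simulate,
                    "seed": config.seed + 1,
                }
            )
            test_cohort = simulate_cohort(test_cfg)
            test_expr = _preprocess(config, test_cohort.expression)
            external = results.validate(
                test_expr.subset_features(results.signature_features),
                test_cohort.true_labels,
            )
            external.to_csv(outdir / "external_metrics.tsv", sep="\t", float_format="%.6g")
            paths["external_metrics"] = outdir / "external_metrics.tsv"
            log_lines.append(f"external validation: n={test_cfg.n_samples}")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    paths["run_log"] = outdir / "run_log.txt"
    for line in log_lines:
        logger.info(line)
    return {"results": results, "cohort": cohort, "external": external, "paths": paths}
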