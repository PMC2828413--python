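# anchorsig

Anchor-gene expression signatures with cluster-based prognosis and survival
validation.

## The problem

In non-muscle invasive bladder cancer (NMIBC), a minority of patients
progress to muscle-invasive disease, and conventional staging predicts this
poorly. One line of work builds a *prognostic expression signature around a
single anchor gene*: S100A8, a calcium-binding protein up-regulated in many
cancers. The recipe:

1. **Screen** every gene for Pearson correlation with the anchor across the
   cohort; keep genes with two-sided *p* < 0.001 and |*r*| > 0.3 (the
   *p*-value comes from *t* = *r*·√((n−2)/(1−*r*²)) on *n*−2 df).
2. **Cluster** samples on the signature genes with Eisen-style hierarchical
   clustering — uncentered correlation similarity
   *s*(x,y) = (1/n)Σ(xᵢ/σ⁰ₓ)(yᵢ/σ⁰ᵧ), σ⁰ᵥ = √((1/n)Σvᵢ²), distance 1−*s*,
   average (UPGMA) linkage — and cut the dendrogram at the root into the
   high-anchor cluster (HSC) and the low-anchor cluster (LSC).
3. **Validate** the dichotomy with five classical class predictors — compound
   covariate predictor (CCP, score cⱼ = Σᵢ tᵢxᵢⱼ, midpoint threshold),
   Bayesian compound covariate (BCC, Gaussian class densities on c, equal
   priors), diagonal linear discriminant analysis (DLDA), nearest centroid
   (NC), and a linear soft-margin SVM (C = 1) — under leave-one-out
   cross-validation in which the two-sample *t*-test gene selection
   (*p* < 0.001, pooled variance) is *repeated inside every fold*, and by
   predicting an independent cohort.
4. **Quantify prognosis** with Kaplan–Meier curves, the two-group log-rank
   test, and multivariate Cox proportional-hazards regression (Efron tie
   handling, Wald CIs exp(β ± 1.96·SE)) of progression against the signature
   and standard clinical covariates (stage, grade, tumor count, size,
   intravesical therapy).

`anchorsig` implements this entire pipeline as a tested, reusable library
plus CLI, together with a synthetic-cohort generator that emulates the
statistical structure such a study assumes — a latent two-cluster structure
driving the anchor, a correlated module with both signs of loading,
background genes, cluster-dependent exponential progression hazards with
uniform censoring, and categorical clinical covariates — so every stage can
be exercised and checked at desk scale.

## Worked example

```python
from anchorsig import AnchorSignatureModel, SimulationConfig, simulate_cohort

cohort = simulate_cohort(SimulationConfig(seed=9))           # 103 samples, 5000 genes
model = AnchorSignatureModel(cohort.expression, cohort.clinical, anchor_id="S100A8")
results = model.fit()
print(results.summary())
```

```
Anchor-gene signature analysis
================================================================
Anchor feature:        S100A8
Cohort size:           103 samples, 5000 features
Correlation screen:    p < 0.001, |r| > 0.3 -> 1003 correlated features
Clusters:              HSC n=40, LSC n=63  (mean anchor HSC=0.943, LSC=-0.884)
Log-rank (HSC vs LSC): chi2 = 7.432, p = 0.006409

Multivariate Cox regression (progression)
----------------------------------------------------------------
                                 HR (95% CI) P-value
variable
stage_T1               0.208 (0.045 - 0.976)   0.046
grade_high            4.869 (0.959 - 24.722)   0.056
n_tumors_2to7          1.399 (0.354 - 5.519)   0.632
n_tumors_ge8          4.004 (0.385 - 41.655)   0.246
size_gt3cm             0.317 (0.058 - 1.721)   0.183
intravesical_therapy   0.511 (0.129 - 2.033)   0.341
signature_HSC         8.909 (2.069 - 38.361)   0.003

Leave-one-out cross-validated class prediction
----------------------------------------------------------------
              Sensitivity  Specificity    PPV    NPV
Method Class
CCP    HSC          0.975        1.000  1.000  0.984
       LSC          1.000        0.975  0.984  1.000
...
SVM    HSC          1.000        1.000  1.000  1.000
       LSC          1.000        1.000  1.000  1.000
```

Reading the output: the correlation screen found the planted ~1,000-gene
module around the anchor; the root split of the dendrogram recovered the two
latent patient groups; belonging to the high-anchor cluster multiplies the
progression hazard by ≈8.9 (95% CI 2.1–38.4) after adjusting for the
clinical covariates — the wide interval is what 11 progression events in 103
patients buys — and all five cross-validated classifiers reproduce the
cluster membership almost perfectly.

An external cohort is predicted with the classifiers fitted on the full
training cohort:

```python
test = simulate_cohort(SimulationConfig(n_samples=302, seed=10, structure_seed=9))
results.validate(test.expression.subset_features(results.signature_features),
                 test.true_labels)
```

`structure_seed` makes the independent cohort share the training cohort's
gene-level biology (module membership and loading signs) while drawing
entirely new patients.

## Command line

```bash
anchorsig simulate --config sim.yaml --outdir cohort/ --seed 7
anchorsig preprocess --expr raw.tsv --out norm.tsv            # quantile + median centering
anchorsig derive --expr cohort/expression.tsv --anchor S100A8 --out signature.tsv
anchorsig cluster --expr cohort/expression.tsv --signature signature.tsv --out clusters.tsv
anchorsig validate --train-expr cohort/expression.tsv --train-labels clusters.tsv --out metrics.tsv
anchorsig survival --clinical cohort/clinical.tsv --clusters clusters.tsv \
    --out-cox cox_table.tsv --out-km km_curves.tsv
anchorsig run --config pipeline.yaml --outdir run/          # everything, one bundle
```

All tables are plain TSV; an identical config and seed reproduce the output
bundle byte for byte.

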