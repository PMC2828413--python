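"""Survival statistics: Kaplan-Meier, two-group log-rank, and Cox regression.

The Cox model maximizes the partial likelihood with the Efron correction for
tied event times (follow-up recorded in months ties heavily) by
Newton-Raphson with step-halving; standard errors come from the inverse
observed information, and confidence intervals are Wald intervals
``exp(beta +- 1.96 SE)``.  These routines are written out in full (rather
than delegating to a survival library) so that the score vector, the
information matrix, and every tie/convergence rule are available to the
rest of the package — e.g. the score test at beta = 0, which for a single
binary covariate with no ties must reproduce the log-rank chi-square
exactly, a useful internal consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "km_fit",
    "logrank_two_group",
    "cox_fit",
    "cox_score_test",
    "build_cox_design",
    "cox_table",
]


@dataclass
class KMCurve:
    """Kaplan-Meier estimate over the distinct event times.

    ``survival[i]`` is the estimate just after ``event_times[i]``; the curve
    starts at S(0) = 1.  ``variance`` is the Greenwood estimate per step.
    """

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    n_samples: int

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of the survival estimate at time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
                "greenwood_var": self.variance,
            }
        )


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if not (times > 0).all():
        raise ValueError("all times must be > 0")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be binary 0/1")
    return times, events.astype(int)


def km_fit(times, events) -> KMCurve:
    """Product-limit estimator; censored-only times shrink the risk set only."""
    times, events = _check_surv(times, events)
    n = times.size
    event_times = np.unique(times[events == 1])
    n_at_risk = np.empty(event_times.size, dtype=int)
    n_events = np.empty(event_times.size, dtype=int)
    surv = np.empty(event_times.size)
    var = np.empty(event_times.size)
    s = 1.0
    gw = 0.0  # running sum d / (n (n - d))
    for i, t in enumerate(event_times):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        n_at_risk[i] = at_risk
        n_events[i] = d
        s *= 1.0 - d / at_risk
        if at_risk > d:
            gw += d / (at_risk * (at_risk - d))
        else:
            gw = np.inf  # curve hit zero; Greenwood variance degenerates
        surv[i] = s
        var[i] = s**2 * gw if np.isfinite(gw) else 0.0
    return KMCurve(event_times, n_at_risk, n_events, surv, var, n_samples=n)


@dataclass
class LogRankResult:
    chi_square: float
    p: float
    observed: dict  # group -> observed events
    expected: dict  # group -> expected events under H0
    df: int = 1


def logrank_two_group(times, events, group) -> LogRankResult:
    """Two-group log-rank test with the hypergeometric variance."""
    times, events = _check_surv(times, events)
    group = pd.Series(np.asarray(group))
    names = sorted(pd.unique(group))
    if len(names) != 2:
        raise ValueError(f"need exactly two non-empty groups; got {names}")
    g1 = (group == names[0]).to_numpy()

    o_minus_e = 0.0
    var = 0.0
    obs = {names[0]: 0.0, names[1]: 0.0}
    exp = {names[0]: 0.0, names[1]: 0.0}
    for t in np.unique(times[events == 1]):
        at = times >= t
        n_i = int(at.sum())
        n1 = int((at & g1).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & g1).sum())
        e1 = d * n1 / n_i
        o_minus_e += d1 - e1
        if n_i > 1:
            var += d * (n1 / n_i) * (1 - n1 / n_i) * (n_i - d) / (n_i - 1)
        obs[names[0]] += d1
        obs[names[1]] += d - d1
        exp[names[0]] += e1
        exp[names[1]] += d - e1
    chi2 = o_minus_e**2 / var if var > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1)) if var > 0 else 1.0
    return LogRankResult(chi_square=float(chi2), p=p, observed=obs, expected=exp)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties, Newton-Raphson)
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Fitted Cox model: per-covariate estimates and Wald inference."""

    params: pd.DataFrame  # beta, se, hr, ci_low, ci_high, p per covariate
    loglik: float
    converged: bool
    n_iter: int
    n_samples: int
    n_events: int
    message: str = ""

    @property
    def beta(self) -> pd.Series:
        return self.params["beta"]

    @property
    def hazard_ratios(self) -> pd.Series:
        return self.params["hr"]

    def summary(self) -> pd.DataFrame:
        """Report table: HR (95% CI) and P-value per covariate."""
        out = pd.DataFrame(index=self.params.index)
        out["HR (95% CI)"] = [
            f"{r.hr:.3f} ({r.ci_low:.3f} - {r.ci_high:.3f})" for r in self.params.itertuples()
        ]
        out["P-value"] = [f"{p:.3f}" for p in self.params["p"]]
        return out


def _efron_loglik(beta, times, events, X):
    """Log partial likelihood, score and information with Efron ties."""
    p = X.shape[1]
    eta = X @ beta
    # guard exp overflow during aggressive Newton steps
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    loglik = 0.0
    U = np.zeros(p)
    I = np.zeros((p, p))
    for t in np.unique(times[events == 1]):
        risk = times >= t
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        S0 = w[risk].sum()
        S1 = X[risk].T @ w[risk]
        S2 = (X[risk].T * w[risk]) @ X[risk]
        S0d = w[dead].sum()
        S1d = X[dead].T @ w[dead]
        S2d = (X[dead].T * w[dead]) @ X[dead]
        loglik += eta[dead].sum()
        U += X[dead].sum(axis=0)
        for l in range(d):
            f = l / d
            s0 = S0 - f * S0d
            s1 = S1 - f * S1d
            s2 = S2 - f * S2d
            loglik -= np.log(s0)
            U -= s1 / s0
            I += s2 / s0 - np.outer(s1, s1) / s0**2
    return loglik, U, I


def _collinear_columns(X: np.ndarray, names) -> list:
    """Name columns that are linearly dependent on earlier ones."""
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc) == X.shape[1]:
        return []
    # greedy: a column is redundant if adding it does not raise the rank
    kept: list[int] = []
    redundant = []
    for j in range(X.shape[1]):
        cand = kept + [j]
        if np.linalg.matrix_rank(Xc[:, cand]) > len(kept):
            kept.append(j)
        else:
            redundant.append(names[j])
    return redundant


def cox_fit(
    times,
    events,
    covariates: pd.DataFrame,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Parameters
    ----------
    covariates
        Numeric design matrix, one row per sample, no constant column.
    tol
        Convergence when ``max |score| < tol``.

    Monotone partial likelihoods (perfect separation) do not converge to a
    finite maximizer; the fit is then flagged ``converged=False`` with a
    diagnostic message rather than raising.
    """
    times, events = _check_surv(times, events)
    if not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame(np.asarray(covariates, dtype=float))
    names = list(covariates.columns)
    X = covariates.to_numpy(dtype=float)
    if X.ndim != 2 or X.shape[0] != times.size:
        raise ValueError("covariate matrix must have one row per sample")
    if np.ptp(X, axis=0).min() == 0:
        const = [n for n, r in zip(names, np.ptp(X, axis=0)) if r == 0]
        raise ValueError(f"constant covariate column(s): {const}")

    beta = np.zeros(X.shape[1])
    loglik, U, I = _efron_loglik(beta, times, events, X)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        if np.abs(U).max() < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(I, U)
        except np.linalg.LinAlgError as exc:
            bad = _collinear_columns(X, names)
            raise ValueError(
                f"singular information matrix; collinear column(s): {bad or names}"
            ) from exc
        # step-halving keeps the ascent monotone
        factor = 1.0
        for _ in range(30):
            new_beta = beta + factor * step
            new_ll, new_U, new_I = _efron_loglik(new_beta, times, events, X)
            if new_ll >= loglik - 1e-12:
                break
            factor /= 2.0
        beta, loglik, U, I = new_beta, new_ll, new_U, new_I
    else:
        it = max_iter
    if not converged and np.abs(U).max() < tol:
        converged = True
    if converged and np.abs(beta).max() > 15:
        # the score can vanish numerically while beta runs off to infinity
        converged = False
    if not converged:
        if np.abs(beta).max() > 15:
            message = (
                "monotone partial likelihood (perfect separation?); "
                "estimates diverge and are not reliable"
            )
        else:
            message = f"Newton-Raphson did not converge in {max_iter} iterations"

    try:
        cov = np.linalg.inv(I)
    except np.linalg.LinAlgError as exc:
        bad = _collinear_columns(X, names)
        raise ValueError(
            f"singular information matrix; collinear column(s): {bad or names}"
        ) from exc
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):  # near-separation: an infinite CI bound is honest
        params = pd.DataFrame(
            {
                "beta": beta,
                "se": se,
                "hr": np.exp(beta),
                "ci_low": np.exp(beta - 1.96 * se),
                "ci_high": np.exp(beta + 1.96 * se),
                "p": pvals,
            },
            index=pd.Index(names, name="variable"),
        )
    return CoxFit(
        params=params,
        loglik=float(loglik),
        converged=converged,
        n_iter=it,
        n_samples=int(times.size),
        n_events=int(events.sum()),
        message=message,
    )


def cox_score_test(times, events, covariates) -> tuple[float, int, float]:
    """Cox score (Rao) test at beta = 0: ``U' I^{-1} U`` on p df."""
    times, events = _check_surv(times, events)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    _, U, I = _efron_loglik(np.zeros(X.shape[1]), times, events, X)
    chi2 = float(U @ np.linalg.solve(I, U))
    df = X.shape[1]
    return chi2, df, float(stats.chi2.sf(chi2, df=df))


# ---------------------------------------------------------------------------
# Clinical design matrix and report formatting
# ---------------------------------------------------------------------------

#: reference levels: Ta stage, low grade, single tumor, small size, no therapy, LSC
DESIGN_COLUMNS = (
    "stage_T1",
    "grade_high",
    "n_tumors_2to7",
    "n_tumors_ge8",
    "size_gt3cm",
    "intravesical_therapy",
    "signature_HSC",
)


def build_cox_design(clinical: ClinicalTable, signature_labels: pd.Series) -> pd.DataFrame:
    """Indicator-encode the clinical covariates plus the HSC/LSC signature.

    Reference levels: stage Ta, grade low, single tumor, size <= 3 cm, no
    intravesical therapy, LSC.
    """
    df = clinical.data
    labels = signature_labels.reindex(df.index)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])[:10]
        raise ValueError(f"signature label missing for sample(s): {missing}")
    design = pd.DataFrame(index=df.index)
    design["stage_T1"] = (df["stage"] == "T1").astype(float)
    design["grade_high"] = (df["grade"] == "high").astype(float)
    design["n_tumors_2to7"] = (df["n_tumors"] == "2to7").astype(float)
    design["n_tumors_ge8"] = (df["n_tumors"] == "ge8").astype(float)
    design["size_gt3cm"] = df["size_gt3cm"].astype(float)
    design["intravesical_therapy"] = df["intravesical_therapy"].astype(float)
    design["signature_HSC"] = (labels == "HSC").astype(float)
    return design


def cox_table(fit: CoxFit) -> pd.DataFrame:
    """Flat TSV-friendly table: variable, HR, CI_low, CI_high, P."""
    out = fit.params.reset_index()[["variable", "hr", "ci_low", "ci_high", "p"]]
    return out.rename(columns={"hr": "HR", "ci_low": "CI_low", "ci_high": "CI_high", "p": "P"})
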