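"""Cohort-level statistics.

Contingency-table tests of detection rates, Pearson correlation of gene
mutation frequencies between compartments, univariate/multivariate logistic
models of ctDNA detectability, one-way ANOVA of MVAF across clinical groups,
and confusion metrics for ERBB2 amplification against HER2 IHC.

Conventions: the chi-square test is Pearson's without continuity correction;
multi-level ordered covariates (age group, T, N) enter the logistic models as
ordinal numeric scores so each clinical characteristic yields a single
p-value; logistic p-values come from likelihood-ratio tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

#: ordinal/binary codings of the seven clinical covariates of the
#: detectability analysis
COVARIATE_CODINGS: dict[str, dict[str, float]] = {
    "age_group": {"<=35": 0, "36-55": 1, ">=56": 2},
    "t_stage": {"T1": 0, "T2": 1, "T3": 2, "T4": 3},
    "n_stage": {"N0": 0, "N1": 1, "N2": 2, "N3": 3},
    "m_stage": {"M0": 0, "M1": 1},
    "hr_status": {"positive": 0, "negative": 1},
    "her2_ihc": {"negative": 0, "positive": 1},  # unknown rows are dropped
    "ki67_group": {"low": 0, "high": 1},
}

TABLE2_COVARIATES = list(COVARIATE_CODINGS)


@dataclass(slots=True)
class AssociationResult:
    covariate: str
    statistic: float
    df: int
    p_value: float
    coefficient: float
    direction: str  # "increases" | "decreases" | "flat"
    flagged: str | None = None  # e.g. "penalized_fallback"


@dataclass(slots=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise ValueError("confusion matrix must contain at least one count")


@dataclass(slots=True)
class ConfusionMetrics:
    overall_consistency: float
    ppv: float | None
    npv: float | None
    sensitivity: float | None
    specificity: float | None


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction.

    Returns (statistic, degrees of freedom, upper-tail p).  Raises on tables
    with a zero row/column marginal (expected counts undefined).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: expected counts are undefined")
    res = sps.chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def confusion_metrics(m: ConfusionMatrix) -> ConfusionMetrics:
    """Overall consistency, predictive values, sensitivity and specificity.

    Metrics with an empty denominator come back as None (flagged undefined),
    never as 0.
    """
    total = m.tp + m.fp + m.fn + m.tn

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return ConfusionMetrics(
        overall_consistency=(m.tp + m.tn) / total,
        ppv=ratio(m.tp, m.tp + m.fp),
        npv=ratio(m.tn, m.tn + m.fn),
        sensitivity=ratio(m.tp, m.tp + m.fn),
        specificity=ratio(m.tn, m.tn + m.fp),
    )


def gene_frequency_table(
    variants_by_patient: Mapping[str, Sequence],
    all_patients: Sequence[str],
) -> dict[str, float]:
    """Per-gene fraction of patients carrying >= 1 variant in that gene.

    The denominator is the full patient list, including patients without any
    variant in the given compartment.
    """
    if len(all_patients) == 0:
        raise ValueError("cohort is empty")
    counts: dict[str, int] = {}
    for pid in all_patients:
        genes = {v.gene for v in variants_by_patient.get(pid, ()) if v.gene}
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return {g: c / len(all_patients) for g, c in sorted(counts.items())}


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in an input vector")
    r, _ = sps.pearsonr(x, y)
    return float(r * r)


# ---------------------------------------------------------------------------
# logistic models of detectability


def _design(cohort: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        coding = COVARIATE_CODINGS[cov]
        cols[cov] = cohort[cov].map(coding)
    X = pd.DataFrame(cols, index=cohort.index)
    return X.dropna()


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """Fit a Logit, falling back to L2-penalized likelihood under separation.

    Returns (params, llf, flagged).
    """
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
            if np.isfinite(res.llf) and np.all(np.abs(res.params) < 25):
                return np.asarray(res.params), float(res.llf), None
        except Exception:
            pass
        res = model.fit_regularized(disp=0, alpha=1e-3, maxiter=500)
    params = np.asarray(res.params)
    llf = float(model.loglike(params))
    return params, llf, "penalized_fallback"


def logistic_uva(
    cohort: pd.DataFrame,
    covariate: str,
    outcome: str = "ctdna_positive",
) -> AssociationResult:
    """Univariate logistic regression of ctDNA positivity on one covariate.

    Multi-level covariates enter as ordinal scores.  The p-value is a
    likelihood-ratio test against the intercept-only model.
    """
    X = _design(cohort, [covariate])
    y = cohort.loc[X.index, outcome].astype(int).to_numpy()
    x = X[covariate].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError(f"covariate '{covariate}' has a single observed level")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant")
    Xd = sm.add_constant(x)
    params, llf, flagged = _fit_logit(y, Xd)
    p0 = y.mean()
    ll0 = float(len(y) * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0)))
    lr = max(0.0, 2.0 * (llf - ll0))
    p = float(sps.chi2.sf(lr, 1))
    beta = float(params[1])
    return AssociationResult(
        covariate=covariate,
        statistic=lr,
        df=1,
        p_value=p,
        coefficient=beta,
        direction="increases" if beta > 0 else ("decreases" if beta < 0 else "flat"),
        flagged=flagged,
    )


def logistic_mva(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = tuple(TABLE2_COVARIATES),
    outcome: str = "ctdna_positive",
) -> list[AssociationResult]:
    """Joint logistic model; per-covariate p-values from drop-one
    likelihood-ratio tests."""
    X = _design(cohort, list(covariates))
    y = cohort.loc[X.index, outcome].astype(int).to_numpy()
    if len(y) <= len(covariates) + 1:
        raise ValueError("need more observations than parameters")
    Xm = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), Xm]))
    if rank < len(covariates) + 1:
        # name a culprit: a covariate whose removal restores full rank
        for j, cov in enumerate(covariates):
            sub = np.delete(Xm, j, axis=1)
            if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), sub])) == rank:
                raise ValueError(f"design matrix is rank deficient (covariate '{cov}')")
        raise ValueError("design matrix is rank deficient")
    Xd = sm.add_constant(Xm)
    params_full, llf_full, flagged = _fit_logit(y, Xd)
    results = []
    for j, cov in enumerate(covariates):
        Xr = sm.add_constant(np.delete(Xm, j, axis=1))
        _, llf_r, flag_r = _fit_logit(y, Xr)
        lr = max(0.0, 2.0 * (llf_full - llf_r))
        beta = float(params_full[j + 1])
        results.append(
            AssociationResult(
                covariate=cov,
                statistic=lr,
                df=1,
                p_value=float(sps.chi2.sf(lr, 1)),
                coefficient=beta,
                direction=(
                    "increases" if beta > 0 else ("decreases" if beta < 0 else "flat")
                ),
                flagged=flagged or flag_r,
            )
        )
    return results


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and upper-tail p."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    res = sps.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)
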