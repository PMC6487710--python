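"""Cohort statistics: contingency tests, correlation, logistic models, ANOVA."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ctdnatrace.stats import (
    COVARIATE_CODINGS,
    TABLE2_COVARIATES,
    ConfusionMatrix,
    anova_oneway,
    chi_square,
    confusion_metrics,
    gene_frequency_table,
    logistic_mva,
    logistic_uva,
    pearson_r2,
)
from ctdnatrace.variants import VariantCall


# ---------------------------------------------------------------------------
# chi-square


def test_chi_square_reference_table():
    stat, df, p = chi_square([[25, 27], [3, 16]])
    assert df == 1
    assert stat == pytest.approx(6.0737, abs=1e-3)
    assert p == pytest.approx(0.0137, abs=1e-3)


def test_chi_square_null_table():
    stat, _, p = chi_square([[20, 30], [20, 30]])
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi_square_input_validation():
    with pytest.raises(ValueError):
        chi_square([[1, 2]])  # single row
    with pytest.raises(ValueError):
        chi_square([[1, -2], [3, 4]])
    with pytest.raises(ValueError, match="marginal"):
        chi_square([[0, 0], [3, 4]])


def test_chi_square_agrees_with_permutation_oracle(rng):
    """Asymptotic p vs a label-permutation null, on a table with adequate
    expected counts; agreement tolerance 0.04 covers both the chi-square
    approximation and Monte-Carlo error (see decisions ledger)."""
    n = 240
    x = rng.integers(0, 2, size=n)
    y = (rng.random(n) < np.where(x == 1, 0.55, 0.40)).astype(int)

    def table(xv, yv):
        return [
            [np.sum((xv == 0) & (yv == 0)), np.sum((xv == 0) & (yv == 1))],
            [np.sum((xv == 1) & (yv == 0)), np.sum((xv == 1) & (yv == 1))],
        ]

    stat_obs, _, p_asym = chi_square(table(x, y))
    n_perm, hits = 20_000, 0
    for _ in range(n_perm):
        stat_perm, _, _ = chi_square(table(x, rng.permutation(y)))
        hits += stat_perm >= stat_obs - 1e-12
    p_perm = hits / n_perm
    assert abs(p_asym - p_perm) < 0.04


# ---------------------------------------------------------------------------
# confusion metrics


def test_confusion_metrics_identities(rng):
    for _ in range(50):
        tp, fp, fn, tn = (int(v) for v in rng.integers(1, 40, size=4))
        m = confusion_metrics(ConfusionMatrix(tp, fp, fn, tn))
        assert m.overall_consistency == pytest.approx(
            (tp + tn) / (tp + fp + fn + tn)
        )
        for v in (m.ppv, m.npv, m.sensitivity, m.specificity):
            assert 0.0 <= v <= 1.0


def test_confusion_metrics_undefined_denominators():
    m = confusion_metrics(ConfusionMatrix(tp=0, fp=0, fn=3, tn=7))
    assert m.ppv is None and m.sensitivity is not None
    m = confusion_metrics(ConfusionMatrix(tp=3, fp=0, fn=2, tn=0))
    assert m.specificity is None and m.npv == 0.0
    with pytest.raises(ValueError):
        ConfusionMatrix(0, 0, 0, 0)
    with pytest.raises(ValueError):
        ConfusionMatrix(-1, 1, 1, 1)


# ---------------------------------------------------------------------------
# gene frequencies & correlation


def _gv(gene):
    return VariantCall("syn1", 1, "A", "T", gene=gene)


def test_gene_frequency_table_fixture():
    patients = [f"P{i}" for i in range(70)]
    by_patient = {p: [_gv("TP53")] for p in patients[:33]}
    by_patient["P0"].append(_gv("TP53"))  # duplicate gene counts once
    by_patient["P1"].append(_gv("PIK3CA"))
    freqs = gene_frequency_table(by_patient, patients)
    assert freqs["TP53"] == pytest.approx(33 / 70)
    assert round(100 * freqs["TP53"], 2) == 47.14
    assert freqs["PIK3CA"] == pytest.approx(1 / 70)
    assert gene_frequency_table({}, patients) == {}
    with pytest.raises(ValueError):
        gene_frequency_table(by_patient, [])


def test_gene_frequency_brute_force_recount(rng):
    patients = [f"P{i}" for i in range(50)]
    genes = ["A1", "B2", "C3", "D4"]
    by_patient = {
        p: [_gv(genes[int(g)]) for g in rng.integers(0, 4, size=rng.integers(0, 6))]
        for p in patients
    }
    freqs = gene_frequency_table(by_patient, patients)
    for g in genes:
        expected = sum(
            any(v.gene == g for v in by_patient[p]) for p in patients
        ) / len(patients)
        assert freqs.get(g, 0.0) == pytest.approx(expected)


def test_pearson_r2():
    x = [1.0, 2.0, 3.0, 4.0]
    assert pearson_r2(x, x) == pytest.approx(1.0)
    assert pearson_r2(x, [-v for v in x]) == pytest.approx(1.0)
    y = [2.0, 4.0, 5.0, 9.0]
    assert pearson_r2(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)
    with pytest.raises(ValueError):
        pearson_r2([1, 2], [1, 2])
    with pytest.raises(ValueError):
        pearson_r2([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# logistic models


def _frame(rng, n: int, logit_fn) -> pd.DataFrame:
    """Random clinical frame with outcome drawn from a supplied logit."""
    rows = {}
    for cov, coding in COVARIATE_CODINGS.items():
        levels = list(coding)
        rows[cov] = rng.choice(levels, size=n)
    df = pd.DataFrame(rows)
    codes = {
        cov: df[cov].map(coding).to_numpy(dtype=float)
        for cov, coding in COVARIATE_CODINGS.items()
    }
    eta = logit_fn(codes)
    df["ctdna_positive"] = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    return df


def test_uva_recovers_planted_effect(rng):
    hits = 0
    for _ in range(10):
        df = _frame(rng, 2000, lambda c: -1.0 + np.log(2.0) * c["n_stage"])
        res = logistic_uva(df, "n_stage")
        assert res.direction == "increases"
        assert abs(res.coefficient - np.log(2.0)) < 0.25
        hits += res.p_value < 0.001
    assert hits >= 9  # power ~1 at odds ratio 2/step, n=2000


def test_uva_null_pvalues_uniform(rng):
    pvals = []
    for _ in range(200):
        df = _frame(rng, 500, lambda c: np.full(500, -0.3))
        pvals.append(logistic_uva(df, "hr_status").p_value)
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


def test_uva_degenerate_inputs(rng):
    df = _frame(rng, 100, lambda c: np.zeros(100))
    df["hr_status"] = "positive"
    with pytest.raises(ValueError, match="single observed level"):
        logistic_uva(df, "hr_status")
    df = _frame(rng, 100, lambda c: np.zeros(100))
    df["ctdna_positive"] = True
    with pytest.raises(ValueError, match="constant"):
        logistic_uva(df, "n_stage")


def test_uva_separation_flagged(rng):
    df = _frame(rng, 200, lambda c: np.zeros(200))
    df["ctdna_positive"] = df["hr_status"].eq("negative")  # perfect separation
    res = logistic_uva(df, "hr_status")
    assert res.flagged == "penalized_fallback"
    assert res.p_value < 1e-6


def test_her2_unknown_rows_are_dropped(rng):
    df = _frame(rng, 300, lambda c: np.zeros(300))
    # make every known HER2 row negative: after dropping unknowns the
    # covariate is single-level, proving unknowns are excluded
    df["her2_ihc"] = "negative"
    df.loc[:49, "her2_ihc"] = "unknown"
    with pytest.raises(ValueError, match="single observed level"):
        logistic_uva(df, "her2_ihc")


def test_mva_single_covariate_agrees_with_uva(rng):
    df = _frame(rng, 1500, lambda c: -0.8 + 0.7 * c["n_stage"])
    uva = logistic_uva(df, "n_stage")
    (mva,) = logistic_mva(df, ["n_stage"])
    assert mva.statistic == pytest.approx(uva.statistic, rel=1e-6)
    assert mva.p_value == pytest.approx(uva.p_value, rel=1e-6)
    assert mva.coefficient == pytest.approx(uva.coefficient, rel=1e-6)


def test_mva_rank_deficiency_names_a_covariate(rng):
    df = _frame(rng, 400, lambda c: np.zeros(400))
    t_by_n = {"N0": "T1", "N1": "T2", "N2": "T3", "N3": "T4"}
    df["t_stage"] = df["n_stage"].map(t_by_n)  # t collinear with n
    with pytest.raises(ValueError, match="rank deficient .*'(t|n)_stage'"):
        logistic_mva(df, ["t_stage", "n_stage", "hr_status"])


def test_mva_needs_enough_observations(rng):
    df = _frame(rng, 8, lambda c: np.zeros(8))
    with pytest.raises(ValueError, match="observations"):
        logistic_mva(df)


def test_mva_recovers_planted_covariates_and_controls_false_positives(rng):
    """Only N stage and HR status carry signal; both must test significant in
    >= 90% of replicates while the five null covariates fire at ~nominal
    alpha.  (An "exactly these two significant" event is not attainable at
    nominal alpha with five null covariates in play.)"""
    n_rep, both_hits, null_fp, null_total = 30, 0, 0, 0
    for _ in range(n_rep):
        df = _frame(
            rng, 1200,
            lambda c: -1.2 + 0.9 * c["n_stage"] + 1.1 * c["hr_status"],
        )
        results = {r.covariate: r for r in logistic_mva(df)}
        if results["n_stage"].p_value < 0.05 and results["hr_status"].p_value < 0.05:
            both_hits += 1
        assert results["n_stage"].direction == "increases"
        assert results["hr_status"].direction == "increases"
        for cov in TABLE2_COVARIATES:
            if cov in ("n_stage", "hr_status"):
                continue
            null_total += 1
            null_fp += results[cov].p_value < 0.05
    assert both_hits >= int(0.9 * n_rep)
    # family-wise: 150 null tests at alpha 0.05 -> ~7.5 expected FPs
    fp_rate = null_fp / null_total
    assert fp_rate < 0.05 + 4 * np.sqrt(0.05 * 0.95 / null_total)


# ---------------------------------------------------------------------------
# ANOVA


def test_anova_identical_groups_null():
    g = [1.0, 2.0, 3.0, 4.0]
    f, p = anova_oneway([g, list(g)])
    assert f == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_anova_two_group_t_identity(rng):
    a = rng.normal(0.0, 1.0, size=30)
    b = rng.normal(0.6, 1.0, size=24)
    f, p = anova_oneway([a, b])
    t = sps.ttest_ind(a, b, equal_var=True)
    assert f == pytest.approx(t.statistic**2, rel=1e-10)
    assert p == pytest.approx(t.pvalue, rel=1e-10)


def test_anova_detects_planted_shift(rng):
    a = rng.normal(0.0, 1.0, size=40)
    b = rng.normal(1.5, 1.0, size=40)
    _, p = anova_oneway([a, b])
    assert p < 1e-6


def test_anova_rejection_rate_matches_noncentral_f(rng):
    """Empirical power at a planted shift vs the analytic non-central-F power."""
    n, delta, alpha, reps = 20, 0.8, 0.05, 400
    # two groups of n, means 0 and delta, sd 1: lambda = n * delta^2 / 2
    lam = n * delta**2 / 2.0
    crit = sps.f.ppf(1 - alpha, 1, 2 * n - 2)
    power = 1.0 - sps.ncf.cdf(crit, 1, 2 * n - 2, lam)
    hits = 0
    for _ in range(reps):
        a = rng.normal(0.0, 1.0, size=n)
        b = rng.normal(delta, 1.0, size=n)
        _, p = anova_oneway([a, b])
        hits += p < alpha
    assert abs(hits / reps - power) < 4 * np.sqrt(power * (1 - power) / reps)


def test_anova_group_size_errors():
    with pytest.raises(ValueError):
        anova_oneway([[1.0, 2.0]])
    with pytest.raises(ValueError, match="group 1"):
        anova_oneway([[1.0, 2.0], [3.0]])
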