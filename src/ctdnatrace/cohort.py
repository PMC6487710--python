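"""Synthetic breast-cancer cohort generator.

Emulates the study population a tumor-informed liquid-biopsy analysis runs
on: clinical covariates drawn from configured marginal proportions, per-tumor
somatic mutation profiles with a clonal/subclonal CCF structure, and plasma
observations produced by a covariate-dependent logistic shedding model with a
clonal-hematopoiesis side channel.

Determinism contract: every sampling entry point is driven either by the
config seed (``sample_cohort``) or by a seed derived from the config seed and
the patient id (``sample_tumor_mutations``, ``simulate_plasma``), so identical
configs reproduce bit-identical cohorts regardless of call order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .reference import GENE_WEIGHTS, gene_window, ref_base
from .variants import VariantCall, classify_var_type

AGE_GROUPS = ("<=35", "36-55", ">=56")
T_STAGES = ("T1", "T2", "T3", "T4")
N_STAGES = ("N0", "N1", "N2", "N3")
STAGES = ("I", "II", "III", "IV")

# Default marginal proportions of the 71-patient cohort being emulated.
DEFAULT_PROPORTIONS: dict[str, dict[str, float]] = {
    "age_group": {"<=35": 12 / 71, "36-55": 40 / 71, ">=56": 19 / 71},
    "tnm_stage": {"I": 8 / 71, "II": 18 / 71, "III": 38 / 71, "IV": 7 / 71},
    "t_stage": {"T1": 26 / 71, "T2": 33 / 71, "T3": 9 / 71, "T4": 3 / 71},
    "n_stage": {"N0": 19 / 71, "N1": 12 / 71, "N2": 20 / 71, "N3": 20 / 71},
    "hr_status": {"positive": 52 / 71, "negative": 19 / 71},
    "her2_ihc": {"positive": 28 / 71, "negative": 42 / 71, "unknown": 1 / 71},
    "ki67_group": {"high": 60 / 71, "low": 11 / 71},
}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True, slots=True)
class Patient:
    patient_id: str
    age_group: str
    t_stage: str
    n_stage: str
    m_stage: str
    tnm_stage: str
    hr_status: str
    her2_ihc: str
    ki67_group: str
    subtype: str
    tumor_purity: float

    def __post_init__(self) -> None:
        if (self.m_stage == "M1") != (self.tnm_stage == "IV"):
            raise ValueError("M1 and stage IV must coincide")
        if not 0.0 < self.tumor_purity <= 1.0:
            raise ValueError("tumor_purity must lie in (0, 1]")

    @property
    def n_ordinal(self) -> int:
        return N_STAGES.index(self.n_stage)

    @property
    def t_ordinal(self) -> int:
        return T_STAGES.index(self.t_stage)

    @property
    def age_ordinal(self) -> int:
        return AGE_GROUPS.index(self.age_group)


def ihc_subtype(hr_status: str, her2_ihc: str, ki67_group: str) -> str:
    """Immunohistochemical surrogate subtype (St. Gallen convention)."""
    if her2_ihc == "unknown":
        return "unknown"
    if hr_status == "positive":
        if her2_ihc == "negative" and ki67_group == "low":
            return "LuminalA"
        return "LuminalB"
    return "HER2" if her2_ihc == "positive" else "TNBC"


@dataclass(slots=True)
class SheddingParams:
    """Logistic model of per-mutation plasma shedding.

    log-odds = intercept + coef_n_stage·N + coef_hr_negative·1[HR−]
             + coef_m1·1[M1] (+ log(clonal_boost) for clonal mutations),
    with N the ordinal nodal stage 0..3.  ``vaf_scale_by_stage`` sets the
    median circulating tumor fraction by TNM stage; ``vaf_log_sigma`` is the
    log-normal spread of the per-patient tumor fraction around that median.
    ``tf_coef_n_stage`` and ``tf_coef_hr_negative`` shift the log tumor
    fraction with nodal stage and HR negativity — tumor burden, not just the
    per-mutation shedding odds, carries the clinical detectability gradient.
    """

    intercept: float = 0.3
    coef_n_stage: float = 0.5
    coef_hr_negative: float = 1.0
    coef_m1: float = 1.0
    clonal_boost: float = 4.0
    vaf_scale_by_stage: dict[str, float] = field(
        default_factory=lambda: {"I": 0.003, "II": 0.0045, "III": 0.00675, "IV": 0.021}
    )
    vaf_log_sigma: float = 1.1
    tf_coef_n_stage: float = 0.65
    tf_coef_hr_negative: float = 0.9

    def __post_init__(self) -> None:
        if self.clonal_boost < 1.0:
            raise ConfigurationError("clonal_boost must be >= 1")
        if any(v <= 0 for v in self.vaf_scale_by_stage.values()):
            raise ConfigurationError("vaf_scale_by_stage entries must be positive")


@dataclass(slots=True)
class GroundTruthMutation:
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    ccf_true: float
    clonal_true: bool
    tumor_vaf_true: float
    shed_vaf_true: float = 0.0
    origin: str = "tumor"  # "tumor" | "hematopoietic"

    def __post_init__(self) -> None:
        if self.origin == "hematopoietic" and self.tumor_vaf_true != 0.0:
            raise ValueError("hematopoietic mutations have zero tumor VAF")


def truncated_negbinom_pmf(r: float = 2.0, p: float = 0.445,
                           lo: int = 1, hi: int = 15) -> dict[int, float]:
    """Negative-binomial pmf truncated to [lo, hi] and renormalized.

    The default (r=2, p=0.445) puts the population median of per-tumor
    mutation counts at ~2.5 with a long tail to 15, matching an overdispersed
    mutation-burden distribution.
    """
    ks = np.arange(lo, hi + 1)
    pmf = stats.nbinom.pmf(ks, r, p)
    pmf = pmf / pmf.sum()
    return dict(zip(ks.tolist(), pmf.tolist()))


@dataclass(slots=True)
class CohortConfig:
    n_patients: int = 71
    covariate_proportions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PROPORTIONS.items()}
    )
    mutation_count_distribution: dict[int, float] = field(
        default_factory=truncated_negbinom_pmf
    )
    gene_frequency_table: dict[str, float] = field(
        default_factory=lambda: dict(GENE_WEIGHTS)
    )
    shedding_params: SheddingParams = field(default_factory=SheddingParams)
    seed: int = 0
    # tumor purity ~ Beta(a, b): mean 2/3, mass on 0.35-0.9
    purity_beta: tuple[float, float] = (6.0, 3.0)
    # clonal architecture
    n_subclones_pmf: dict[int, float] = field(
        default_factory=lambda: {0: 0.25, 1: 0.45, 2: 0.30}
    )
    p_clonal_assignment: float = 0.45
    subclone_ccf_range: tuple[float, float] = (0.1, 0.7)
    indel_fraction: float = 0.15
    # clonal hematopoiesis side channel
    hematopoietic_rate: float = 0.15
    hematopoietic_genes: dict[str, float] = field(
        default_factory=lambda: {"DNMT3A": 0.6, "JAK2": 0.2, "TET2": 0.2}
    )
    hematopoietic_vaf_range: tuple[float, float] = (0.006, 0.025)

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        for cov, probs in self.covariate_proportions.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"proportions for covariate '{cov}' sum to "
                    f"{sum(probs.values())!r}, expected 1"
                )
        counts = self.mutation_count_distribution
        if abs(sum(counts.values()) - 1.0) > 1e-9:
            raise ConfigurationError("mutation_count_distribution must sum to 1")
        if counts and not all(1 <= k <= 15 for k in counts):
            raise ConfigurationError("mutation counts must lie in [1, 15]")
        if not self.gene_frequency_table:
            raise ConfigurationError("gene_frequency_table is empty")


def _derive_seed(seed: int, tag: str) -> int:
    return (seed * 2_654_435_761 + zlib.crc32(tag.encode())) % (2**31 - 1)


def _choice(rng: np.random.Generator, probs: dict[str, float] | dict[int, float]):
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def sample_cohort(config: CohortConfig) -> list[Patient]:
    """Draw a cohort of patients with independent configured marginals.

    M stage is derived from TNM stage (M1 iff stage IV) and the molecular
    subtype from HR/HER2/Ki67, so the type invariants hold by construction.
    """
    config.validate()
    rng = np.random.default_rng(_derive_seed(config.seed, "cohort"))
    props = config.covariate_proportions
    a, b = config.purity_beta
    patients = []
    for i in range(config.n_patients):
        stage = _choice(rng, props["tnm_stage"])
        hr = _choice(rng, props["hr_status"])
        her2 = _choice(rng, props["her2_ihc"])
        ki67 = _choice(rng, props["ki67_group"])
        patients.append(
            Patient(
                patient_id=f"P{i + 1:03d}",
                age_group=_choice(rng, props["age_group"]),
                t_stage=_choice(rng, props["t_stage"]),
                n_stage=_choice(rng, props["n_stage"]),
                m_stage="M1" if stage == "IV" else "M0",
                tnm_stage=stage,
                hr_status=hr,
                her2_ihc=her2,
                ki67_group=ki67,
                subtype=ihc_subtype(hr, her2, ki67),
                tumor_purity=float(np.clip(rng.beta(a, b), 0.05, 1.0)),
            )
        )
    return patients


def _draw_locus(rng: np.random.Generator, gene: str, taken: set[tuple[str, int]],
                indel_fraction: float) -> tuple[str, int, str, str]:
    chrom, lo, hi = gene_window(gene)
    for _ in range(100):
        pos = int(rng.integers(lo, hi + 1))
        if (chrom, pos) not in taken:
            break
    taken.add((chrom, pos))
    ref = ref_base(chrom, pos)
    if rng.random() < indel_fraction:
        ins = rng.random() < 0.5
        piece = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
        if ins:
            return chrom, pos, ref, ref + piece
        # deletion of the bases following the anchor
        deleted = "".join(ref_base(chrom, pos + k) for k in range(1, len(piece) + 1))
        return chrom, pos, ref + deleted, ref
    alt = rng.choice([b for b in "ACGT" if b != ref])
    return chrom, pos, ref, str(alt)


def sample_tumor_mutations(patient: Patient, config: CohortConfig) -> list[GroundTruthMutation]:
    """Draw a tumor mutation profile with clonal structure for one patient.

    The CCF law: one clonal cluster at CCF 1.0 plus 0-2 subclones with CCFs
    uniform on the configured range; each mutation joins the clonal cluster
    with probability ``p_clonal_assignment`` (always, when no subclones were
    drawn).  Mutations with CCF >= 75% of the patient's maximum are flagged
    ``clonal_true``, so relabelling noise-free data downstream reproduces the
    flags exactly.  Tumor VAF assumes heterozygous mutations at copy number 2:
    vaf = ccf * purity / 2.
    """
    config.validate()
    rng = np.random.default_rng(
        _derive_seed(config.seed, f"mutations:{patient.patient_id}")
    )
    n_mut = int(_choice(rng, config.mutation_count_distribution))
    n_sub = int(_choice(rng, config.n_subclones_pmf))
    lo, hi = config.subclone_ccf_range
    subclone_ccfs = sorted(rng.uniform(lo, hi, size=n_sub).tolist(), reverse=True)
    genes = list(config.gene_frequency_table)
    weights = np.asarray([config.gene_frequency_table[g] for g in genes], dtype=float)
    weights = weights / weights.sum()

    taken: set[tuple[str, int]] = set()
    ccfs = []
    for _ in range(n_mut):
        if n_sub == 0 or rng.random() < config.p_clonal_assignment:
            ccfs.append(1.0)
        else:
            ccfs.append(subclone_ccfs[int(rng.integers(0, n_sub))])
    max_ccf = max(ccfs)
    mutations = []
    for ccf in ccfs:
        gene = genes[rng.choice(len(genes), p=weights)]
        chrom, pos, ref, alt = _draw_locus(rng, gene, taken, config.indel_fraction)
        mutations.append(
            GroundTruthMutation(
                gene=gene,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                ccf_true=float(ccf),
                clonal_true=ccf >= 0.75 * max_ccf,
                tumor_vaf_true=float(ccf * patient.tumor_purity / 2.0),
            )
        )
    return mutations


def shedding_probability(
    patient: Patient, mutation: GroundTruthMutation, params: SheddingParams
) -> float:
    """Probability that a tumor mutation is shed into plasma at an
    observable level, as a logistic function of the clinical covariates."""
    logit = (
        params.intercept
        + params.coef_n_stage * patient.n_ordinal
        + params.coef_hr_negative * (patient.hr_status == "negative")
        + params.coef_m1 * (patient.m_stage == "M1")
    )
    if mutation.clonal_true:
        logit += float(np.log(params.clonal_boost))
    return float(1.0 / (1.0 + np.exp(-logit)))


def simulate_plasma(
    patient: Patient,
    mutations: list[GroundTruthMutation],
    params: SheddingParams,
    seed: int,
    config: CohortConfig | None = None,
) -> list[VariantCall]:
    """Generate ground-truth plasma observations for one patient.

    Each tumor mutation is shed independently with its logistic probability;
    shed mutations acquire a plasma VAF equal to ccf x (circulating tumor
    fraction)/2, with a per-patient log-normal tumor fraction whose median is
    set by TNM stage.  Hematopoiesis-derived mutations are appended from the
    configured side channel.  ``shed_vaf_true`` is filled in on the input
    mutations as a side effect.
    """
    rng = np.random.default_rng(seed % (2**31 - 1))
    calls: list[VariantCall] = []
    scale = params.vaf_scale_by_stage[patient.tnm_stage]
    log_median = (
        np.log(scale)
        + params.tf_coef_n_stage * patient.n_ordinal
        + params.tf_coef_hr_negative * (patient.hr_status == "negative")
    )
    tumor_fraction = float(np.exp(log_median + rng.normal(0.0, params.vaf_log_sigma)))
    for mut in mutations:
        p_shed = shedding_probability(patient, mut, params)
        if rng.random() < p_shed:
            vaf = float(min(0.45, mut.ccf_true * tumor_fraction / 2.0))
            mut.shed_vaf_true = vaf
            calls.append(
                VariantCall(
                    chrom=mut.chrom, pos=mut.pos, ref=mut.ref, alt=mut.alt,
                    var_type=classify_var_type(mut.ref, mut.alt),
                    vaf=vaf, source="plasma", gene=mut.gene, origin="tumor",
                )
            )
        else:
            mut.shed_vaf_true = 0.0
    if config is not None and config.hematopoietic_genes:
        if rng.random() < config.hematopoietic_rate:
            gene = _choice(rng, config.hematopoietic_genes)
            taken = {(m.chrom, m.pos) for m in mutations}
            chrom, pos, ref, alt = _draw_locus(rng, gene, taken, indel_fraction=0.0)
            lo, hi = config.hematopoietic_vaf_range
            calls.append(
                VariantCall(
                    chrom=chrom, pos=pos, ref=ref, alt=alt, var_type="SNV",
                    vaf=float(rng.uniform(lo, hi)), source="plasma",
                    gene=gene, origin="hematopoietic",
                )
            )
    return calls
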