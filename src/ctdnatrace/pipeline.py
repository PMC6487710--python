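"""Pipeline orchestration: one reproducible simulate -> detect -> filter ->
concord -> stats run with config validation, stage resumption, checksums and
a run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, SheddingParams
from .stats import (
    TABLE2_COVARIATES,
    anova_oneway,
    chi_square,
    gene_frequency_table,
    logistic_mva,
    logistic_uva,
    pearson_r2,
)
from .study import StudyParams, StudyResult, run_study


class PipelineConfigError(ValueError):
    pass


@dataclass(slots=True)
class RunConfig:
    """Single-file configuration of a pipeline run.

    Every assay threshold of the method surfaces here with its standard
    default: 0.5% LOD, background test alpha, >=5 high-quality reads, 1%
    tissue VAF floor, 11-bp indel window (as its >10-read count), 40-bp
    control flank (>=3 indel reads), and the 75% clonality cutoff.
    """

    outdir: str = "results/run"
    seed: int = 0
    n_patients: int = 71
    stages: tuple[str, ...] = ("simulate", "stats")
    lod: float = 0.005
    alpha: float = 0.01
    consensus_depth: int = 1000
    tissue_depth: int = 800
    min_hq_reads: int = 5
    min_vaf: float = 0.01
    indel_window_max: int = 10
    control_indel_min: int = 3
    clonality_threshold: float = 0.75
    mvaf_scope: str = "tumor_derived_only"
    planted_artifacts_per_patient: int = 2
    shedding: dict = field(default_factory=dict)

    def validate(self) -> None:
        checks = [
            (0.0 < self.lod < 1.0, f"lod={self.lod} outside (0, 1)"),
            (0.0 < self.alpha < 1.0, f"alpha={self.alpha} outside (0, 1)"),
            (0.0 < self.min_vaf < 1.0, f"min_vaf={self.min_vaf} outside (0, 1)"),
            (0.0 < self.clonality_threshold <= 1.0,
             f"clonality_threshold={self.clonality_threshold} outside (0, 1]"),
            (self.n_patients >= 0, "n_patients must be >= 0"),
            (self.consensus_depth > 0, "consensus_depth must be positive"),
            (self.min_hq_reads >= 0, "min_hq_reads must be >= 0"),
            (self.mvaf_scope in ("tumor_derived_only", "all_plasma"),
             f"unknown mvaf_scope {self.mvaf_scope!r}"),
            (all(s in ("simulate", "stats") for s in self.stages),
             f"unknown stage in {self.stages!r}"),
        ]
        for ok, msg in checks:
            if not ok:
                raise PipelineConfigError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def cohort_config(self) -> CohortConfig:
        shed = SheddingParams(**self.shedding) if self.shedding else SheddingParams()
        return CohortConfig(
            n_patients=self.n_patients, seed=self.seed, shedding_params=shed
        )

    def study_params(self) -> StudyParams:
        return StudyParams(
            consensus_depth=self.consensus_depth,
            tissue_depth=self.tissue_depth,
            lod=self.lod,
            alpha=self.alpha,
            mvaf_scope=self.mvaf_scope,
            clonality_threshold=self.clonality_threshold,
            planted_artifacts_per_patient=self.planted_artifacts_per_patient,
            filter_thresholds={
                "min_hq_reads": self.min_hq_reads,
                "min_vaf": self.min_vaf,
                "indel_window_max": self.indel_window_max,
                "control_indel_min": self.control_indel_min,
            },
        )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _variants_frame(result: StudyResult, which: str) -> pd.DataFrame:
    rows = []
    for pr in result.patients:
        variants = pr.tumor_validated if which == "tumor" else pr.plasma_detected
        for v in variants:
            rows.append(
                {
                    "patient_id": pr.patient.patient_id,
                    "gene": v.gene,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "var_type": v.var_type,
                    "vaf": v.vaf,
                    "origin": v.origin,
                }
            )
    cols = ["patient_id", "gene", "chrom", "pos", "ref", "alt", "var_type",
            "vaf", "origin"]
    return pd.DataFrame(rows, columns=cols)


def stage_simulate(config: RunConfig, outdir: Path) -> list[Path]:
    result = run_study(config.cohort_config(), config.study_params())
    clinical_cols = [
        "patient_id", "age_group", "t_stage", "n_stage", "m_stage", "tnm_stage",
        "hr_status", "her2_ihc", "ki67_group", "subtype", "tumor_purity",
    ]
    paths = []
    for name, frame in (
        ("clinical.tsv", result.table[clinical_cols]),
        ("per_patient_results.tsv", result.table),
        ("tumor_variants.tsv", _variants_frame(result, "tumor")),
        ("plasma_variants.tsv", _variants_frame(result, "plasma")),
    ):
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        paths.append(path)
    echo = outdir / "config_echo.json"
    echo.write_text(json.dumps(dataclasses.asdict(config), indent=2, default=list))
    paths.append(echo)
    return paths


def stage_stats(config: RunConfig, outdir: Path) -> list[Path]:
    table = pd.read_csv(outdir / "per_patient_results.tsv", sep="\t")
    tumor = pd.read_csv(outdir / "tumor_variants.tsv", sep="\t")
    plasma = pd.read_csv(outdir / "plasma_variants.tsv", sep="\t")
    evaluable = table[table.n_tumor > 0].copy()
    paths = []

    # Table-2-shaped UVA/MVA summary.  Small or degenerate cohorts (a
    # single observed level, constant outcome, too few rows) make individual
    # models undefined; those p-values are reported as NaN, not errors.
    try:
        mva = {r.covariate: r.p_value for r in logistic_mva(evaluable)}
    except ValueError:
        mva = {}
    rows = []
    for cov in TABLE2_COVARIATES:
        try:
            uva_p = logistic_uva(evaluable, cov).p_value
        except ValueError:
            uva_p = float("nan")
        levels = sorted(evaluable[cov].dropna().unique())
        for level in levels:
            grp = evaluable[evaluable[cov] == level]
            rows.append(
                {
                    "characteristic": cov,
                    "group": level,
                    "n": len(grp),
                    "ctdna_positive_n": int(grp.ctdna_positive.sum()),
                    "ctdna_positive_pct": 100.0 * grp.ctdna_positive.mean(),
                    "uva_p": uva_p,
                    "mva_p": mva.get(cov, float("nan")),
                }
            )
    path = outdir / "detectability_table.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.4g")
    paths.append(path)

    # gene frequencies per compartment + correlation
    pids = table.patient_id.tolist()
    freq_rows = []
    freqs = {}
    for name, frame in (("tissue", tumor), ("plasma", plasma)):
        by_patient = {
            pid: [v for v in grp.itertuples()]
            for pid, grp in frame.groupby("patient_id")
        }
        freqs[name] = gene_frequency_table(by_patient, pids)
        freq_rows.extend(
            {"compartment": name, "gene": g, "frequency": f}
            for g, f in freqs[name].items()
        )
    path = outdir / "gene_frequencies.tsv"
    pd.DataFrame(freq_rows).to_csv(path, sep="\t", index=False, float_format="%.4g")
    paths.append(path)

    shared = sorted(set(freqs["plasma"]) & set(freqs["tissue"]))
    summary = {}
    if len(shared) >= 3:
        try:
            summary["gene_frequency_r2"] = pearson_r2(
                [freqs["tissue"][g] for g in shared],
                [freqs["plasma"][g] for g in shared],
            )
        except ValueError:  # degenerate (zero-variance) frequency vector
            pass
    # MVAF by M stage (metastatic vs localized), one-way ANOVA
    with_mvaf = evaluable.dropna(subset=["mvaf"])
    groups = [
        with_mvaf[with_mvaf.m_stage == m].mvaf.to_numpy() for m in ("M0", "M1")
    ]
    if all(len(g) >= 2 for g in groups):
        f_stat, p = anova_oneway(groups)
        summary["mvaf_m_stage_anova_F"] = f_stat
        summary["mvaf_m_stage_anova_p"] = p
    # detection-rate chi-square across TNM stage
    stage_tab = pd.crosstab(evaluable.tnm_stage, evaluable.ctdna_positive)
    if stage_tab.shape[1] == 2 and (stage_tab.values.sum(axis=1) > 0).all():
        stat, df, p = chi_square(stage_tab.values)
        summary["detection_by_stage_chi2"] = stat
        summary["detection_by_stage_p"] = p
    summary["cohort_detection_rate"] = float(evaluable.ctdna_positive.mean())
    path = outdir / "summary_stats.json"
    path.write_text(json.dumps(summary, indent=2))
    paths.append(path)
    return paths


@dataclass(slots=True)
class RunManifest:
    config: dict
    version: str
    stages: dict  # stage -> {"outputs": {path: sha256}, "seconds": float}

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=list))


_STAGE_FNS = {"simulate": stage_simulate, "stats": stage_stats}
_STAGE_ORDER = ("simulate", "stats")


def run_pipeline(config: RunConfig, resume: bool = True) -> RunManifest:
    """Execute the enabled stages in dependency order and write a manifest.

    With ``resume``, a stage whose outputs already exist is skipped (its
    checksums are still recorded).  The manifest is written last; a failing
    stage is recorded before the error propagates.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses.asdict(config), version=__version__, stages={}
    )
    try:
        for stage in _STAGE_ORDER:
            if stage not in config.stages:
                continue
            marker = outdir / f".{stage}.done.json"
            t0 = time.perf_counter()
            if resume and marker.exists():
                outputs = [Path(p) for p in json.loads(marker.read_text())]
                if all(p.exists() for p in outputs):
                    manifest.stages[stage] = {
                        "outputs": {str(p): _checksum(p) for p in outputs},
                        "seconds": 0.0,
                        "resumed": True,
                    }
                    continue
            outputs = _STAGE_FNS[stage](config, outdir)
            marker.write_text(json.dumps([str(p) for p in outputs]))
            manifest.stages[stage] = {
                "outputs": {str(p): _checksum(p) for p in outputs},
                "seconds": round(time.perf_counter() - t0, 3),
                "resumed": False,
            }
    except Exception as exc:
        manifest.stages["failed"] = {"stage": stage, "error": str(exc)}
        manifest.write(outdir / "manifest.json")
        raise
    manifest.write(outdir / "manifest.json")
    return manifest
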