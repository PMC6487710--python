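"""Tumor-plasma concordance, CCF estimation, and clonality classification.

Per patient, validated tumor variants and emitted plasma variants are matched
by left-normalized (chrom, pos, ref, alt) key and split into overlapping,
tissue-specific, and blood-specific sets.  A patient is ctDNA-positive when
at least one tumor-derived mutation is found in plasma.  CCFs are derived
from VAF with the standard purity/copy-number correction, and a mutation is
clonal when its CCF reaches 75% of the patient's maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .variants import VariantCall, VariantKey


class UndefinedMetric(ValueError):
    """Raised when a ratio's denominator is empty (never silently zeroed)."""


@dataclass(slots=True)
class ConcordancePartition:
    overlapping: frozenset[VariantKey]
    tissue_specific: frozenset[VariantKey]
    blood_specific: frozenset[VariantKey]
    n_tumor: int
    n_plasma: int
    plasma_vaf: dict[VariantKey, float]

    @property
    def tracing_fraction(self) -> float | None:
        if self.n_tumor == 0:
            return None
        return len(self.overlapping) / self.n_tumor

    @property
    def ctdna_positive(self) -> bool:
        return bool(self.overlapping)


def partition_variants(
    tumor: Iterable[VariantCall | VariantKey],
    plasma: Iterable[VariantCall | VariantKey],
) -> ConcordancePartition:
    """Split tumor and plasma variant sets into the three concordance classes
    (duplicate keys collapse)."""
    def as_key(v):
        return v.key if isinstance(v, VariantCall) else v

    tumor_keys = {as_key(v) for v in tumor}
    plasma_vaf: dict[VariantKey, float] = {}
    for v in plasma:
        k = as_key(v)
        vaf = v.vaf if isinstance(v, VariantCall) else 0.0
        plasma_vaf[k] = max(plasma_vaf.get(k, 0.0), vaf)
    plasma_keys = set(plasma_vaf)
    return ConcordancePartition(
        overlapping=frozenset(tumor_keys & plasma_keys),
        tissue_specific=frozenset(tumor_keys - plasma_keys),
        blood_specific=frozenset(plasma_keys - tumor_keys),
        n_tumor=len(tumor_keys),
        n_plasma=len(plasma_keys),
        plasma_vaf=plasma_vaf,
    )


def tracing_category(partition: ConcordancePartition) -> str:
    """"full" when every tumor variant is traced in plasma, "none" when no
    tumor variant is, "partial" otherwise.  Undefined for tumor-negative
    patients (they are excluded from concordance denominators)."""
    frac = partition.tracing_fraction
    if frac is None:
        raise UndefinedMetric(
            "tracing category undefined for a patient without tumor variants"
        )
    if frac == 1.0:
        return "full"
    if frac == 0.0:
        return "none"
    return "partial"


def mvaf(partition: ConcordancePartition, scope: str = "tumor_derived_only") -> float | None:
    """Maximal plasma VAF, the tumor-burden proxy.

    Scope "tumor_derived_only" restricts to plasma variants matching tumor
    variants; "all_plasma" includes blood-specific variants.  None when the
    scope set is empty.
    """
    if scope == "tumor_derived_only":
        keys = partition.overlapping
    elif scope == "all_plasma":
        keys = partition.plasma_vaf.keys()
    else:
        raise ValueError(f"unknown MVAF scope: {scope!r}")
    vafs = [partition.plasma_vaf[k] for k in keys]
    return max(vafs) if vafs else None


# ---------------------------------------------------------------------------
# cancer cell fraction


@dataclass(slots=True)
class CCFAssignment:
    key: VariantKey
    vaf: float
    ccf: float
    label: str  # "clonal" | "subclonal"


def compute_ccf(vaf: float, purity: float, copy_number: int = 2) -> float:
    """CCF from VAF with purity/copy-number correction, capped at 1.

    ccf = vaf * (purity*CN + (1-purity)*2) / purity; at purity 1 and CN 2
    this reduces to 2*vaf (heterozygous mutations).
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError("vaf must lie in [0, 1]")
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must lie in (0, 1]")
    return min(1.0, vaf * (purity * copy_number + (1.0 - purity) * 2.0) / purity)


def classify_clonality(ccfs: Sequence[float], threshold_fraction: float = 0.75) -> list[str]:
    """Label each CCF clonal iff it reaches ``threshold_fraction`` of the
    patient's maximum CCF.  At least one label is always clonal, and labels
    are invariant under positive rescaling of all CCFs."""
    if len(ccfs) == 0:
        raise ValueError("classify_clonality requires at least one CCF")
    cutoff = threshold_fraction * max(ccfs)
    return ["clonal" if c >= cutoff else "subclonal" for c in ccfs]


def assign_ccf(
    variants: Sequence[VariantCall],
    purity: float,
    copy_number: int = 2,
    threshold_fraction: float = 0.75,
) -> list[CCFAssignment]:
    """CCF and clonality label for each of a patient's tumor variants."""
    ccfs = [compute_ccf(v.vaf, purity, copy_number) for v in variants]
    labels = classify_clonality(ccfs, threshold_fraction) if ccfs else []
    return [
        CCFAssignment(key=v.key, vaf=v.vaf, ccf=c, label=lab)
        for v, c, lab in zip(variants, ccfs, labels)
    ]


# ---------------------------------------------------------------------------
# cohort-level tracing rates


@dataclass(slots=True)
class TracingRates:
    clonal_detected_fraction: float | None
    subclonal_detected_fraction: float | None
    n_clonal: int
    n_subclonal: int
    n_clonal_detected: int
    n_subclonal_detected: int
    patients_with_clonal_in_blood: int
    patients_with_subclonal_in_blood: int


def clonal_tracing_rates(
    per_patient: Mapping[str, Sequence[tuple[str, bool]]],
) -> TracingRates:
    """Pooled detection fractions of clonal vs subclonal tumor mutations.

    ``per_patient`` maps patient id to a list of (label, detected_in_blood)
    for that patient's tumor variants.  Fractions are pooled mutation counts;
    a class with zero mutations yields None, never 0.
    """
    n = {"clonal": 0, "subclonal": 0}
    det = {"clonal": 0, "subclonal": 0}
    pats = {"clonal": 0, "subclonal": 0}
    for labels in per_patient.values():
        seen = {"clonal": False, "subclonal": False}
        for label, detected in labels:
            n[label] += 1
            if detected:
                det[label] += 1
                seen[label] = True
        for lab, hit in seen.items():
            pats[lab] += hit
    return TracingRates(
        clonal_detected_fraction=det["clonal"] / n["clonal"] if n["clonal"] else None,
        subclonal_detected_fraction=(
            det["subclonal"] / n["subclonal"] if n["subclonal"] else None
        ),
        n_clonal=n["clonal"],
        n_subclonal=n["subclonal"],
        n_clonal_detected=det["clonal"],
        n_subclonal_detected=det["subclonal"],
        patients_with_clonal_in_blood=pats["clonal"],
        patients_with_subclonal_in_blood=pats["subclonal"],
    )
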