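"""Tissue somatic-variant filter cascade.

Post-processing of candidate somatic calls against the matched germline
control.  SNV rules (each an independent predicate; any firing rule rejects
the candidate):

  indel_window      > 10 reads with indels in the 11-bp window centered on
                    the site (mapping-artifact proxy)
  germline_evidence control sample carries >= 3% alternate-allele reads, or
                    >= 2% with a summed alt base quality above 80
  dbsnp_not_cosmic  known polymorphism (dbSNP) absent from COSMIC
  low_hq_support    fewer than 5 alt reads at base quality >= 30 and mapping
                    quality >= 30
  low_vaf           allele frequency strictly below 1%

Indel rules: control_indel (>= 3 control reads with indels at the site or
within 40 bp) and low_complexity (homopolymer or short-tandem-repeat
context).  Boundaries are exact: "more than 10" keeps 10, "fewer than five"
keeps 5, VAF exactly 0.01 is kept.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .variants import VariantCall

SNV_REASONS = (
    "indel_window",
    "germline_evidence",
    "dbsnp_not_cosmic",
    "low_hq_support",
    "low_vaf",
)
INDEL_REASONS = ("control_indel", "low_complexity")


class MissingContextError(ValueError):
    pass


@dataclass(slots=True)
class SiteContext:
    """Local alignment/control evidence around a candidate site."""

    indel_reads_in_window: int | None = None   # 11-bp window centered on pos
    control_alt_fraction: float | None = None
    control_alt_quality_sum: float | None = None
    control_indel_reads_nearby: int | None = None  # pos +/- 40 bp, max count
    window_sequence: str | None = None         # reference +/- 40 bp

    def require(self, *fields_: str) -> None:
        for name in fields_:
            if getattr(self, name) is None:
                raise MissingContextError(
                    f"SiteContext field '{name}' is required but missing"
                )


@dataclass(slots=True)
class FilterVerdict:
    kept: bool
    reasons: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.kept != (not self.reasons):
            raise ValueError("kept must hold exactly when reasons is empty")


def _verdict(reasons: Iterable[str]) -> FilterVerdict:
    rs = frozenset(reasons)
    return FilterVerdict(kept=not rs, reasons=rs)


def filter_snv(
    candidate: VariantCall,
    ctx: SiteContext,
    indel_window_max: int = 10,
    control_frac_hard: float = 0.03,
    control_frac_soft: float = 0.02,
    control_qual_sum: float = 80.0,
    min_hq_reads: int = 5,
    min_vaf: float = 0.01,
) -> FilterVerdict:
    if candidate.var_type != "SNV":
        raise ValueError("filter_snv expects an SNV candidate")
    ctx.require(
        "indel_reads_in_window", "control_alt_fraction", "control_alt_quality_sum"
    )
    reasons = []
    if ctx.indel_reads_in_window > indel_window_max:
        reasons.append("indel_window")
    if ctx.control_alt_fraction >= control_frac_hard or (
        ctx.control_alt_fraction >= control_frac_soft
        and ctx.control_alt_quality_sum > control_qual_sum
    ):
        reasons.append("germline_evidence")
    if candidate.db_flags.in_dbsnp and not candidate.db_flags.in_cosmic:
        reasons.append("dbsnp_not_cosmic")
    if candidate.hq_alt_reads < min_hq_reads:
        reasons.append("low_hq_support")
    if candidate.vaf < min_vaf:
        reasons.append("low_vaf")
    return _verdict(reasons)


def filter_indel(
    candidate: VariantCall,
    ctx: SiteContext,
    control_indel_min: int = 3,
    homopolymer_min: int = 8,
    repeat_min_copies: int = 4,
) -> FilterVerdict:
    if candidate.var_type != "indel":
        raise ValueError("filter_indel expects an indel candidate")
    ctx.require("control_indel_reads_nearby", "window_sequence")
    reasons = []
    if ctx.control_indel_reads_nearby >= control_indel_min:
        reasons.append("control_indel")
    if is_low_complexity(
        ctx.window_sequence,
        homopolymer_min=homopolymer_min,
        repeat_min_copies=repeat_min_copies,
    ):
        reasons.append("low_complexity")
    return _verdict(reasons)


def is_low_complexity(
    window_sequence: str,
    homopolymer_min: int = 8,
    repeat_unit_lengths: range = range(2, 7),
    repeat_min_copies: int = 4,
) -> bool:
    """True when the window contains a homopolymer run of ``homopolymer_min``
    or a tandem repeat (unit length 2-6) with at least ``repeat_min_copies``
    contiguous copies."""
    seq = window_sequence.upper()
    if re.search(f"[^ACGTN]", seq):
        bad = sorted(set(re.findall("[^ACGTN]", seq)))
        raise ValueError(f"non-ACGTN symbols in window sequence: {bad}")
    # N encodes missing data, not sequence, so N runs are never repeats
    if re.search(r"([ACGT])\1{%d,}" % (homopolymer_min - 1), seq):
        return True
    n = len(seq)
    for unit_len in repeat_unit_lengths:
        span = unit_len * repeat_min_copies
        if span > n:
            break
        for start in range(n - span + 1):
            unit = seq[start : start + unit_len]
            if "N" in unit:
                continue
            if seq[start : start + span] == unit * repeat_min_copies:
                # a homopolymer masquerading as a longer unit doesn't count as
                # a tandem repeat; the homopolymer rule owns that case
                if len(set(unit)) > 1:
                    return True
    return False


def apply_cascade(
    candidates: Sequence[VariantCall],
    contexts: Sequence[SiteContext],
    **thresholds,
) -> tuple[list[VariantCall], list[FilterVerdict]]:
    """Run the per-variant-type rule set over aligned candidate/context pairs.

    Returns the kept candidates and one audit verdict per input candidate.
    Rules are independent predicates, so the cascade is order-independent and
    idempotent on the kept set.
    """
    if len(candidates) != len(contexts):
        raise ValueError("candidates and contexts must be aligned")
    snv_kw = {k: v for k, v in thresholds.items()
              if k in {"indel_window_max", "control_frac_hard", "control_frac_soft",
                       "control_qual_sum", "min_hq_reads", "min_vaf"}}
    indel_kw = {k: v for k, v in thresholds.items()
                if k in {"control_indel_min", "homopolymer_min", "repeat_min_copies"}}
    kept, audit = [], []
    for cand, ctx in zip(candidates, contexts):
        if cand.var_type == "SNV":
            verdict = filter_snv(cand, ctx, **snv_kw)
        else:
            verdict = filter_indel(cand, ctx, **indel_kw)
        audit.append(verdict)
        if verdict.kept:
            kept.append(cand)
    return kept, audit
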