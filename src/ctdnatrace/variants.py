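"""Variant containers shared across the pipeline.

Coordinates are 1-based inclusive everywhere in memory; SAM/VCF conventions
are handled at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable


@dataclass(frozen=True, slots=True)
class VariantKey:
    """Identity of a variant: left-normalized locus plus alleles.

    Equality is exact field equality; indels must be left-normalized before a
    key is built (see :func:`left_normalize`) so that "same location" is
    well-defined.
    """

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True, slots=True)
class DbFlags:
    in_dbsnp: bool = False
    in_cosmic: bool = False


@dataclass(slots=True)
class VariantCall:
    """One candidate or validated somatic variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    var_type: str = "SNV"  # "SNV" | "indel"
    depth: int = 0
    alt_reads: int = 0
    vaf: float = 0.0
    hq_alt_reads: int = 0
    source: str = "tissue"  # "tissue" | "plasma" | "germline"
    db_flags: DbFlags = field(default_factory=DbFlags)
    gene: str | None = None
    origin: str | None = None  # "tumor" | "hematopoietic" (simulated plasma)
    duplex: bool | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.alt_reads <= max(self.depth, 0)) and self.depth > 0:
            raise ValueError(
                f"alt_reads={self.alt_reads} outside [0, depth={self.depth}]"
            )
        if self.hq_alt_reads > self.alt_reads:
            raise ValueError("hq_alt_reads cannot exceed alt_reads")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf={self.vaf} outside [0, 1]")

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    def normalized(self, ref_fn: Callable[[str, int], str] | None = None) -> "VariantCall":
        chrom, pos, ref, alt = left_normalize(self.chrom, self.pos, self.ref, self.alt, ref_fn)
        if (pos, ref, alt) == (self.pos, self.ref, self.alt):
            return self
        return replace(self, pos=pos, ref=ref, alt=alt)


def classify_var_type(ref: str, alt: str) -> str:
    return "SNV" if len(ref) == 1 and len(alt) == 1 else "indel"


def left_normalize(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    ref_fn: Callable[[str, int], str] | None = None,
) -> tuple[str, int, str, str]:
    """Left-normalize an allele pair (VCF-style parsimony + left alignment).

    Trims shared suffix/prefix bases, then, when a reference accessor is
    supplied, shifts pure insertions/deletions left while the haplotype is
    unchanged.  SNVs pass through untouched.
    """
    if not ref or not alt:
        raise ValueError("empty allele string")
    ref, alt = ref.upper(), alt.upper()
    # shift left: truncate a shared last base; when an allele empties, extend
    # both alleles leftward from the reference (requires ref_fn)
    while ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        if (len(ref) == 1 or len(alt) == 1) and (ref_fn is None or pos <= 1):
            break
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            pos -= 1
            prev = ref_fn(chrom, pos)  # type: ignore[misc]
            ref, alt = prev + ref, prev + alt
    # trim shared prefix, keeping one anchor base
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt
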