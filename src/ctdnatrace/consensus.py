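"""UMI duplex consensus calling and rare-variant detection gates.

The error-correction contract: reads are clustered into families by exact
(UID, contig, fragment start, fragment end); within a family each physical
strand is collapsed to a majority consensus (quality-weighted tie-break); an
allele is duplex-supported only when both strand consensuses agree.  Variant
emission then requires duplex support, an allele fraction at or above the
limit of detection (0.5% by default), a one-sided binomial test against a
background error model built from control plasma, and absence from the
matched germline set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .reference import ref_base
from .variants import VariantCall, VariantKey

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_DECODE = "ACGTN"
_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in _CODE.items():
    _LUT[ord(_b)] = _c


@dataclass(slots=True)
class TaggedRead:
    """One aligned plasma read carrying its duplex UID."""

    uid: str
    chrom: str
    fragment_start: int
    fragment_end: int
    strand_orientation: str  # "top" | "bottom"
    bases: str  # covers fragment_start .. fragment_start + len(bases) - 1
    base_qualities: Sequence[int]
    mapping_quality: int = 60

    def __post_init__(self) -> None:
        if self.fragment_start > self.fragment_end:
            raise ValueError("fragment_start must be <= fragment_end")
        if len(self.bases) != len(self.base_qualities):
            raise ValueError("bases and base_qualities length mismatch")


FamilyKey = tuple[str, str, int, int]  # (uid, chrom, start, end)


@dataclass(slots=True)
class ReadFamily:
    family_key: FamilyKey
    top_members: list[TaggedRead] = field(default_factory=list)
    bottom_members: list[TaggedRead] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.top_members) + len(self.bottom_members)


@dataclass(slots=True)
class ConsensusCall:
    chrom: str
    pos: int
    allele: str
    top_support: int
    bottom_support: int
    consensus_depth: int
    #: number of families whose duplex (both-strand) consensus is this allele
    duplex_support: int = 0

    @property
    def duplex(self) -> bool:
        return self.top_support >= 1 and self.bottom_support >= 1

    @property
    def allele_fraction(self) -> float:
        if self.consensus_depth == 0:
            return 0.0
        return self.duplex_support / self.consensus_depth


def group_families(reads: Iterable[TaggedRead]) -> list[ReadFamily]:
    """Partition reads into duplex families keyed by exact
    (UID, contig, fragment start, fragment end).

    Reads with a missing UID are rejected with a counted warning.
    """
    families: dict[FamilyKey, ReadFamily] = {}
    n_missing = 0
    for read in reads:
        if not read.uid:
            n_missing += 1
            continue
        key = (read.uid, read.chrom, read.fragment_start, read.fragment_end)
        fam = families.get(key)
        if fam is None:
            fam = families[key] = ReadFamily(family_key=key)
        if read.strand_orientation == "top":
            fam.top_members.append(read)
        else:
            fam.bottom_members.append(read)
    if n_missing:
        warnings.warn(f"rejected {n_missing} reads with missing UID", stacklevel=2)
    return list(families.values())


def _strand_consensus(members: list[TaggedRead]) -> tuple[int, np.ndarray] | None:
    """Majority base per position over a strand's members.

    Returns (start position, codes) over the span covered by every member;
    ties are broken by summed base quality, then lexicographically.  Positions
    whose winner is N yield code 4 (treated as no call).
    """
    if not members:
        return None
    start = members[0].fragment_start
    span = min(len(m.bases) for m in members)
    counts = np.zeros((span, 5), dtype=np.int32)
    qsums = np.zeros((span, 5), dtype=np.float64)
    for m in members:
        codes = _LUT[np.frombuffer(m.bases[:span].encode(), dtype=np.uint8)]
        idx = np.arange(span)
        counts[idx, codes] += 1
        qsums[idx, codes] += np.asarray(m.base_qualities[:span], dtype=float)
    # quality-weighted tie-break: tiny quality term never overturns a count
    score = counts.astype(float) + qsums * 1e-9
    return start, score.argmax(axis=1).astype(np.uint8)


def family_consensus(
    family: ReadFamily, min_members_per_strand: int = 1
) -> dict[int, tuple[str | None, str | None, str | None]]:
    """Per-position (top, bottom, duplex) consensus alleles of one family.

    A strand with fewer than ``min_members_per_strand`` members contributes no
    consensus; the duplex allele exists only where both strands agree.
    """
    if min_members_per_strand < 1:
        raise ValueError("min_members_per_strand must be >= 1")
    top = _strand_consensus(family.top_members) \
        if len(family.top_members) >= min_members_per_strand else None
    bot = _strand_consensus(family.bottom_members) \
        if len(family.bottom_members) >= min_members_per_strand else None
    out: dict[int, tuple[str | None, str | None, str | None]] = {}
    spans = []
    if top is not None:
        spans.append((top[0], len(top[1])))
    if bot is not None:
        spans.append((bot[0], len(bot[1])))
    if not spans:
        return out
    lo = min(s for s, _ in spans)
    hi = max(s + n for s, n in spans)
    for pos in range(lo, hi):
        t = b = None
        if top is not None and top[0] <= pos < top[0] + len(top[1]):
            code = top[1][pos - top[0]]
            t = _DECODE[code] if code < 4 else None
        if bot is not None and bot[0] <= pos < bot[0] + len(bot[1]):
            code = bot[1][pos - bot[0]]
            b = _DECODE[code] if code < 4 else None
        duplex = t if (t is not None and t == b) else None
        out[pos] = (t, b, duplex)
    return out


def consensus_pileup(
    families: Iterable[ReadFamily], min_members_per_strand: int = 1
) -> list[ConsensusCall]:
    """Aggregate family consensuses into per-(position, allele) calls.

    ``consensus_depth`` counts duplex-evaluable families (both strands pass
    the member threshold and agree on some allele) covering the position;
    supports count families whose strand consensus equals the allele.
    """
    depth: dict[tuple[str, int], int] = {}
    support: dict[tuple[str, int, str], list[int]] = {}
    for fam in families:
        chrom = fam.family_key[1]
        cons = family_consensus(fam, min_members_per_strand)
        for pos, (t, b, duplex) in cons.items():
            if duplex is not None:
                depth[(chrom, pos)] = depth.get((chrom, pos), 0) + 1
            for allele, slot in ((t, 0), (b, 1), (duplex, 2)):
                if allele is None:
                    continue
                rec = support.setdefault((chrom, pos, allele), [0, 0, 0])
                rec[slot] += 1
    calls = []
    for (chrom, pos, allele), (n_top, n_bot, n_dup) in sorted(support.items()):
        calls.append(
            ConsensusCall(
                chrom=chrom,
                pos=pos,
                allele=allele,
                top_support=n_top,
                bottom_support=n_bot,
                consensus_depth=depth.get((chrom, pos), 0),
                duplex_support=n_dup,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# background error model


@dataclass(slots=True)
class BackgroundModel:
    """Site-level (fallback: substitution-class) error fractions estimated
    from control plasma consensus calls, with a pseudocount."""

    site_rates: dict[tuple[str, int, str], float] = field(default_factory=dict)
    class_rates: dict[tuple[str, str], float] = field(default_factory=dict)
    floor: float = 1e-4
    pseudocount: float = 0.5

    @classmethod
    def null(cls, floor: float = 1e-4) -> "BackgroundModel":
        """Packaged null model: a flat error-fraction floor at every site."""
        return cls(floor=floor)

    def rate(self, chrom: str, pos: int, ref: str, alt: str) -> float:
        r = self.site_rates.get((chrom, pos, alt))
        if r is None:
            r = self.class_rates.get((ref, alt))
        if r is None:
            r = self.floor
        return min(max(r, self.floor), 1.0 - 1e-12)


def build_background(
    controls: Sequence[Sequence[ConsensusCall]],
    pseudocount: float = 0.5,
    ref_fn: Callable[[str, int], str] = ref_base,
) -> BackgroundModel:
    """Pool control-plasma consensus calls into a background error model.

    Per site and alt allele the error fraction is
    (alt families + a) / (depth + 2a) with pseudocount ``a``, pooled over
    controls; substitution-class rates are pooled genome-wide as fallback.
    """
    if len(controls) == 0:
        raise ValueError(
            "build_background requires at least one control sample; "
            "use BackgroundModel.null() for the packaged null model"
        )
    site_alt: dict[tuple[str, int, str], int] = {}
    site_depth: dict[tuple[str, int], int] = {}
    class_alt: dict[tuple[str, str], int] = {}
    class_depth: dict[tuple[str, str], int] = {}
    for calls in controls:
        for call in calls:
            ref = ref_fn(call.chrom, call.pos)
            site_depth[(call.chrom, call.pos)] = (
                site_depth.get((call.chrom, call.pos), 0) + 0
            )
            if call.allele == ref:
                site_depth[(call.chrom, call.pos)] += call.duplex_support
                for alt in "ACGT":
                    if alt != ref:
                        class_depth[(ref, alt)] = (
                            class_depth.get((ref, alt), 0) + call.duplex_support
                        )
            else:
                site_alt[(call.chrom, call.pos, call.allele)] = (
                    site_alt.get((call.chrom, call.pos, call.allele), 0)
                    + call.duplex_support
                )
                site_depth[(call.chrom, call.pos)] += call.duplex_support
                class_alt[(ref, call.allele)] = (
                    class_alt.get((ref, call.allele), 0) + call.duplex_support
                )
                class_depth[(ref, call.allele)] = (
                    class_depth.get((ref, call.allele), 0) + call.duplex_support
                )
    a = pseudocount
    site_rates = {}
    for (chrom, pos, alt), k in site_alt.items():
        n = site_depth[(chrom, pos)]
        site_rates[(chrom, pos, alt)] = (k + a) / (n + 2 * a)
    # sites with zero alt events contribute only through the class fallback
    class_rates = {}
    for key, n in class_depth.items():
        k = class_alt.get(key, 0)
        class_rates[key] = (k + a) / (n + 2 * a)
    floor = a / (max(max(site_depth.values(), default=0), 1) + 2 * a)
    return BackgroundModel(
        site_rates=site_rates,
        class_rates=class_rates,
        floor=max(floor, 1e-12),
        pseudocount=a,
    )


# ---------------------------------------------------------------------------
# detection gates


def detection_gates(
    duplex: bool,
    allele_fraction: float,
    alt_families: int,
    depth: int,
    background_rate: float,
    is_germline: bool,
    lod: float = 0.005,
    alpha: float = 0.01,
) -> tuple[bool, list[str]]:
    """Apply the four emission gates; returns (emit, rejection reasons)."""
    reasons = []
    if not duplex:
        reasons.append("no_duplex_support")
    if allele_fraction < lod:
        reasons.append("below_lod")
    # one-sided exact binomial: P(X >= alt | depth, background) <= alpha
    if depth <= 0 or stats.binom.sf(alt_families - 1, depth, background_rate) > alpha:
        reasons.append("background_noise")
    if is_germline:
        reasons.append("germline")
    return (not reasons, reasons)


def call_plasma_variants(
    calls: Iterable[ConsensusCall],
    background: BackgroundModel,
    germline: Iterable[VariantCall | VariantKey] = (),
    lod: float = 0.005,
    alpha: float = 0.01,
    ref_fn: Callable[[str, int], str] = ref_base,
    return_audit: bool = False,
):
    """Emit plasma SNVs passing duplex/LOD/background/germline gates.

    Only consensus alleles differing from the reference are candidates.
    With ``return_audit`` a list of (candidate, reasons) for rejected
    candidates is returned alongside the emitted variants.
    """
    if not 0.0 < lod < 1.0:
        raise ValueError("lod must lie in (0, 1)")
    germ_keys = {
        v.key if isinstance(v, VariantCall) else v for v in germline
    }
    germ_loci = {(k.chrom, k.pos, k.alt) for k in germ_keys}
    emitted: list[VariantCall] = []
    audit: list[tuple[ConsensusCall, list[str]]] = []
    for call in calls:
        ref = ref_fn(call.chrom, call.pos)
        if call.allele == ref:
            continue
        ok, reasons = detection_gates(
            duplex=call.duplex,
            allele_fraction=call.allele_fraction,
            alt_families=call.duplex_support,
            depth=call.consensus_depth,
            background_rate=background.rate(call.chrom, call.pos, ref, call.allele),
            is_germline=(call.chrom, call.pos, call.allele) in germ_loci,
            lod=lod,
            alpha=alpha,
        )
        if ok:
            emitted.append(
                VariantCall(
                    chrom=call.chrom,
                    pos=call.pos,
                    ref=ref,
                    alt=call.allele,
                    var_type="SNV",
                    depth=call.consensus_depth,
                    alt_reads=call.duplex_support,
                    vaf=call.allele_fraction,
                    hq_alt_reads=call.duplex_support,
                    source="plasma",
                    duplex=True,
                )
            )
        else:
            audit.append((call, reasons))
    if return_audit:
        return emitted, audit
    return emitted
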