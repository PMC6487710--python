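"""UID-tagged duplex read-family simulation.

Emulates the molecule-level structure a UMI duplex protocol produces: each
cfDNA fragment yields one read family per physical strand (top/bottom), all
members sharing a UID and fragment coordinates.  Fragment lengths follow the
bimodal cfDNA profile (mono-nucleosomal major peak at ~177 bp, a minor peak
near 322 bp).  Per-base sequencing/PCR errors are injected independently.

Read-level simulation covers SNVs; cohort-scale runs use the count-level
consensus sampling in :mod:`ctdnatrace.study` with identical detection gates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .consensus import TaggedRead
from .reference import ref_window
from .variants import VariantCall

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(slots=True)
class FragmentLengthMixture:
    """Two-component normal mixture of cfDNA fragment lengths (bp)."""

    weights: tuple[float, float] = (0.85, 0.15)
    means: tuple[float, float] = (177.0, 322.0)
    sds: tuple[float, float] = (4.0, 12.0)
    min_length: int = 100
    max_length: int = 420

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        comp = rng.random(size) >= self.weights[0]
        means = np.where(comp, self.means[1], self.means[0])
        sds = np.where(comp, self.sds[1], self.sds[0])
        lengths = np.rint(rng.normal(means, sds)).astype(int)
        return np.clip(lengths, self.min_length, self.max_length)


def poisson_plus_one(mean_extra: float = 1.5) -> Callable[[np.random.Generator], int]:
    """Family-size law: 1 + Poisson(mean_extra) members per strand."""
    return lambda rng: 1 + int(rng.poisson(mean_extra))


def simulate_read_families(
    variant: VariantCall,
    depth: int,
    family_size_law: Callable[[np.random.Generator], int] | int = 3,
    error_rate: float = 1e-3,
    fragment_length_mixture: FragmentLengthMixture | None = None,
    seed: int = 0,
    read_length: int = 160,
    base_quality: int = 37,
) -> list[TaggedRead]:
    """Simulate ``depth`` UID families of reads covering a variant locus.

    Each family is a fragment spanning the variant position; the fragment
    carries the alt allele with probability ``variant.vaf``.  Both strands of
    each family receive ``family_size_law`` reads (an int for a fixed size, or
    a callable drawing one size per strand).  Reads cover the fragment's first
    ``read_length`` bases (a merged read pair); the variant offset is drawn so
    the stored bases always cover it.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must lie in [0, 1)")
    mixture = fragment_length_mixture or FragmentLengthMixture()
    rng = np.random.default_rng(seed % (2**31 - 1))
    size_fn = (lambda _rng: family_size_law) if isinstance(family_size_law, int) \
        else family_size_law

    lengths = mixture.draw(rng, depth)
    is_alt = rng.random(depth) < variant.vaf
    quals = None
    reads: list[TaggedRead] = []
    for i in range(depth):
        frag_len = int(lengths[i])
        covered = min(frag_len, read_length)
        offset = int(rng.integers(10, max(11, covered - 10)))
        start = variant.pos - offset
        if start < 1:
            start, offset = 1, variant.pos - 1
        end = start + frag_len - 1
        template = ref_window(variant.chrom, start, start + covered - 1)
        if is_alt[i]:
            template = template[:offset] + variant.alt[0] + template[offset + 1:]
        tpl = np.frombuffer(template.encode(), dtype=np.uint8).copy()
        uid = f"{rng.integers(0, 1 << 30):08x}"
        if quals is None or len(quals) != covered:
            quals = np.full(covered, base_quality, dtype=np.int16)
        for strand in ("top", "bottom"):
            for _ in range(size_fn(rng)):
                bases = tpl
                if error_rate > 0.0:
                    err = rng.random(covered) < error_rate
                    if err.any():
                        bases = tpl.copy()
                        bases[err] = _BASES[
                            (np.searchsorted(_BASES, bases[err])
                             + rng.integers(1, 4, size=int(err.sum()))) % 4
                        ]
                reads.append(
                    TaggedRead(
                        uid=uid,
                        chrom=variant.chrom,
                        fragment_start=start,
                        fragment_end=end,
                        strand_orientation=strand,
                        bases=bases.tobytes().decode(),
                        base_qualities=quals,
                        mapping_quality=60,
                    )
                )
    return reads
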