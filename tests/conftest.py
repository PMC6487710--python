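"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ctdnatrace.filters import SiteContext
from ctdnatrace.variants import DbFlags, VariantCall


def make_snv(
    chrom: str = "syn1",
    pos: int = 123_456,
    ref: str = "A",
    alt: str = "T",
    depth: int = 800,
    alt_reads: int = 40,
    hq_alt_reads: int | None = None,
    vaf: float | None = None,
    in_dbsnp: bool = False,
    in_cosmic: bool = True,
    **kw,
) -> VariantCall:
    """A tissue SNV candidate that passes every filter rule by default."""
    return VariantCall(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        var_type="SNV",
        depth=depth,
        alt_reads=alt_reads,
        vaf=alt_reads / depth if vaf is None else vaf,
        hq_alt_reads=alt_reads if hq_alt_reads is None else hq_alt_reads,
        db_flags=DbFlags(in_dbsnp=in_dbsnp, in_cosmic=in_cosmic),
        **kw,
    )


# an 81-mer with no homopolymer run of 8 and no 2-6-mer tandem repeat of 4+
# copies (period-4 pattern ACGT... has unit copies but unit "ACGT" repeats
# would count -- so use a de-Bruijn-ish scramble checked by the naive oracle)
CLEAN_WINDOW = (
    "ACGTTGCAATCCGGATAGCTTAGCCATGGTACAGTCCTTGAACGGATCAG"
    "TCAGGCTAATCGGTTCAGATCCATGCAAGTC"
)


def clean_context(**kw) -> SiteContext:
    defaults = dict(
        indel_reads_in_window=0,
        control_alt_fraction=0.0,
        control_alt_quality_sum=0.0,
        control_indel_reads_nearby=0,
        window_sequence=CLEAN_WINDOW,
    )
    defaults.update(kw)
    return SiteContext(**defaults)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240317)
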