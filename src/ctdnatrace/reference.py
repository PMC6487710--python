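"""Deterministic synthetic reference genome.

Nothing downstream needs real genome coordinates, so the package carries a
procedurally generated reference: the base at any (contig, position) is a pure
hash of its coordinates.  This keeps the reference reproducible across
processes without shipping sequence files, and lets reads, variant records and
filter windows all agree on reference context.

Panel genes are laid out on a single synthetic contig, one 10-kb tile per
gene; mutations are drawn inside a 2-kb "exonic" window at the start of each
tile.
"""

from __future__ import annotations

import zlib

BASES = "ACGT"

#: Synthetic contigs and their lengths (1-based, inclusive coordinates).
CONTIGS: dict[str, int] = {"syn1": 2_000_000}

#: Panel gene set with per-draw weights for the mutation sampler.  The
#: weights are calibrated so that, under the cohort's mutation-count law,
#: per-patient gene prevalences land near the tissue prevalences observed in
#: breast-cancer panel studies (TP53 ~47%, PIK3CA ~40%, AKT1 ~7%, DNMT3A ~3%).
GENE_WEIGHTS: dict[str, float] = {
    "TP53": 0.225,
    "PIK3CA": 0.185,
    "GATA3": 0.055,
    "KMT2C": 0.050,
    "CDH1": 0.045,
    "MAP3K1": 0.040,
    "ARID1A": 0.040,
    "SPEN": 0.039,
    "NF1": 0.035,
    "PTEN": 0.035,
    "ERBB2": 0.030,
    "ESR1": 0.030,
    "MED12": 0.030,
    "FOXA1": 0.030,
    "AKT1": 0.029,
    "CCND1": 0.025,
    "RB1": 0.025,
    "SF3B1": 0.020,
    "CBFB": 0.020,
    "DNMT3A": 0.012,
    "JAK2": 0.010,
    "TET2": 0.010,
}

_TILE = 10_000
_EXON = 2_000

#: gene -> (contig, tile start) in deterministic alphabetical-independent
#: insertion order of GENE_WEIGHTS.
GENE_LOCI: dict[str, tuple[str, int]] = {
    gene: ("syn1", 50_000 + i * _TILE) for i, gene in enumerate(GENE_WEIGHTS)
}


def gene_window(gene: str) -> tuple[str, int, int]:
    """Contig and 1-based inclusive bounds of the mutable window for *gene*."""
    chrom, start = GENE_LOCI[gene]
    return chrom, start, start + _EXON - 1


def gene_at(chrom: str, pos: int) -> str | None:
    """Inverse lookup: which panel gene tile covers (chrom, pos), if any."""
    for gene, (c, start) in GENE_LOCI.items():
        if c == chrom and start <= pos < start + _TILE:
            return gene
    return None


def ref_base(chrom: str, pos: int) -> str:
    """Reference base at a 1-based position — a pure hash of the coordinates."""
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    return BASES[zlib.crc32(f"{chrom}:{pos}".encode()) & 3]


def ref_window(chrom: str, start: int, end: int) -> str:
    """Reference sequence over [start, end], 1-based inclusive, clipped at 1."""
    start = max(start, 1)
    if end < start:
        return ""
    return "".join(ref_base(chrom, p) for p in range(start, end + 1))
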