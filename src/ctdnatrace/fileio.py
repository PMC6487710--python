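"""File-format boundary: minimal VCF 4.2, SAM with UID tags, result tables.

In-memory coordinates are 1-based inclusive, which matches VCF directly;
SAM's 0-based POS is converted here.  The UID travels in the standard RX tag,
the duplex strand in a custom DS tag, and the fragment extent in POS/TLEN.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .consensus import TaggedRead
from .reference import CONTIGS
from .variants import DbFlags, VariantCall, classify_var_type

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Consensus family depth">
##INFO=<ID=AF,Number=1,Type=Float,Description="Allele fraction">
##INFO=<ID=AD,Number=1,Type=Integer,Description="Alternate-allele read count">
##INFO=<ID=HQ,Number=1,Type=Integer,Description="High-quality alternate reads (Q30/MQ30)">
##INFO=<ID=DUP,Number=0,Type=Flag,Description="Duplex support">
##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene">
##INFO=<ID=SRC,Number=1,Type=String,Description="Source compartment">
##INFO=<ID=DBSNP,Number=0,Type=Flag,Description="Present in dbSNP annotation">
##INFO=<ID=COSMIC,Number=0,Type=Flag,Description="Present in COSMIC annotation">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


class VcfParseError(ValueError):
    pass


def write_variants(path: str | Path, variants: Iterable[VariantCall]) -> None:
    lines = [VCF_HEADER]
    for v in variants:
        info = [
            f"DP={v.depth}", f"AF={v.vaf:.6g}", f"AD={v.alt_reads}",
            f"HQ={v.hq_alt_reads}", f"SRC={v.source}",
        ]
        if v.duplex:
            info.append("DUP")
        if v.gene:
            info.append(f"GENE={v.gene}")
        if v.db_flags.in_dbsnp:
            info.append("DBSNP")
        if v.db_flags.in_cosmic:
            info.append("COSMIC")
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{';'.join(info)}\n"
        )
    Path(path).write_text("".join(lines))


def read_variants(path: str | Path) -> list[VariantCall]:
    """Parse a minimal VCF; multi-allelic rows split into biallelic records."""
    out: list[VariantCall] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise VcfParseError(f"{path}:{lineno}: expected >= 8 columns")
        chrom, pos_s, _id, ref, alt_s = fields[:5]
        info_s = fields[7]
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise VcfParseError(f"{path}:{lineno}: bad POS {pos_s!r}") from exc
        info: dict[str, str | bool] = {}
        for item in info_s.split(";"):
            if not item or item == ".":
                continue
            key, _, val = item.partition("=")
            info[key] = val if val else True
        for alt in alt_s.split(","):
            if not alt or alt == ".":
                raise VcfParseError(f"{path}:{lineno}: empty ALT allele")
            depth = int(info.get("DP", 0))
            af = float(info.get("AF", 0.0))
            alt_reads = int(info.get("AD", round(af * depth)))
            out.append(
                VariantCall(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    var_type=classify_var_type(ref, alt),
                    depth=depth,
                    alt_reads=alt_reads,
                    vaf=af,
                    hq_alt_reads=int(info.get("HQ", 0)),
                    source=str(info.get("SRC", "tissue")),
                    db_flags=DbFlags(
                        in_dbsnp=bool(info.get("DBSNP", False)),
                        in_cosmic=bool(info.get("COSMIC", False)),
                    ),
                    gene=info.get("GENE") or None,
                    duplex=bool(info.get("DUP", False)) or None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# SAM


def _sam_header(contigs: dict[str, int] | None = None) -> dict:
    contigs = contigs or CONTIGS
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
    }


def write_reads(
    path: str | Path,
    reads: Sequence[TaggedRead],
    contigs: dict[str, int] | None = None,
) -> None:
    """Write UID-tagged reads as SAM (UID in RX, duplex strand in DS)."""
    header = _sam_header(contigs)
    ref_ids = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        for i, read in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = f"r{i:08d}"
            a.reference_id = ref_ids[read.chrom]
            a.reference_start = read.fragment_start - 1  # SAM is 0-based
            a.mapping_quality = read.mapping_quality
            a.query_sequence = read.bases
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(min(q, 60) + 33) for q in read.base_qualities)
            )
            a.cigarstring = f"{len(read.bases)}M"
            a.flag = 16 if read.strand_orientation == "bottom" else 0
            tlen = read.fragment_end - read.fragment_start + 1
            a.template_length = tlen if read.strand_orientation == "top" else -tlen
            a.set_tag("RX", read.uid)
            a.set_tag("DS", read.strand_orientation)
            sam.write(a)


def read_reads(path: str | Path) -> list[TaggedRead]:
    reads = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for a in sam:
            uid = a.get_tag("RX") if a.has_tag("RX") else ""
            strand = (
                a.get_tag("DS")
                if a.has_tag("DS")
                else ("bottom" if a.is_reverse else "top")
            )
            start = a.reference_start + 1
            tlen = abs(a.template_length) or len(a.query_sequence)
            reads.append(
                TaggedRead(
                    uid=str(uid),
                    chrom=a.reference_name,
                    fragment_start=start,
                    fragment_end=start + tlen - 1,
                    strand_orientation=str(strand),
                    bases=a.query_sequence,
                    base_qualities=list(a.query_qualities),
                    mapping_quality=a.mapping_quality,
                )
            )
    return reads
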