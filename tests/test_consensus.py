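"""Duplex consensus calling, background model, and detection gates."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from ctdnatrace.consensus import (
    BackgroundModel,
    ConsensusCall,
    ReadFamily,
    TaggedRead,
    build_background,
    call_plasma_variants,
    consensus_pileup,
    detection_gates,
    family_consensus,
    group_families,
)
from ctdnatrace.readsim import simulate_read_families
from ctdnatrace.reference import ref_base, ref_window
from ctdnatrace.study import StudyParams, detect_plasma_from_counts
from ctdnatrace.variants import VariantCall, VariantKey


def read(uid="u1", start=100, end=260, strand="top", bases="ACGT", quals=None):
    return TaggedRead(
        uid=uid, chrom="syn1", fragment_start=start, fragment_end=end,
        strand_orientation=strand, bases=bases,
        base_qualities=quals if quals is not None else [37] * len(bases),
    )


# ---------------------------------------------------------------------------
# family grouping


def test_group_families_empty():
    assert group_families([]) == []


def test_group_families_exact_key_and_strand_split():
    reads = [
        read(uid="a", strand="top"),
        read(uid="a", strand="top"),
        read(uid="a", strand="bottom"),
        read(uid="a", start=101, end=261),   # different fragment -> new family
        read(uid="b"),
    ]
    fams = {f.family_key: f for f in group_families(reads)}
    assert len(fams) == 3
    fam = fams[("a", "syn1", 100, 260)]
    assert len(fam.top_members) == 2 and len(fam.bottom_members) == 1
    assert fam.size == 3


def test_group_families_counts_missing_uid():
    reads = [read(), read(uid=""), read(uid="")]
    with pytest.warns(UserWarning, match="2 reads"):
        fams = group_families(reads)
    assert sum(f.size for f in fams) == 1


def test_grouping_partitions_simulated_reads():
    var = VariantCall("syn1", 700_000, ref_base("syn1", 700_000),
                      "A" if ref_base("syn1", 700_000) != "A" else "C", vaf=0.2)
    reads = simulate_read_families(var, depth=300, seed=3)
    fams = group_families(reads)
    assert sum(f.size for f in fams) == len(reads)
    assert len(fams) == 300


# ---------------------------------------------------------------------------
# family consensus


def test_unanimous_duplex_consensus():
    fam = ReadFamily(
        family_key=("u", "syn1", 10, 13),
        top_members=[read(start=10, end=13, bases="ACGT") for _ in range(3)],
        bottom_members=[read(start=10, end=13, strand="bottom", bases="ACGT")
                        for _ in range(3)],
    )
    cons = family_consensus(fam)
    assert cons == {
        10: ("A", "A", "A"), 11: ("C", "C", "C"),
        12: ("G", "G", "G"), 13: ("T", "T", "T"),
    }


def test_strand_disagreement_voids_duplex_at_that_position():
    fam = ReadFamily(
        family_key=("u", "syn1", 10, 13),
        top_members=[read(start=10, end=13, bases="ACGT")],
        bottom_members=[read(start=10, end=13, strand="bottom", bases="ACGA")],
    )
    cons = family_consensus(fam)
    assert cons[12] == ("G", "G", "G")
    assert cons[13] == ("T", "A", None)


def test_min_members_per_strand_gate():
    fam = ReadFamily(
        family_key=("u", "syn1", 10, 13),
        top_members=[read(start=10, end=13, bases="ACGT") for _ in range(2)],
        bottom_members=[read(start=10, end=13, strand="bottom", bases="ACGT")],
    )
    cons = family_consensus(fam, min_members_per_strand=2)
    # bottom strand has too few members: consensus exists for top only
    assert all(b is None and d is None for _, b, d in cons.values())
    assert [t for t, _, _ in cons.values()] == list("ACGT")
    with pytest.raises(ValueError):
        family_consensus(fam, min_members_per_strand=0)


def test_majority_vote_with_quality_tiebreak():
    top = [
        read(start=10, end=10, bases="A", quals=[20]),
        read(start=10, end=10, bases="C", quals=[40]),
    ]
    fam = ReadFamily(family_key=("u", "syn1", 10, 10), top_members=top)
    cons = family_consensus(fam)
    assert cons[10][0] == "C"  # 1-1 count tie broken by base quality
    # ... but a count majority beats any quality imbalance
    fam.top_members.append(read(start=10, end=10, bases="A", quals=[2]))
    assert family_consensus(fam)[10][0] == "A"


def test_n_bases_yield_no_call():
    fam = ReadFamily(
        family_key=("u", "syn1", 10, 11),
        top_members=[read(start=10, end=11, bases="NA")],
        bottom_members=[read(start=10, end=11, strand="bottom", bases="NA")],
    )
    cons = family_consensus(fam)
    assert cons[10] == (None, None, None)
    assert cons[11] == ("A", "A", "A")


# ---------------------------------------------------------------------------
# pileup


def test_pileup_counts_duplex_and_strand_support_exactly():
    def fam(uid, top_base, bottom_base):
        return ReadFamily(
            family_key=(uid, "syn1", 10, 10),
            top_members=[read(uid=uid, start=10, end=10, bases=top_base)],
            bottom_members=[read(uid=uid, start=10, end=10, strand="bottom",
                                 bases=bottom_base)],
        )

    fams = [fam("a", "T", "T"), fam("b", "T", "T"), fam("c", "A", "A"),
            fam("d", "T", "A")]  # d: strands disagree, not duplex-evaluable
    calls = {c.allele: c for c in consensus_pileup(fams)}
    assert calls["T"].top_support == 3
    assert calls["T"].bottom_support == 2
    assert calls["T"].duplex_support == 2
    assert calls["T"].consensus_depth == 3  # a, b, c (d has no duplex allele)
    assert calls["T"].allele_fraction == pytest.approx(2 / 3)
    assert calls["A"].duplex_support == 1
    assert calls["T"].duplex and calls["A"].duplex


def test_allele_fraction_zero_depth():
    call = ConsensusCall("syn1", 1, "A", top_support=1, bottom_support=0,
                         consensus_depth=0)
    assert call.allele_fraction == 0.0
    assert not call.duplex


# ---------------------------------------------------------------------------
# background model


def test_build_background_requires_controls():
    with pytest.raises(ValueError, match="null"):
        build_background([])


def test_background_site_rate_closed_form():
    chrom, pos = "syn1", 900_000
    ref = ref_base(chrom, pos)
    alt = next(b for b in "ACGT" if b != ref)
    control = [
        ConsensusCall(chrom, pos, ref, 997, 997, 1000, duplex_support=997),
        ConsensusCall(chrom, pos, alt, 3, 3, 1000, duplex_support=3),
    ]
    bg = build_background([control], pseudocount=0.5)
    assert bg.rate(chrom, pos, ref, alt) == pytest.approx(3.5 / 1001)
    # pooled substitution-class fallback: 997 ref + 3 alt families in class
    assert bg.class_rates[(ref, alt)] == pytest.approx(3.5 / 1001)


def test_clean_controls_floor_rate():
    chrom, pos = "syn1", 900_010
    ref = ref_base(chrom, pos)
    control = [ConsensusCall(chrom, pos, ref, 500, 500, 500, duplex_support=500)]
    bg = build_background([control])
    for alt in "ACGT":
        if alt != ref:
            assert bg.rate(chrom, pos, ref, alt) == pytest.approx(0.5 / 501)


def test_null_model_flat_floor():
    bg = BackgroundModel.null(floor=1e-4)
    assert bg.rate("syn1", 1, "A", "T") == 1e-4


# ---------------------------------------------------------------------------
# detection gates


def test_detection_gates_individual_reasons():
    common = dict(depth=1000, background_rate=1e-4, is_germline=False)
    ok, reasons = detection_gates(True, 0.02, 20, **common)
    assert ok and reasons == []
    _, r = detection_gates(False, 0.02, 20, **common)
    assert r == ["no_duplex_support"]
    _, r = detection_gates(True, 0.004, 4, **common)
    assert "below_lod" in r
    _, r = detection_gates(True, 0.002, 2, depth=1000, background_rate=1e-3,
                           is_germline=False, lod=0.001)
    assert r == ["background_noise"]  # 2 alt at rate 1e-3 is not significant
    _, r = detection_gates(True, 0.02, 20, depth=1000, background_rate=1e-4,
                           is_germline=True)
    assert r == ["germline"]


def test_af_exactly_at_lod_passes():
    ok, reasons = detection_gates(True, 0.005, 5, depth=1000,
                                  background_rate=1e-4, is_germline=False)
    assert ok, reasons


def test_binomial_gate_matches_summed_pmf_oracle():
    depth, rate, alpha = 60, 0.05, 0.01
    for alt in range(0, 15):
        tail = sum(sps.binom.pmf(k, depth, rate) for k in range(alt, depth + 1))
        _, reasons = detection_gates(
            True, 0.5, alt, depth=depth, background_rate=rate,
            is_germline=False, lod=1e-6, alpha=alpha,
        )
        assert ("background_noise" in reasons) == (tail > alpha), alt


# ---------------------------------------------------------------------------
# calling


def _call(pos, allele, dup, depth=1000):
    return ConsensusCall("syn1", pos, allele, dup, dup, depth,
                         duplex_support=dup)


def test_reference_alleles_are_never_candidates():
    pos = 910_000
    ref = ref_base("syn1", pos)
    out = call_plasma_variants([_call(pos, ref, 500)], BackgroundModel.null())
    assert out == []


def test_call_emits_and_audits():
    pos = 910_001
    ref = ref_base("syn1", pos)
    alts = [b for b in "ACGT" if b != ref]
    low_pos = pos + 2
    low_alt = next(b for b in "ACGT" if b != ref_base("syn1", low_pos))
    calls = [_call(pos, alts[0], 30), _call(low_pos, low_alt, 2)]
    emitted, audit = call_plasma_variants(
        calls, BackgroundModel.null(), return_audit=True
    )
    assert [v.key for v in emitted] == [VariantKey("syn1", pos, ref, alts[0])]
    assert emitted[0].vaf == pytest.approx(0.03)
    assert len(audit) == 1 and "below_lod" in audit[0][1]


def test_germline_variants_are_suppressed():
    pos = 910_010
    ref = ref_base("syn1", pos)
    alt = next(b for b in "ACGT" if b != ref)
    call = _call(pos, alt, 50)
    assert call_plasma_variants([call], BackgroundModel.null()) != []
    germ = [VariantKey("syn1", pos, ref, alt)]
    assert call_plasma_variants([call], BackgroundModel.null(), germ) == []


def test_emission_monotone_in_lod_and_alpha(rng):
    bg = BackgroundModel.null()
    calls = []
    for _ in range(200):
        pos = int(rng.integers(800_000, 801_000))
        ref = ref_base("syn1", pos)
        alt = rng.choice([b for b in "ACGT" if b != ref])
        calls.append(_call(pos, str(alt), int(rng.integers(0, 30)),
                           depth=int(rng.integers(500, 1500))))
    keyset = lambda lod, alpha: {
        v.key for v in call_plasma_variants(calls, bg, lod=lod, alpha=alpha)
    }
    assert keyset(0.01, 0.01) <= keyset(0.005, 0.01)
    assert keyset(0.005, 0.001) <= keyset(0.005, 0.01)
    with pytest.raises(ValueError):
        call_plasma_variants(calls, bg, lod=1.5)


def test_read_level_variant_recovery():
    pos = 920_000
    ref = ref_base("syn1", pos)
    alt = next(b for b in "ACGT" if b != ref)
    var = VariantCall("syn1", pos, ref, alt, vaf=0.10)
    reads = simulate_read_families(var, depth=400, error_rate=1e-3, seed=11)
    pileup = consensus_pileup(group_families(reads))
    emitted = call_plasma_variants(pileup, BackgroundModel.null())
    assert [v.key for v in emitted] == [var.key]
    tol = 5.0 * np.sqrt(0.1 * 0.9 / 400)
    assert abs(emitted[0].vaf - 0.10) < tol


def test_lod_characterization():
    """With a hard AF >= LOD gate the caller detects ~half of variants whose
    true fraction sits exactly at the LOD, >= 90% at 1.5x the LOD, and almost
    none well below it."""
    params = StudyParams(consensus_depth=2000)
    bg = BackgroundModel.null(floor=params.background_floor)
    rng = np.random.default_rng(77)
    pos = 930_000
    ref = ref_base("syn1", pos)
    alt = next(b for b in "ACGT" if b != ref)

    def detect_fraction(true_af: float, reps: int = 500) -> float:
        truth = [VariantCall("syn1", pos, ref, alt, vaf=true_af)] * reps
        return len(detect_plasma_from_counts(truth, params, bg, rng)) / reps

    assert abs(detect_fraction(0.005) - 0.54) < 0.10
    assert detect_fraction(0.0075) >= 0.88
    assert detect_fraction(0.002) <= 0.05
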