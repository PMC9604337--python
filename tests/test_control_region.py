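"""Microsatellite, tandem-repeat and stem-loop detection."""
import numpy as np
import pytest

from mitocomp import (GenomeSpec, find_microsatellites, find_stem_loops,
                      find_tandem_repeats, generate_genome,
                      planted_cr_coordinates, scan_control_region)
from mitocomp.control_region import reconstruct_repeat

TANDEM_MOTIF = "ATATAATTAAATATTTAA"  # 18 bp


# --------------------------------------------------------------------------
# microsatellites

def test_microsatellite_hand_example():
    # GG TATATATA GG: motif TA, canonical rotation AT, period 2, copies 4
    hits = find_microsatellites("GGTATATATAGG", min_copies=3)
    assert len(hits) == 1
    h = hits[0]
    assert (h.motif, h.period, h.copies, h.start, h.end) == ("AT", 2, 4.0, 3, 10)
    assert h.identity == 1.0


def test_homopolymer_reported_only_at_period_one():
    hits = find_microsatellites("CCAAAAAACC", min_copies=3)
    assert len(hits) == 1
    assert hits[0].period == 1 and hits[0].motif == "A" and hits[0].copies == 6.0


def test_microsatellite_none_below_min_copies():
    assert find_microsatellites("GGTATAGG", min_copies=3) == []


def test_microsatellite_overlap_suppression_keeps_longest():
    hits = find_microsatellites("ATATATATAT", min_copies=3)
    assert len(hits) == 1
    assert hits[0].period == 2 and hits[0].copies == 5.0


# --------------------------------------------------------------------------
# tandem repeats

def test_tandem_repeat_planted_in_neutral_flanks():
    seq = "G" * 20 + TANDEM_MOTIF * 2 + TANDEM_MOTIF[:5] + "G" * 20
    hits = find_tandem_repeats(seq)
    assert len(hits) == 1
    h = hits[0]
    assert h.period == 18
    assert h.start == 21 and h.end == 61
    assert h.copies == pytest.approx(41 / 18)
    assert h.identity == 1.0
    assert reconstruct_repeat(h) == TANDEM_MOTIF * 2 + TANDEM_MOTIF[:5]


def test_tandem_repeat_tolerates_one_mismatch():
    copy2 = TANDEM_MOTIF[:7] + "C" + TANDEM_MOTIF[8:]
    seq = "G" * 20 + TANDEM_MOTIF + copy2 + "G" * 20
    hits = find_tandem_repeats(seq, min_copies=1.9)
    assert len(hits) == 1
    assert hits[0].period == 18
    assert hits[0].identity == pytest.approx(17 / 18)


def test_tandem_repeat_min_matches_floor():
    # two copies of a 10-mer: 10 aligned matches < min_matches 16 -> rejected
    motif = "ACGGTACGTC"
    seq = "T" * 20 + motif * 2 + "T" * 20
    assert find_tandem_repeats(seq, min_matches=16) == []
    assert len(find_tandem_repeats(seq, min_matches=10)) == 1


def test_tandem_repeat_leaves_microsatellites_alone():
    seq = "G" * 10 + "AT" * 30 + "G" * 10
    assert find_tandem_repeats(seq) == []


def test_tandem_repeat_min_period_guard():
    with pytest.raises(ValueError):
        find_tandem_repeats("ACGT" * 30, min_period=2)


def test_no_hits_on_trivial_sequences():
    assert find_tandem_repeats("ACGT") == []
    assert find_microsatellites("ACGT") == []
    assert find_stem_loops("ACGT") == []


# --------------------------------------------------------------------------
# stem-loops

def test_stem_loop_hand_example():
    # GGGGG TTTTCTCTTT CCCCC: stem 5 (all GC), loop carries T+(TC)(TC)T+
    hits = find_stem_loops("GGGGGTTTTCTCTTTCCCCC")
    assert len(hits) == 1
    h = hits[0]
    assert h.stem_len == 5 and h.mismatches == 0
    assert h.loop_seq == "TTTTCTCTTT"
    assert h.motif_match
    assert (h.arm5_start, h.arm5_end, h.arm3_start, h.arm3_end) == (1, 5, 16, 20)


def test_stem_loop_none_in_homopolymer():
    assert find_stem_loops("A" * 30) == []


def test_stem_loop_terminal_mismatches_are_trimmed():
    # arms pair only over the inner 5 bp; outer bases do not pair
    seq = "TTGGGGGAAACGAAACCCCCTT"
    hits = find_stem_loops(seq, min_stem=5, max_mismatch=0)
    assert hits
    for h in hits:
        assert h.mismatches == 0


def test_stem_loop_mismatch_budget():
    # one internal non-complementary pair allowed, two rejected
    stem5 = "GCGCG"
    loop = "TTTAAATT"
    perfect = stem5 + loop + "CGCGC"
    one_mm = "GAGCG" + loop + "CGCGC"  # A-G pair inside the stem
    assert any(h.mismatches == 0 for h in find_stem_loops(perfect))
    hits1 = find_stem_loops(one_mm, max_mismatch=1)
    assert any(h.stem_len == 5 and h.mismatches == 1 for h in hits1)
    hits0 = find_stem_loops(one_mm, max_mismatch=0)
    assert not any(h.stem_len >= 5 for h in hits0)


def test_loop_motif_requires_flanking_ts():
    hits = find_stem_loops("GGGGGAAGCAGCAACCCCC")
    assert hits and not any(h.motif_match for h in hits)


# --------------------------------------------------------------------------
# scan_control_region against generator ground truth

def test_scan_control_region_recovers_planted_motifs(synthetic_genome):
    spec = GenomeSpec(seed=0)
    truth = planted_cr_coordinates(spec)
    hits = scan_control_region(synthetic_genome)

    ms_s, ms_e = truth["microsatellite"]
    assert any(h.period == 2 and h.start <= ms_s and h.end >= ms_e
               for h in hits["microsatellites"])

    tr_s, tr_e = truth["tandem_repeat"]
    tandem = [h for h in hits["tandem_repeats"]
              if h.period == 18 and h.start <= tr_s and h.end >= tr_e]
    assert len(tandem) == 1
    assert tandem[0].copies >= 2.2

    sl_s, sl_e = truth["stem_loop"]
    assert any(h.motif_match and h.arm5_start <= sl_s and h.arm3_end >= sl_e
               for h in hits["stem_loops"])


def test_scan_control_region_requires_cr_annotation():
    from mitocomp import GeneFeature, MitogenomeRecord
    rec = MitogenomeRecord(
        id="r", length=12, sequence="ACGTACGTACGT",
        features=[GeneFeature(name="trnK", gene_class="tRNA", start=1, end=12)])
    with pytest.raises(KeyError):
        scan_control_region(rec)


def test_planted_hairpin_sits_near_cr_three_prime_end():
    spec = GenomeSpec(seed=3)
    truth = planted_cr_coordinates(spec)
    cr_len = 863
    assert cr_len - truth["stem_loop"][1] <= 50
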