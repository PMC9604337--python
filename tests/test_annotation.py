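"""Junction gaps, spacer/overlap accounting, strand census, codon classes."""
import pytest

from mitocomp import (GeneFeature, MitogenomeRecord, classify_codons,
                      junction_gaps, partition_regions, shared_junctions,
                      spacer_overlap_report, strand_census)
from mitocomp.model import MitocompError


def _rec(coords, length, names=None, classes=None):
    feats = []
    for i, (s, e) in enumerate(coords):
        feats.append(GeneFeature(
            name=(names[i] if names else f"g{i + 1}"),
            gene_class=(classes[i] if classes else "tRNA"),
            start=s, end=e))
    return MitogenomeRecord(id="toy", length=length, features=feats)


def test_junction_gaps_toy_including_wrap():
    # g1 1..10, g2 12..20, g3 18..30 on a length-35 circle
    rec = _rec([(1, 10), (12, 20), (18, 30)], 35)
    gaps = junction_gaps(rec)
    assert [(g.upstream, g.downstream, g.ign) for g in gaps] == [
        ("g1", "g2", 1),     # 12 - 10 - 1
        ("g2", "g3", -3),    # 18 - 20 - 1: 3-bp overlap
        ("g3", "g1", 5),     # (35 - 30) + 1 - 1: wrap across the origin
    ]


def test_junction_gaps_requires_circle_order():
    rec = _rec([(12, 20), (1, 10)], 35)
    with pytest.raises(MitocompError):
        junction_gaps(rec)


def test_telescoping_identity_on_toy():
    rec = _rec([(1, 10), (12, 20), (18, 30)], 35)
    spans = sum(f.span(rec.length) for f in rec.features)
    igns = sum(g.ign for g in junction_gaps(rec))
    assert spans + igns == rec.length


def test_telescoping_identity_on_all_bundled_tables(all_refs):
    """Sum of spans plus sum of coordinate-derived IGNs closes the circle."""
    for key, rec in all_refs.items():
        spans = sum(f.span(rec.length) for f in rec.features)
        igns = sum(g.ign for g in junction_gaps(rec))
        assert spans + igns == rec.length, key


def test_declared_ign_overrides_coordinates():
    feats = [
        GeneFeature(name="a", gene_class="tRNA", start=1, end=10),
        GeneFeature(name="b", gene_class="tRNA", start=12, end=20,
                    declared_ign=-1),
    ]
    rec = MitogenomeRecord(id="toy", length=25, features=feats)
    coords = junction_gaps(rec)
    declared = junction_gaps(rec, use_declared_ign=True)
    assert coords[0].ign == 1
    assert declared[0].ign == -1


def test_spacer_overlap_report_zero_gaps_count_as_neither():
    rec = _rec([(1, 10), (11, 20), (22, 30)], 30)  # gaps 0, 1, wrap 0
    rep = spacer_overlap_report(rec)
    assert rep.spacer_count == 1
    assert rep.spacer_total_bp == 1
    assert rep.overlap_count == 0
    assert rep.overlap_max_bp is None


def test_spacer_overlap_report_excludes_cr_junctions_by_default():
    rec = _rec([(1, 10), (16, 25), (26, 30)], 30,
               names=["g1", "g2", "CR"], classes=["tRNA", "tRNA", "CR"])
    default = spacer_overlap_report(rec)
    # only the g1-g2 junction (+5) remains; CR-adjacent junctions are out
    assert (default.spacer_count, default.spacer_total_bp) == (1, 5)
    everything = spacer_overlap_report(rec, include_cr_junctions=True)
    assert len(everything.gaps) == 3


def test_strand_census_henana(henana):
    assert strand_census(henana) == {"J": 23, "N": 14}


def test_strand_census_excludes_control_region(henana):
    assert sum(strand_census(henana).values()) == len(henana.genes()) == 37


def test_classify_codons_complete_and_incomplete_stops():
    # cox1: ATG ... TAA (complete); cox2 ends on a lone T (incomplete stop)
    seq = "ATGAAATAA" + "ATTCCCT" + "GGGG"
    feats = [
        GeneFeature(name="cox1", gene_class="PCG", start=1, end=9),
        GeneFeature(name="cox2", gene_class="PCG", start=10, end=16),
    ]
    rec = MitogenomeRecord(id="toy", length=len(seq), sequence=seq, features=feats)
    cls = {c.gene: c for c in classify_codons(rec)}
    assert cls["cox1"].start_codon == "ATG" and cls["cox1"].start_typical
    assert cls["cox1"].stop_codon == "TAA" and cls["cox1"].stop_complete
    assert cls["cox2"].start_codon == "ATT" and cls["cox2"].start_typical
    assert cls["cox2"].stop_codon == "T" and not cls["cox2"].stop_complete


def test_classify_codons_atypical_start():
    seq = "GTGAAATAA"
    rec = MitogenomeRecord(
        id="toy", length=9, sequence=seq,
        features=[GeneFeature(name="cox1", gene_class="PCG", start=1, end=9)])
    (c,) = classify_codons(rec)
    assert c.start_codon == "GTG" and not c.start_typical


def test_shared_junctions_toy():
    r1 = _rec([(1, 10), (12, 20), (19, 30)], 32)   # gaps: +1, -2, wrap +2
    r2 = _rec([(1, 12), (14, 20), (19, 28)], 30)   # gaps: +1, -2, wrap +2
    shared = shared_junctions([r1, r2])
    assert [(g.upstream, g.ign) for g in shared["spacers"]] == [("g1", 1), ("g3", 2)]
    assert [(g.upstream, g.ign) for g in shared["overlaps"]] == [("g2", -2)]


def test_shared_junctions_rejects_different_gene_orders():
    r1 = _rec([(1, 10), (12, 20)], 25, names=["a", "b"])
    r2 = _rec([(1, 10), (12, 20)], 25, names=["b", "a"])
    with pytest.raises(MitocompError):
        shared_junctions([r1, r2])


def test_partition_regions_codon_positions():
    # Two J-strand PCGs "ATGAAATAA" and "ATGCCCTAA": first positions of the
    # codons {ATG, AAA, TAA, ATG, CCC, TAA} spell "AATACT".
    seq = "ATGAAATAA" + "ATGCCCTAA"
    feats = [
        GeneFeature(name="nad2", gene_class="PCG", start=1, end=9),
        GeneFeature(name="cox1", gene_class="PCG", start=10, end=18),
    ]
    rec = MitogenomeRecord(id="toy", length=18, sequence=seq, features=feats)
    with pytest.warns(UserWarning, match="no control region"):
        part = partition_regions(rec)
    assert part.codon_pos1 == "AATACT"
    assert part.codon_pos2 == "TAATCA"
    assert part.codon_pos3 == "GAAGCA"
    assert part.pcgs_concat == seq
    assert part.cr is None


def test_partition_regions_trims_trailing_incomplete_codon():
    seq = "ATGAAAT" + "GGG"  # 7-nt PCG: trailing T dropped from codon split
    feats = [GeneFeature(name="cox3", gene_class="PCG", start=1, end=7),
             GeneFeature(name="CR", gene_class="CR", start=8, end=10)]
    rec = MitogenomeRecord(id="toy", length=10, sequence=seq, features=feats)
    part = partition_regions(rec)
    assert part.codon_pos1 == "AA"
    assert part.codon_pos2 == "TA"
    assert part.codon_pos3 == "GA"
    assert part.pcgs_concat == "ATGAAAT"  # full sequence still reported
    assert part.cr == "GGG"
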