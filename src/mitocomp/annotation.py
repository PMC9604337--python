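"""Statistics derived from the feature table alone.

Junction gaps (IGN — intergenic nucleotides, negative = overlap), spacer and
overlap accounting, strand census, start/stop codon classification, and the
partitioning of the genome into the regions used for composition reporting
(PCGs, codon positions 1-3, tRNAs, rRNAs, control region).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

from .io import extract_region
from .model import GeneFeature, MitocompError, MitogenomeRecord

TYPICAL_STARTS = {"ATA", "ATT", "ATG", "ATC"}
COMPLETE_STOPS = {"TAA", "TAG"}


@dataclass(frozen=True)
class JunctionGap:
    """Signed gap between two adjacent features around the circle."""
    upstream: str
    downstream: str
    ign: int


@dataclass
class SpacerOverlapReport:
    gaps: list[JunctionGap]
    spacer_count: int
    spacer_total_bp: int
    spacer_min_bp: int | None
    spacer_max_bp: int | None
    overlap_count: int
    overlap_total_bp: int
    overlap_max_bp: int | None


@dataclass(frozen=True)
class CodonClassification:
    gene: str
    start_codon: str
    start_typical: bool
    stop_codon: str
    stop_complete: bool


@dataclass
class RegionPartition:
    pcgs_concat: str
    codon_pos1: str
    codon_pos2: str
    codon_pos3: str
    trnas_concat: str
    rrnas_concat: str
    cr: str | None


def _check_sorted(features: list[GeneFeature]) -> None:
    starts = [f.start for f in features]
    if starts != sorted(starts):
        raise MitocompError(
            "features are not in circle order; sort by start coordinate first")


def junction_gaps(record: MitogenomeRecord,
                  use_declared_ign: bool = False) -> list[JunctionGap]:
    """One signed gap per adjacent feature pair, wrap junction included.

    ign = downstream.start - upstream.end - 1; the final junction wraps the
    last feature back to the first across the origin.  With
    ``use_declared_ign`` the IGN values carried on the features (e.g. a
    published table's own IGN column) replace the coordinate-derived values
    where present.
    """
    feats = record.features
    if len(feats) < 2:
        return []
    _check_sorted(feats)
    gaps = []
    for f, g in zip(feats, feats[1:]):
        ign = g.start - f.end - 1
        if use_declared_ign and g.declared_ign is not None:
            ign = g.declared_ign
        gaps.append(JunctionGap(f.name, g.name, ign))
    last, first = feats[-1], feats[0]
    wrap = (record.length - last.end) + first.start - 1
    if use_declared_ign and first.declared_ign is not None:
        wrap = first.declared_ign
    gaps.append(JunctionGap(last.name, first.name, wrap))
    return gaps


def spacer_overlap_report(record: MitogenomeRecord,
                          include_cr_junctions: bool = False,
                          use_declared_ign: bool = False) -> SpacerOverlapReport:
    """Aggregate spacers (positive gaps) and overlaps (negative gaps).

    Zero-length junctions count as neither.  Junctions where either side is
    the control region are excluded by default: published spacer/overlap
    totals count only inter-gene junctions and treat the CR separately.
    """
    cr_names = {f.name for f in record.features if f.gene_class == "CR"}
    gaps = junction_gaps(record, use_declared_ign=use_declared_ign)
    if not include_cr_junctions:
        gaps = [g for g in gaps if g.upstream not in cr_names
                and g.downstream not in cr_names]
    spacers = [g.ign for g in gaps if g.ign > 0]
    overlaps = [-g.ign for g in gaps if g.ign < 0]
    return SpacerOverlapReport(
        gaps=gaps,
        spacer_count=len(spacers),
        spacer_total_bp=sum(spacers),
        spacer_min_bp=min(spacers) if spacers else None,
        spacer_max_bp=max(spacers) if spacers else None,
        overlap_count=len(overlaps),
        overlap_total_bp=sum(overlaps),
        overlap_max_bp=max(overlaps) if overlaps else None,
    )


def strand_census(record: MitogenomeRecord) -> dict[str, int]:
    """Gene counts per coding strand (control region excluded)."""
    census = {"J": 0, "N": 0}
    for f in record.genes():
        census[f.strand] += 1
    return census


def classify_codons(record: MitogenomeRecord) -> list[CodonClassification]:
    """Start/stop codon classification of every protein-coding gene.

    The start codon is the first triplet of the coding-strand sequence; the
    stop is a trailing TAA/TAG when the length is a multiple of three, else
    the trailing TA or T left by an incomplete stop (completed to TAA by
    polyadenylation of the mRNA).
    """
    out = []
    for f in record.features:
        if f.gene_class != "PCG":
            continue
        seq = extract_region(record, f)
        if len(seq) < 6:
            raise MitocompError(f"{f.name}: PCG shorter than 6 nt")
        start = seq[:3]
        rem = len(seq) % 3
        if rem == 0:
            tail = seq[-3:]
            if tail in COMPLETE_STOPS:
                stop, complete = tail, True
            else:
                stop, complete = tail, False
        else:
            stop, complete = seq[-rem:], False
        out.append(CodonClassification(
            gene=f.name, start_codon=start,
            start_typical=start in TYPICAL_STARTS,
            stop_codon=stop, stop_complete=complete))
    return out


def shared_junctions(records: list[MitogenomeRecord],
                     use_declared_ign: bool = False) -> dict[str, list[JunctionGap]]:
    """Junctions with identical nonzero IGN in every record.

    Returns ``{"overlaps": [...], "spacers": [...]}`` keyed by sign; requires
    all records to share the gene order.
    """
    if not records:
        raise MitocompError("no records supplied")
    all_gaps = [junction_gaps(r, use_declared_ign=use_declared_ign)
                for r in records]
    orders = {tuple((g.upstream, g.downstream) for g in gaps) for gaps in all_gaps}
    if len(orders) > 1:
        raise MitocompError("records differ in gene order; junctions not comparable")
    overlaps, spacers = [], []
    for column in zip(*all_gaps):
        values = {g.ign for g in column}
        if len(values) == 1:
            v = values.pop()
            if v < 0:
                overlaps.append(column[0])
            elif v > 0:
                spacers.append(column[0])
    return {"overlaps": overlaps, "spacers": spacers}


#: circle order of the 13 protein-coding genes in the ancestral insect arrangement
PCG_ORDER = ("nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
             "nad5", "nad4", "nad4L", "nad6", "cytb", "nad1")


def partition_regions(record: MitogenomeRecord) -> RegionPartition:
    """Concatenated region sequences for composition reporting.

    Every gene is read 5'->3' on its coding strand; PCGs are concatenated in
    circle order with any trailing incomplete codon trimmed before codon
    positions are split, so the three codon-position strings are equal length.
    """
    pcgs, trnas, rrnas = [], [], []
    pos = {1: [], 2: [], 3: []}
    cr_seq = None
    for f in record.features:
        if f.gene_class == "CR":
            cr_seq = extract_region(record, f)
            continue
        seq = extract_region(record, f)
        if f.gene_class == "PCG":
            pcgs.append(seq)
            trimmed = seq[:len(seq) - len(seq) % 3]
            for i in (1, 2, 3):
                pos[i].append(trimmed[i - 1::3])
        elif f.gene_class == "tRNA":
            trnas.append(seq)
        elif f.gene_class == "rRNA":
            rrnas.append(seq)
    if cr_seq is None:
        warnings.warn(f"{record.id}: no control region annotated", stacklevel=2)
    return RegionPartition(
        pcgs_concat="".join(pcgs),
        codon_pos1="".join(pos[1]),
        codon_pos2="".join(pos[2]),
        codon_pos3="".join(pos[3]),
        trnas_concat="".join(trnas),
        rrnas_concat="".join(rrnas),
        cr=cr_seq,
    )
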