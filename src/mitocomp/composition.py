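"""Base composition and strand-asymmetry (skew) statistics.

AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C), computed on the
strand the region is read on: the J strand for the whole genome, the coding
strand for gene regions.  IUPAC ambiguity codes and gaps are excluded from
every numerator and denominator.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .annotation import partition_regions
from .model import MitocompError, MitogenomeRecord


@dataclass
class CompositionSummary:
    counts: dict[str, int]
    at_content: float          # percent of A+T among A+C+G+T
    at_skew: float | None      # None when A+T = 0
    gc_skew: float | None      # None when G+C = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def composition(seq: str) -> CompositionSummary:
    """Composition summary of one sequence (full precision, no rounding)."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise MitocompError("sequence contains no unambiguous A/C/G/T")
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    at_skew = (a - t) / (a + t) if a + t else None
    gc_skew = (g - c) / (g + c) if g + c else None
    return CompositionSummary(counts=counts,
                              at_content=100.0 * (a + t) / total,
                              at_skew=at_skew, gc_skew=gc_skew)


REGION_ROWS = ("Whole genome", "PCGs", "1st codon position",
               "2nd codon position", "3rd codon position",
               "tRNAs", "rRNAs", "CR")


def composition_by_region(record: MitogenomeRecord,
                          rounded: bool = False) -> pd.DataFrame:
    """Composition table with one row per genomic region.

    Gene regions are concatenations of coding-strand sequences; the whole
    genome is the J strand.  With ``rounded`` the report mirrors the usual
    published precision (one decimal for percent, three for skews).
    """
    if record.sequence is None:
        raise MitocompError(f"{record.id}: composition needs the sequence")
    part = partition_regions(record)
    regions = {
        "Whole genome": record.sequence,
        "PCGs": part.pcgs_concat,
        "1st codon position": part.codon_pos1,
        "2nd codon position": part.codon_pos2,
        "3rd codon position": part.codon_pos3,
        "tRNAs": part.trnas_concat,
        "rRNAs": part.rrnas_concat,
        "CR": part.cr,
    }
    rows = []
    for name in REGION_ROWS:
        seq = regions[name]
        if not seq:
            warnings.warn(f"{record.id}: region {name!r} missing; row omitted",
                          stacklevel=2)
            continue
        summ = composition(seq)
        rows.append({
            "region": name,
            "size_bp": summ.total,
            "at_content": summ.at_content,
            "at_skew": summ.at_skew,
            "gc_skew": summ.gc_skew,
        })
    table = pd.DataFrame(rows).set_index("region")
    if rounded:
        table["at_content"] = table["at_content"].round(1)
        table["at_skew"] = table["at_skew"].round(3)
        table["gc_skew"] = table["gc_skew"].round(3)
    return table
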