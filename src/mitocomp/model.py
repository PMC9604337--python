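"""Core data model for annotated circular mitochondrial genomes.

Coordinates are 1-based inclusive throughout, as in published gene tables;
conversion to Python's 0-based half-open slices happens only at the I/O and
extraction boundary.  Strands are labelled J (majority / annotated forward
strand) and N (minority / complement).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

GENE_CLASSES = ("PCG", "tRNA", "rRNA", "CR")
STRANDS = ("J", "N")

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                           "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class MitocompError(Exception):
    """Base class for validation and parse errors."""


@dataclass
class GeneFeature:
    """One annotated element of a mitogenome.

    ``end < start`` is permitted only for origin-spanning features on a
    circular record.  ``declared_ign`` carries the intergenic-nucleotide
    value printed in a published gene table, when one was supplied; it may
    legitimately disagree with the coordinate-derived junction gap (published
    tables occasionally do) and is never used unless explicitly requested.
    """

    name: str
    gene_class: str
    start: int
    end: int
    strand: str = "J"
    start_codon: str | None = None
    stop_codon: str | None = None
    declared_ign: int | None = None

    def __post_init__(self):
        if self.gene_class not in GENE_CLASSES:
            raise MitocompError(f"unknown gene class {self.gene_class!r} for {self.name}")
        if self.strand not in STRANDS:
            raise MitocompError(f"strand must be J or N, got {self.strand!r} for {self.name}")
        if self.start < 1 or self.end < 1:
            raise MitocompError(
                f"coordinates are 1-based; got {self.name} at {self.start}..{self.end}")
        if (self.start_codon or self.stop_codon) and self.gene_class != "PCG":
            raise MitocompError(f"start/stop codons only apply to PCGs ({self.name})")

    def span(self, genome_length: int | None = None) -> int:
        """Feature length in bp; origin-spanning features need the genome length."""
        if self.end >= self.start:
            return self.end - self.start + 1
        if genome_length is None:
            raise MitocompError(
                f"{self.name} spans the origin ({self.start}..{self.end}); "
                "genome length required")
        return self.end - self.start + 1 + genome_length

    @property
    def spans_origin(self) -> bool:
        return self.end < self.start


@dataclass
class MitogenomeRecord:
    """A circular annotated mitogenome: sequence plus ordered feature table.

    ``sequence`` may be None for records built from a gene table alone
    (coordinate-level statistics need no nucleotides); ``length`` is then the
    authoritative molecule size.
    """

    id: str
    length: int
    sequence: str | None = None
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise MitocompError(
                    f"{self.id}: length field {self.length} != sequence length "
                    f"{len(self.sequence)}")
        for f in self.features:
            if f.start > self.length or f.end > self.length:
                raise MitocompError(
                    f"{self.id}: feature {f.name} at {f.start}..{f.end} exceeds "
                    f"genome length {self.length}")
            if f.spans_origin and not self.circular:
                raise MitocompError(
                    f"{self.id}: origin-spanning feature {f.name} on a linear record")
        if not self.features:
            warnings.warn(f"{self.id}: record has no annotated features", stacklevel=2)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def genes(self) -> list[GeneFeature]:
        """The annotated genes, i.e. every feature except the control region."""
        return [f for f in self.features if f.gene_class != "CR"]

    def control_region(self) -> GeneFeature | None:
        cr = [f for f in self.features if f.gene_class == "CR"]
        return cr[0] if cr else None

    def with_features(self, features: list[GeneFeature]) -> "MitogenomeRecord":
        return replace(self, features=list(features))


@dataclass
class Alignment:
    """A multiple sequence alignment over {A, C, G, T, -, N and IUPAC codes}."""

    ids: list[str]
    rows: list[str]
    codon_aware: bool = False

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise MitocompError("ids and rows differ in number")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise MitocompError(f"alignment rows differ in length: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]
        if self.codon_aware and self.rows and len(self.rows[0]) % 3:
            raise MitocompError("codon-aware alignment length not divisible by 3")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def slice(self, start: int, end: int) -> "Alignment":
        """Column slice, 1-based inclusive."""
        return Alignment(self.ids, [r[start - 1:end] for r in self.rows],
                         codon_aware=False)
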