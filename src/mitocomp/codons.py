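"""Codon counting and relative synonymous codon usage (RSCU).

All computations use the invertebrate mitochondrial genetic code (NCBI
translation table 5), with the Leu and Ser families split to match the two
tRNAs that serve them: Leu1 = CUN, Leu2 = UUR, Ser1 = AGN, Ser2 = UCN.
RSCU(c) = observed count of c divided by the mean count over its family;
1 means no bias within the family.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio.Data import CodonTable

MITO_TABLE = CodonTable.unambiguous_dna_by_id[5]
STOP_CODONS = frozenset(MITO_TABLE.stop_codons)        # TAA, TAG in table 5
CODON_TO_AA = dict(MITO_TABLE.forward_table)           # sense codons only

_AA1TO3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}


def _build_families() -> dict[str, frozenset[str]]:
    fams: dict[str, set[str]] = {}
    for codon, aa in CODON_TO_AA.items():
        label = _AA1TO3[aa]
        if aa == "L":
            label = "Leu1" if codon.startswith("C") else "Leu2"
        elif aa == "S":
            label = "Ser1" if codon.startswith("AG") else "Ser2"
        fams.setdefault(label, set()).add(codon)
    return {label: frozenset(s) for label, s in fams.items()}


#: family label -> set of DNA codons (Leu/Ser split per the serving tRNA)
FAMILIES = _build_families()
FAMILY_OF_CODON = {c: label for label, fam in FAMILIES.items() for c in fam}


def to_rna(codon: str) -> str:
    return codon.replace("T", "U")


@dataclass
class CodonUsageTable:
    counts: dict[str, int]                 # DNA codons, sense + stop
    families: dict[str, frozenset[str]]
    rscu: dict[str, float]                 # sense codons only
    empty_families: list[str]              # families with zero total count

    def as_frame(self) -> pd.DataFrame:
        """Long-format report (RNA alphabet) suitable for stacked-bar plots."""
        rows = []
        for label, fam in sorted(self.families.items()):
            for codon in sorted(fam):
                rows.append({"codon": to_rna(codon), "family": label,
                             "count": self.counts.get(codon, 0),
                             "rscu": self.rscu[codon]})
        return pd.DataFrame(rows)


def count_codons(pcg_seqs: list[str]) -> Counter[str]:
    """Codon counts over coding-strand PCG sequences read from position 1.

    Trailing incomplete codons are dropped; codons containing non-ACGT
    symbols are skipped.
    """
    counts: Counter[str] = Counter()
    for seq in pcg_seqs:
        seq = seq.upper()
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i:i + 3]
            if set(codon) <= set("ACGT"):
                counts[codon] += 1
    return counts


def rscu(counts: dict[str, int]) -> CodonUsageTable:
    """RSCU table from codon counts; stop codons are excluded from families."""
    for codon in counts:
        if codon not in FAMILY_OF_CODON and codon not in STOP_CODONS:
            raise ValueError(f"{codon!r} is not a codon of the invertebrate "
                             "mitochondrial code")
    values: dict[str, float] = {}
    empty = []
    for label, fam in FAMILIES.items():
        total = sum(counts.get(c, 0) for c in fam)
        if total == 0:
            empty.append(label)
            for c in fam:
                values[c] = 0.0
        else:
            mean = total / len(fam)
            for c in fam:
                values[c] = counts.get(c, 0) / mean
    return CodonUsageTable(counts=dict(counts), families=FAMILIES,
                           rscu=values, empty_families=sorted(empty))


def top_codons(counts: dict[str, int], n: int = 4) -> list[tuple[str, str, int]]:
    """The n most frequent sense codons as (RNA codon, family, count)."""
    sense = [(c, k) for c, k in counts.items() if c in FAMILY_OF_CODON]
    sense.sort(key=lambda item: (-item[1], item[0]))
    return [(to_rna(c), FAMILY_OF_CODON[c], k) for c, k in sense[:n]]
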