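"""Seeded generators of annotated mitogenomes and codon alignments.

The genome generator emulates a circular ~15.5-kb insect mitochondrial
molecule: 37 genes plus control region in the ancestral arrangement (the
default template is the bundled G. henana gene table), per-region AT-content
and skew targets, planted control-region motifs (microsatellite, tandem
repeat, hairpin), and the template's junction gaps reproduced exactly.  The
alignment generator evolves codon sequences on a star tree under an imposed
Ka/Ks (omega): nonsynonymous proposals are accepted with probability omega
relative to synonymous ones, and stop codons are never introduced.  Every
generator is byte-deterministic under a fixed seed; the generated parameters
are the ground truth the analysis modules are tested against.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .codons import CODON_TO_AA, STOP_CODONS
from .model import Alignment, GeneFeature, MitocompError, MitogenomeRecord, reverse_complement
from .reference import load_reference

#: per-region (AT content, AT-skew, GC-skew) targets on the region's coding
#: strand; mid-range values for gryllotalpid mitogenomes
REGION_TARGETS = {
    "PCG": (0.69, -0.16, -0.04),
    "tRNA": (0.73, 0.02, 0.14),
    "rRNA": (0.72, -0.09, 0.38),
    "CR": (0.77, 0.03, -0.12),
    "spacer": (0.71, 0.05, -0.30),
}

BASES = np.array(list("ACGT"))


def base_frequencies(at: float, at_skew: float, gc_skew: float) -> np.ndarray:
    """(pA, pC, pG, pT) from AT content and the two skews."""
    gc = 1.0 - at
    a = at * (1.0 + at_skew) / 2.0
    t = at * (1.0 - at_skew) / 2.0
    g = gc * (1.0 + gc_skew) / 2.0
    c = gc * (1.0 - gc_skew) / 2.0
    return np.array([a, c, g, t])


@dataclass
class CRMotifSpec:
    """Planted control-region motifs, offsets relative to the CR 5' end."""
    microsat_motif: str = "TA"
    microsat_copies: int = 6
    microsat_offset: int = 100
    tandem_motif: str = "ATATAATTAAATATTTAA"
    tandem_copies: float = 41 / 18          # 2 full copies + 5 bases
    tandem_offset: int = 300
    hairpin_stem: int = 8
    hairpin_loop: str = "TTTTCTCTTTT"       # T+(TC)(TC)T+
    hairpin_end_offset: int = 20            # bp between hairpin and CR 3' end


@dataclass
class GenomeSpec:
    seed: int = 0
    template: list[GeneFeature] | None = None   # default: bundled G. henana table
    length: int | None = None                   # default: template extent
    region_targets: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(REGION_TARGETS))
    cr_motifs: CRMotifSpec | None = field(default_factory=CRMotifSpec)
    record_id: str = "SYN_MITO"


def default_template() -> list[GeneFeature]:
    return load_reference("gryllotalpa_henana").features


def generate_genome(spec: GenomeSpec) -> MitogenomeRecord:
    """Deterministic synthetic annotated mitogenome.

    Realised region compositions fall within binomial noise of the targets;
    planted CR motifs are present verbatim at the offsets in ``spec``; the
    feature table is the template itself, so every coordinate-level statistic
    of the template (junction gaps, strand census, spans) is reproduced
    exactly.
    """
    rng = np.random.default_rng(spec.seed)
    template = spec.template if spec.template is not None else default_template()
    if not template:
        raise MitocompError("empty gene template")
    length = spec.length or max(f.end for f in template)
    for f in template:
        if f.end > length and not f.spans_origin:
            raise MitocompError(f"template feature {f.name} exceeds length {length}")
        if f.span(length) < 1:
            raise MitocompError(f"template feature {f.name} has nonpositive span")

    freqs = {cls: base_frequencies(*target)
             for cls, target in spec.region_targets.items()}
    genome = rng.choice(BASES, size=length, p=freqs["spacer"])

    def write_span(start: int, end: int, coding_seq: str, strand: str) -> None:
        j_seq = coding_seq if strand == "J" else reverse_complement(coding_seq)
        if end >= start:
            genome[start - 1:end] = list(j_seq)
        else:  # origin-spanning
            head = length - start + 1
            genome[start - 1:] = list(j_seq[:head])
            genome[:end] = list(j_seq[head:])

    for f in template:
        span = f.span(length)
        seq = "".join(rng.choice(BASES, size=span, p=freqs[f.gene_class]))
        if f.gene_class == "PCG":
            start_codon = f.start_codon or "ATG"
            stop_codon = f.stop_codon or "TAA"
            body = list(seq)
            body[:3] = start_codon
            body[span - len(stop_codon):] = stop_codon
            # scrub in-frame stop codons from the interior by resampling the
            # codon from the region's base distribution (composition-neutral)
            for i in range(3, span - 2 - len(stop_codon), 3):
                while "".join(body[i:i + 3]) in STOP_CODONS:
                    body[i:i + 3] = rng.choice(BASES, size=3,
                                               p=freqs[f.gene_class])
            seq = "".join(body)
        elif f.gene_class == "CR" and spec.cr_motifs is not None:
            seq = _plant_cr_motifs(seq, spec.cr_motifs, rng)
        write_span(f.start, f.end, seq, f.strand)

    return MitogenomeRecord(id=spec.record_id, length=length,
                            sequence="".join(genome), circular=True,
                            features=[replace(f) for f in template])


def _plant_cr_motifs(cr: str, motifs: CRMotifSpec, rng: np.random.Generator) -> str:
    seq = list(cr)
    n = len(seq)

    def place(offset: int, insert: str, guards: str = "GC") -> None:
        if offset < 1 or offset + len(insert) + 1 > n:
            raise MitocompError("planted CR motif does not fit the control region")
        # guard bases stop the planted motif from extending past its span
        seq[offset - 1] = guards[0]
        seq[offset:offset + len(insert)] = insert
        seq[offset + len(insert)] = guards[1]

    ms = motifs.microsat_motif * motifs.microsat_copies
    place(motifs.microsat_offset, ms)
    tr_len = round(len(motifs.tandem_motif) * motifs.tandem_copies)
    tr = (motifs.tandem_motif * -(-tr_len // len(motifs.tandem_motif)))[:tr_len]
    place(motifs.tandem_offset, tr)
    arm = "".join(rng.choice(BASES, size=motifs.hairpin_stem,
                             p=np.array([0.1, 0.4, 0.4, 0.1])))
    hairpin = arm + motifs.hairpin_loop + reverse_complement(arm)
    # A/A guards cannot pair, so the stem ends exactly at the planted arms
    place(n - motifs.hairpin_end_offset - len(hairpin) - 1, hairpin, guards="AA")
    return "".join(seq)


def planted_cr_coordinates(spec: GenomeSpec) -> dict[str, tuple[int, int]]:
    """1-based CR-relative spans of the motifs ``generate_genome`` plants."""
    m = spec.cr_motifs
    if m is None:
        return {}
    template = spec.template if spec.template is not None else default_template()
    length = spec.length or max(f.end for f in template)
    cr = next(f for f in template if f.gene_class == "CR")
    cr_len = cr.span(length)
    ms_len = len(m.microsat_motif) * m.microsat_copies
    tr_len = round(len(m.tandem_motif) * m.tandem_copies)
    hp_len = 2 * m.hairpin_stem + len(m.hairpin_loop)
    hp_start = cr_len - m.hairpin_end_offset - hp_len - 1
    return {
        "microsatellite": (m.microsat_offset + 1, m.microsat_offset + ms_len),
        "tandem_repeat": (m.tandem_offset + 1, m.tandem_offset + tr_len),
        "stem_loop": (hp_start + 1, hp_start + hp_len),
    }


def random_template(seed: int, n_features: int = 20,
                    min_span: int = 60, max_span: int = 1500,
                    max_gap: int = 80, max_overlap: int = 10) -> tuple[list[GeneFeature], int]:
    """Random circular tiling: features with random spans and signed gaps.

    Returns (features, genome_length); by construction the features are in
    circle order and the final wrap gap is nonnegative.
    """
    rng = np.random.default_rng(seed)
    features = []
    start = 1
    prev_span = None
    for i in range(n_features):
        span = int(rng.integers(min_span, max_span + 1))
        if features:
            lo = -min(max_overlap, prev_span - 1, span - 1)
            gap = int(rng.integers(lo, max_gap + 1))
            start = features[-1].end + gap + 1
        end = start + span - 1
        features.append(GeneFeature(name=f"g{i + 1}", gene_class="tRNA",
                                    start=start, end=end,
                                    strand="J" if rng.random() < 0.6 else "N"))
        prev_span = span
    wrap = int(rng.integers(0, max_gap + 1))
    return features, features[-1].end + wrap


# ---------------------------------------------------------------------------
# codon alignments with known omega

SENSE_CODONS = sorted(CODON_TO_AA)


@dataclass
class AlignmentSpec:
    n_sequences: int = 6
    n_codons: int = 2000
    branch_length: float = 0.2   # expected accepted substitutions per codon per branch
    omega: float = 0.5           # imposed Ka/Ks
    seed: int = 0
    tree: str = "star"


@dataclass
class SimulatedAlignment:
    alignment: Alignment
    syn_subs: list[int]          # realised counts per tip branch
    nonsyn_subs: list[int]


def generate_codon_alignment(spec: AlignmentSpec) -> SimulatedAlignment:
    """Evolve ``n_sequences`` codon sequences from a random ancestor.

    Single-base proposals are uniform over positions and alternative bases;
    proposals creating a stop codon are discarded, synonymous proposals are
    always accepted, nonsynonymous ones with probability ``omega``.  Each tip
    receives a Poisson(branch_length x n_codons) number of accepted
    substitutions.
    """
    if spec.tree != "star":
        raise MitocompError(f"unsupported tree shape {spec.tree!r}")
    rng = np.random.default_rng(spec.seed)
    ancestor = [SENSE_CODONS[k]
                for k in rng.integers(0, len(SENSE_CODONS), size=spec.n_codons)]
    rows, syn_counts, nonsyn_counts = [], [], []
    for t in range(spec.n_sequences):
        codons = list(ancestor)
        target = int(rng.poisson(spec.branch_length * spec.n_codons))
        accepted = syn = nonsyn = 0
        attempts = 0
        max_attempts = 200 * target + 10_000
        while accepted < target and attempts < max_attempts:
            attempts += 1
            idx = int(rng.integers(spec.n_codons))
            pos = int(rng.integers(3))
            old = codons[idx]
            base = "ACGT"[int(rng.integers(4))]
            if base == old[pos]:
                continue
            new = old[:pos] + base + old[pos + 1:]
            if new in STOP_CODONS:
                continue
            if CODON_TO_AA[new] == CODON_TO_AA[old]:
                codons[idx] = new
                accepted += 1
                syn += 1
            elif rng.random() < spec.omega:
                codons[idx] = new
                accepted += 1
                nonsyn += 1
        rows.append("".join(codons))
        syn_counts.append(syn)
        nonsyn_counts.append(nonsyn)
    aln = Alignment(ids=[f"t{i + 1}" for i in range(spec.n_sequences)],
                    rows=rows, codon_aware=True)
    return SimulatedAlignment(alignment=aln, syn_subs=syn_counts,
                              nonsyn_subs=nonsyn_counts)
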