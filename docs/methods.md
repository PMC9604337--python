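# Methods

Statistical conventions, model choices and known limitations of `mitocomp`.

## Coordinates and annotation accounting

Coordinates are 1-based inclusive throughout, as in published gene tables;
conversion to Python slices happens only at the I/O boundary. Strands are
*J* (majority, the annotated forward strand) and *N* (minority, the
complement).

The intergenic nucleotide count at a junction is
`ign = downstream.start − upstream.end − 1`; negative values denote
overlap, zero-length junctions count as neither spacer nor overlap. On a
circular record the final junction wraps the last feature back to the
first, giving the telescoping identity **Σ feature spans + Σ IGN = genome
length**, which is enforced as a property test on random circular tilings.

Published gene tables occasionally print an IGN value that disagrees with
the printed coordinates (the bundled *G. henana* table prints −1 at the
trnM/nad2 junction where the coordinates give +1). Both values are kept:
features carry the printed value as `declared_ign`, and every accounting
function takes `use_declared_ign` (default off, i.e. coordinate-derived).
Reproducing a published spacer/overlap table therefore requires the
declared mode; the two modes are never mixed silently.

Spacer/overlap totals exclude junctions where either side is the control
region, matching the published convention of counting only inter-gene
junctions; `include_cr_junctions=True` restores them.

## Composition and skews

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C); a zero denominator yields
`None` rather than an arbitrary value. Region sequences are read 5'→3' on
their coding strand (so the skews of an N-strand gene describe its own
sense strand); the whole-genome row uses the J strand. Codon-position
strings are built after trimming each PCG's trailing incomplete codon, so
the three strings are equal length; the full (untrimmed) PCG concatenation
is used for the "PCGs" row. Because published PCG-length figures vary with
the chosen stop-trimming convention, region sizes are reported alongside
every composition row. Values are kept at full precision; rounding (one
decimal for percent, three for skews) is applied only at report time.

## Codon usage

The invertebrate mitochondrial code (NCBI translation table 5, via
Biopython's `CodonTable`) defines 62 sense codons and the stops TAA/TAG.
RSCU(c) = count(c) / mean count over c's synonymous family. Leu is split
into Leu1 (CUN) and Leu2 (UUR) and Ser into Ser1 (AGN) and Ser2 (UCN),
matching the two tRNAs serving each; with this split every family's RSCU
values sum to the family size. Families with zero total count are reported
as all-zero and flagged rather than dropped.

## Divergence

**K2P.** d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q), with P and Q the transition
and transversion proportions over columns unambiguous in both sequences
(pairwise deletion, the convention of MEGA-style distance tools). The
implementation was checked to 12 significant digits against
`ape::dist.dna(model = "K80", pairwise.deletion = TRUE)` in R. Divergence
beyond the correctable range raises `SaturationError` instead of returning
NaN.

**Nucleotide diversity.** Pi is the mean over all unordered sequence pairs
of the proportion of differing sites, computed after removing every column
with a gap or ambiguity in any sequence (complete deletion, the DnaSP
convention). Sliding windows (default 100 columns, step 25) start at
columns 1, 26, 51, … while a full window fits; complete deletion is applied
within each window.

**NG86 Ka/Ks.** Synonymous site counts per codon are the fractions of
one-step changes that preserve the amino acid, with changes to stop codons
counted as nonsynonymous; S + N = 3 × (compared codons) exactly. Observed
differences between codon pairs are averaged over all orderings of the
differing positions, discarding orderings that pass through a stop codon
(if all orderings are blocked — unreachable for sense-codon pairs under
table 5, but guarded — the average falls back to all orderings). Distances
use the Jukes–Cantor correction ks = −¾ ln(1 − 4/3 pS); saturated rates
propagate as `None`. Alignment-level omega defaults to the ratio of means
(mean Ka / mean Ks over pairs), which remains defined when individual pairs
have Ks = 0; mean-of-ratios is available. Pathway averaging is verified
against an independent brute-force path enumeration for every sense-codon
pair.

Note that one widely circulated worked example for NG86 assigns ATG zero
synonymous sites; under table 5 ATG↔ATA are both Met, so ATG has 1/3
synonymous site and ATGGCT vs ATGGTT gives S = 4/3, N = 14/3.

## Control region scanners

Scoring is deliberately simple and deterministic — period, copies and
identity, not a probabilistic repeat model or a thermodynamic folding
energy.

**Microsatellites** (period 1–2): maximal runs with ≥ 3 copies, motifs in
canonical (lexicographically least) rotation, homopolymers reported only at
period 1, overlaps suppressed in favour of the longest run.

**Tandem repeats** (period ≥ 10 by default): the sequence is compared with
itself shifted by each candidate period; from each seed match the aligned
extent grows to the argmax of (matches − 3 × mismatches), so extension
stops where agreement decays. A region is reported when copies ≥ 1.9
(fractional copies allowed), identity ≥ 0.85, and at least 16 positions
match — the last floor keeps chance self-matches in short windows from
surfacing. Regions that are really 1–2 bp repeats are left to the
microsatellite scanner, and a period-p hit suppresses its echoes at 2p,
3p, … Monte-Carlo null: on uniform-random 500-mers with min_identity 0.9
and min_copies 2, 0 of 200 seeds produce a hit at period ≥ 10.

**Stem-loops**: for every candidate loop (3–20 nt) the arms extend outward
over strict Watson-Crick DNA pairs with at most one non-complementary pair;
terminal mismatches are trimmed. `motif_match` flags loops matching
T+TCTCT+ allowing up to three flanking bases on each side. Within
overlapping hits, strength is the number of *complementary* pairs
(mismatches add length, not strength), and motif-carrying hairpins are
suppressed separately from plain ones so the biologically meaningful motif
hairpin is never masked by a stronger chance fold. Caveat: in AT-rich
random sequence the loop motif occurs genuinely by chance (≈ 4 % of
uniform-random 900-mers contain some motif-carrying hairpin); a motif hit
in a real control region should be weighed by its position and stem
strength, not treated as significant per se.

## tRNA structures

Dot-bracket structures are *inputs* from an external predictor, not
predictions. Pair classes (Watson-Crick, GU wobble, AC, UU, AA, other)
partition the paired positions; because published "mismatch" totals often
count GU among the unmatched pairs, both a GU-inclusive and a strict
(non-GU) total are reported. Arm labelling takes the outermost helix as the
acceptor stem and names the helices off the central multiloop DHU,
anticodon and TψC in 5'→3' order; when only two inner helices exist the DHU
arm is recorded as a simple loop (the trnS1 configuration). Pseudoknots
(which dot-bracket cannot express) and non-nested foldings are out of
scope.

## Synthetic data generator

**Genomes.** The default template is the bundled *G. henana* gene table, so
every coordinate-level statistic of the synthetic genome equals the
template's by construction. Per-region sequences are drawn i.i.d. from base
frequencies solving (AT content, AT-skew, GC-skew) targets; realised
compositions fall within binomial noise of the targets. PCGs get their
annotated start/stop codons forced and interior in-frame stops resampled
from the same base distribution (composition-neutral). Three motifs are
planted in the control region — (TA)6, an 18-bp tandem repeat at 2.28
copies, and a hairpin with a T+(TC)(TC)T+ loop near the 3' end — each
flanked by guard bases that cannot extend the motif. Limitations of
realism: i.i.d. bases carry no dinucleotide or codon-usage structure;
overlapping genes are written in table order, so a downstream gene
overwrites the shared bases (as in real overlapping genes, only one
sequence exists); chance AT-rich self-similarity around a planted repeat
can legitimately extend a detected repeat a few bases beyond the planted
span, so recovery is asserted as containment of the planted coordinates.

**Codon alignments.** Sequences evolve on a star tree from a random sense
ancestor. Single-base proposals are uniform; proposals creating stops are
discarded, synonymous proposals are always accepted and nonsynonymous ones
with probability ω, with Poisson(branch length × codons) accepted
substitutions per tip. This is an acceptance-ratio construction, not a full
mutation-selection process — it imposes the *ratio* Ka/Ks rather than
absolute rates, which is exactly what the NG86 estimator is tested on:
estimates recover generating ω ∈ {0.05, 0.5, 1.0} within 15 % relative
error at 5,000 codons. At much higher divergence multiple hits saturate the
Jukes–Cantor correction and recovery degrades, as expected of NG86 itself.

**Determinism.** All randomness flows from `numpy.random.default_rng(seed)`
on explicit seeds; generation is byte-deterministic, and the pipeline
writes every parameter and seed to `params.json`.

## Numerical conventions

Full-precision floats are kept internally; rounding happens only in
reports. Ratios with zero denominators become `None`/NaN rather than
infinities; saturation raises or propagates as `None` explicitly. Site
fractions use exact rational arithmetic in spirit (thirds), accumulated in
floats — S + N = 3 × codons holds to machine precision and is asserted
exactly via `pytest.approx`.
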