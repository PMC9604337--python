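"""Pairwise and alignment-wide divergence statistics.

* Kimura two-parameter (K2P) distance with pairwise deletion of gapped or
  ambiguous columns (the convention of distance tools such as MEGA).
* Nucleotide diversity (Pi) with complete deletion (the convention of
  polymorphism tools such as DnaSP): the mean over all unordered sequence
  pairs of the proportion of differing sites.
* Sliding-window Pi profiles (default window 100 columns, step 25).
* Nei-Gojobori (1986) Ka/Ks under the invertebrate mitochondrial code, with
  pathway averaging over substitution orderings and Jukes-Cantor correction.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations

import pandas as pd

from .codons import CODON_TO_AA, STOP_CODONS
from .model import Alignment, MitocompError

VALID = frozenset("ACGT")
PURINES = frozenset("AG")


class SaturationError(MitocompError):
    """Observed divergence too high for the distance correction."""


@dataclass
class K2PResult:
    p_transition: float
    q_transversion: float
    distance: float
    valid_sites: int


@dataclass
class KaKsResult:
    syn_sites: float       # S
    nonsyn_sites: float    # N; S + N = 3 x compared codons
    syn_diffs: float       # Sd (pathway-averaged)
    nonsyn_diffs: float    # Nd
    codons: int            # codon pairs compared
    ps: float
    pn: float
    ks: float | None       # None when saturated
    ka: float | None
    omega: float | None    # Ka/Ks; None when Ks = 0 or a rate is saturated


@dataclass
class DiversityProfile:
    per_window: list[tuple[int, float, float]]  # (start column, midpoint, pi)
    window: int
    step: int


def k2p(a: str, b: str) -> K2PResult:
    """K2P distance between two aligned sequences (pairwise deletion).

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P the transition and Q the
    transversion proportion among columns valid in both sequences.
    """
    if len(a) != len(b):
        raise MitocompError("sequences differ in length")
    a, b = a.upper(), b.upper()
    valid = transitions = transversions = 0
    for x, y in zip(a, b):
        if x in VALID and y in VALID:
            valid += 1
            if x != y:
                if (x in PURINES) == (y in PURINES):
                    transitions += 1
                else:
                    transversions += 1
    if valid == 0:
        raise MitocompError("no jointly unambiguous sites")
    p = transitions / valid
    q = transversions / valid
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P undefined: P={p:.3f}, Q={q:.3f} beyond the correctable range")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(p_transition=p, q_transversion=q, distance=d,
                     valid_sites=valid)


def _complete_deletion_columns(aln: Alignment) -> list[int]:
    cols = []
    for j in range(aln.n_cols):
        if all(row[j] in VALID for row in aln.rows):
            cols.append(j)
    return cols


def nucleotide_diversity(aln: Alignment) -> float:
    """Pi over an alignment: mean pairwise difference proportion.

    Columns containing a gap or ambiguity in any sequence are excluded
    alignment-wide before comparison (complete deletion).
    """
    if aln.n_rows < 2:
        raise MitocompError("nucleotide diversity needs at least two sequences")
    cols = _complete_deletion_columns(aln)
    if not cols:
        return 0.0
    total = 0.0
    n_pairs = 0
    for r1, r2 in combinations(aln.rows, 2):
        diffs = sum(1 for j in cols if r1[j] != r2[j])
        total += diffs / len(cols)
        n_pairs += 1
    return total / n_pairs


def sliding_window_pi(aln: Alignment, window: int = 100,
                      step: int = 25) -> DiversityProfile:
    """Windowed Pi profile; windows start at columns 1, 1+step, ... while
    they fit, each evaluated with complete deletion inside the window."""
    if aln.n_cols < window:
        warnings.warn(
            f"alignment ({aln.n_cols} columns) shorter than window {window}; "
            "single truncated window", stacklevel=2)
        pi = nucleotide_diversity(aln)
        return DiversityProfile([(1, (1 + aln.n_cols) / 2, pi)], window, step)
    rows = []
    start = 1
    while start + window - 1 <= aln.n_cols:
        sub = aln.slice(start, start + window - 1)
        rows.append((start, start + (window - 1) / 2, nucleotide_diversity(sub)))
        start += step
    return DiversityProfile(rows, window, step)


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986)

@lru_cache(maxsize=None)
def _syn_site_fraction(codon: str) -> float:
    """Synonymous site count of one sense codon (0..3).

    Each position contributes (synonymous one-step changes)/3; changes to
    stop codons count as nonsynonymous.
    """
    aa = CODON_TO_AA[codon]
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over substitution pathways.

    Each ordering of the differing positions defines a path of single-base
    steps; paths passing through a stop codon are discarded (zero weight).
    If every path is blocked the average falls back to all paths.
    """
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in permutations(positions):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:  # both neighbours of a stop: average over all orderings
        for order in permutations(positions):
            cur = c1
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                same = (nxt not in STOP_CODONS and cur not in STOP_CODONS
                        and CODON_TO_AA[cur] == CODON_TO_AA[nxt])
                sd += same
                nd += not same
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jc_correct(p: float, label: str) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        raise SaturationError(f"{label} proportion {p:.3f} >= 3/4; rate undefined")
    return -0.75 * math.log(arg)


def ng86_kaks(a: str, b: str) -> KaKsResult:
    """NG86 Ka/Ks between two codon-aligned sequences.

    Codons containing gaps/ambiguity in either sequence, and stop codons,
    are skipped pairwise.  Site counts are averaged between the two
    sequences; S + N equals 3 x the number of compared codons exactly.
    """
    if len(a) != len(b):
        raise MitocompError("sequences differ in length")
    if len(a) % 3:
        raise MitocompError("sequence length not divisible by 3")
    a, b = a.upper(), b.upper()
    s_sites = sd = nd = 0.0
    codons = 0
    for i in range(0, len(a), 3):
        c1, c2 = a[i:i + 3], b[i:i + 3]
        if not (set(c1) <= VALID and set(c2) <= VALID):
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        codons += 1
        s_sites += (_syn_site_fraction(c1) + _syn_site_fraction(c2)) / 2.0
        d_s, d_n = _pair_differences(c1, c2)
        sd += d_s
        nd += d_n
    if codons == 0:
        raise MitocompError("no comparable codons")
    n_sites = 3.0 * codons - s_sites
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    ks = ka = None
    try:
        ks = _jc_correct(ps, "synonymous")
    except SaturationError:
        pass
    try:
        ka = _jc_correct(pn, "nonsynonymous")
    except SaturationError:
        pass
    omega = None
    if ka is not None and ks is not None and ks > 0:
        omega = ka / ks
    return KaKsResult(syn_sites=s_sites, nonsyn_sites=n_sites,
                      syn_diffs=sd, nonsyn_diffs=nd, codons=codons,
                      ps=ps, pn=pn, ks=ks, ka=ka, omega=omega)


def mean_pairwise_kaks(aln: Alignment,
                       aggregation: str = "ratio_of_means") -> tuple[float | None, float, float]:
    """(omega, mean Ka, mean Ks) over all sequence pairs of a codon alignment.

    ``ratio_of_means`` (default) divides mean Ka by mean Ks, which stays
    defined when individual pairs have Ks = 0; ``mean_of_ratios`` averages
    the defined pairwise ratios instead.
    """
    kas, kss, ratios = [], [], []
    for r1, r2 in combinations(aln.rows, 2):
        res = ng86_kaks(r1, r2)
        if res.ka is not None:
            kas.append(res.ka)
        if res.ks is not None:
            kss.append(res.ks)
        if res.omega is not None:
            ratios.append(res.omega)
    mean_ka = sum(kas) / len(kas) if kas else float("nan")
    mean_ks = sum(kss) / len(kss) if kss else float("nan")
    if aggregation == "mean_of_ratios":
        omega = sum(ratios) / len(ratios) if ratios else None
    else:
        omega = mean_ka / mean_ks if kss and mean_ks > 0 else None
    return omega, mean_ka, mean_ks


def gene_divergence_table(gene_alignments: dict[str, Alignment],
                          omega_aggregation: str = "ratio_of_means") -> pd.DataFrame:
    """Per-gene divergence summary: Pi, mean pairwise K2P, Ka, Ks, omega.

    Failures (e.g. saturation) are recorded per gene as NaN rather than
    aborting the table.
    """
    rows = []
    for gene, aln in gene_alignments.items():
        row = {"gene": gene, "pi": float("nan"), "k2p_mean": float("nan"),
               "ka_mean": float("nan"), "ks_mean": float("nan"),
               "omega": float("nan"), "error": ""}
        try:
            row["pi"] = nucleotide_diversity(aln)
            dists = [k2p(r1, r2).distance
                     for r1, r2 in combinations(aln.rows, 2)]
            row["k2p_mean"] = sum(dists) / len(dists)
            if aln.codon_aware or aln.n_cols % 3 == 0:
                omega, ka, ks = mean_pairwise_kaks(aln, omega_aggregation)
                row["ka_mean"], row["ks_mean"] = ka, ks
                row["omega"] = omega if omega is not None else float("nan")
        except MitocompError as exc:
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene")
    for col in ("pi", "k2p_mean", "omega"):
        table[f"rank_{col}"] = table[col].rank(ascending=False, method="min")
    return table
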