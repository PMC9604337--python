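"""K2P, nucleotide diversity, sliding windows, NG86 Ka/Ks."""
import math
from itertools import combinations, permutations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp import (Alignment, SaturationError, gene_divergence_table, k2p,
                      mean_pairwise_kaks, ng86_kaks, nucleotide_diversity,
                      sliding_window_pi)
from mitocomp.codons import CODON_TO_AA, STOP_CODONS
from mitocomp.model import MitocompError

SENSE_CODONS = sorted(CODON_TO_AA)


# --------------------------------------------------------------------------
# K2P

def test_k2p_closed_form_hand_example():
    # 20 sites, 2 transitions, 1 transversion: P=0.10, Q=0.05,
    # d = -1/2 ln(0.75) - 1/4 ln(0.90) = 0.1702...
    a = "A" * 20
    b = "GG" + "C" + "A" * 17
    res = k2p(a, b)
    assert res.p_transition == pytest.approx(0.10)
    assert res.q_transversion == pytest.approx(0.05)
    expected = -0.5 * math.log(0.75) - 0.25 * math.log(0.90)
    assert res.distance == pytest.approx(expected, abs=1e-12)
    assert res.distance == pytest.approx(0.1702, abs=5e-5)


# Frozen oracle: ape::dist.dna(model="K80", pairwise.deletion=TRUE) on these
# three sequences returned the matrix below (12 significant digits).
_ORACLE_A = "ATGGCATTAGCCTTAACCGGAGTTATTCCTTTAGCAACAGGACTTATTCCAGCAACAGG"
_ORACLE_B = "ATGGCGTTAGCTTTAACCGGAGTCATTCCTTTAGCAACAGGACTAATCCCAGCTACAGG"
_ORACLE_C = "ATAGCATTAGCCCTAACTGGAGTTATTCCATTAGCAACCGGACTTATTCCAGCAACAGG"


@pytest.mark.parametrize("x, y, expected", [
    (_ORACLE_A, _ORACLE_B, 0.110409637566),
    (_ORACLE_A, _ORACLE_C, 0.090406970259),
    (_ORACLE_B, _ORACLE_C, 0.218410641396),
])
def test_k2p_matches_independent_r_oracle(x, y, expected):
    assert k2p(x, y).distance == pytest.approx(expected, abs=1e-9)


def test_k2p_pairwise_deletion_of_ambiguous_sites():
    res = k2p("ACGTN-", "ACGAAC")
    assert res.valid_sites == 4  # N and '-' columns dropped
    assert res.q_transversion == pytest.approx(0.25)  # T vs A


def test_k2p_identical_sequences():
    assert k2p("ACGT", "ACGT").distance == 0.0


def test_k2p_saturation_raises():
    with pytest.raises(SaturationError):
        k2p("AAAAAAAA", "GGGGGGGG")  # P = 1


def test_k2p_symmetry():
    assert k2p(_ORACLE_A, _ORACLE_B).distance == k2p(_ORACLE_B, _ORACLE_A).distance


# --------------------------------------------------------------------------
# nucleotide diversity

def test_pi_hand_example():
    # 3 rows, 10 columns, pairwise differences {1, 1, 2}: Pi = 4/30
    r1 = "AAAAAAAAAA"
    r2 = "CAAAAAAAAA"
    r3 = "CGAAAAAAAA"
    aln = Alignment(ids=list("abc"), rows=[r1, r2, r3])
    assert nucleotide_diversity(aln) == pytest.approx(4 / 30)


def test_pi_complete_deletion():
    # the gapped column is excluded for every pair, not only the gapped one
    aln = Alignment(ids=list("abc"), rows=["AC-T", "ACGT", "TCGT"])
    # columns kept: 1, 2, 4 (0-based 0, 1, 3); diffs: a-b 0, a-c 1, b-c 1
    assert nucleotide_diversity(aln) == pytest.approx((0 + 1 / 3 + 1 / 3) / 3)


def test_pi_requires_two_rows():
    with pytest.raises(MitocompError):
        nucleotide_diversity(Alignment(ids=["a"], rows=["ACGT"]))


@settings(max_examples=50)
@given(st.integers(2, 5), st.integers(4, 30), st.integers(0, 2**32 - 1))
def test_pi_equals_brute_force(n_rows, n_cols, seed):
    import numpy as np
    rng = np.random.default_rng(seed)
    rows = ["".join(rng.choice(list("ACGT-"), size=n_cols, p=[.24, .24, .24, .24, .04]))
            for _ in range(n_rows)]
    aln = Alignment(ids=[str(i) for i in range(n_rows)], rows=rows)
    cols = [j for j in range(n_cols) if all(r[j] in "ACGT" for r in rows)]
    if not cols:
        assert nucleotide_diversity(aln) == 0.0
        return
    pairs = list(combinations(rows, 2))
    expect = sum(sum(r1[j] != r2[j] for j in cols) / len(cols)
                 for r1, r2 in pairs) / len(pairs)
    assert nucleotide_diversity(aln) == pytest.approx(expect)


def test_sliding_windows_start_columns():
    aln = Alignment(ids=["a", "b"], rows=["A" * 150, "A" * 150])
    profile = sliding_window_pi(aln, window=100, step=25)
    assert [w[0] for w in profile.per_window] == [1, 26, 51]


def test_sliding_windows_short_alignment_warns():
    aln = Alignment(ids=["a", "b"], rows=["ACGT" * 10, "ACGT" * 10])
    with pytest.warns(UserWarning, match="shorter than window"):
        profile = sliding_window_pi(aln, window=100, step=25)
    assert len(profile.per_window) == 1


def test_sliding_windows_locate_hotspot():
    import numpy as np
    rng = np.random.default_rng(5)
    base = "".join(rng.choice(list("ACGT"), size=200))
    mutant = list(base)
    for j in range(39, 60):  # differences concentrated in columns 40-60
        mutant[j] = {"A": "G", "G": "A", "C": "T", "T": "C"}[mutant[j]]
    aln = Alignment(ids=["a", "b"], rows=[base, "".join(mutant)])
    profile = sliding_window_pi(aln, window=50, step=10)
    best = max(profile.per_window, key=lambda w: w[2])
    assert best[0] <= 60 and best[0] + 49 >= 40


# --------------------------------------------------------------------------
# NG86

def test_ng86_single_codon_pair_hand_example():
    # ATGGCT vs ATGGTT under the invertebrate mito code:
    # ATG has one synonymous one-step change (ATG->ATA, both Met) -> S=1/3;
    # GCT is fourfold degenerate -> S=1; total S=4/3, N=14/3.
    # The single difference GCT->GTT is nonsynonymous (Ala->Val).
    res = ng86_kaks("ATGGCT", "ATGGTT")
    assert res.syn_sites == pytest.approx(4 / 3)
    assert res.nonsyn_sites == pytest.approx(14 / 3)
    assert res.syn_diffs == 0.0
    assert res.nonsyn_diffs == 1.0
    assert res.pn == pytest.approx(3 / 14)
    assert res.ka == pytest.approx(-0.75 * math.log(1 - 4 / 14), abs=1e-12)
    assert res.ks == 0.0
    assert res.omega is None  # Ks = 0


def _brute_force_pathways(c1, c2):
    """Independent pathway enumeration: all orderings of the differing
    positions as explicit single-step walks; stop-crossing walks dropped."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    surviving = []
    for order in permutations(positions):
        cur, sd, nd, ok = c1, 0, 0, True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            surviving.append((sd, nd))
    return surviving


@settings(max_examples=200, deadline=None)
@given(st.sampled_from(SENSE_CODONS), st.sampled_from(SENSE_CODONS))
def test_ng86_pathway_averaging_matches_brute_force(c1, c2):
    res = ng86_kaks(c1, c2)
    paths = _brute_force_pathways(c1, c2)
    assert paths, f"no stop-free pathway between sense codons {c1} and {c2}"
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    assert res.syn_diffs == pytest.approx(sd)
    assert res.nonsyn_diffs == pytest.approx(nd)


@settings(max_examples=100, deadline=None)
@given(st.lists(st.sampled_from(SENSE_CODONS), min_size=1, max_size=10),
       st.lists(st.sampled_from(SENSE_CODONS), min_size=1, max_size=10))
def test_ng86_site_counts_sum_to_three_per_codon(codons1, codons2):
    n = min(len(codons1), len(codons2))
    a = "".join(codons1[:n])
    b = "".join(codons2[:n])
    res = ng86_kaks(a, b)
    assert res.syn_sites + res.nonsyn_sites == pytest.approx(3 * res.codons)
    assert res.codons == n


@given(st.lists(st.sampled_from(SENSE_CODONS), min_size=2, max_size=6),
       st.lists(st.sampled_from(SENSE_CODONS), min_size=2, max_size=6))
def test_ng86_is_symmetric(codons1, codons2):
    n = min(len(codons1), len(codons2))
    a, b = "".join(codons1[:n]), "".join(codons2[:n])
    assert ng86_kaks(a, b) == ng86_kaks(b, a)


def test_ng86_skips_gapped_and_stop_codons():
    res = ng86_kaks("ATG" + "TAA" + "A-G" + "AAA",
                    "ATG" + "AAA" + "AAG" + "AAG")
    assert res.codons == 2  # stop pair and gapped pair skipped


def test_ng86_rejects_non_codon_length():
    with pytest.raises(MitocompError):
        ng86_kaks("ACGT", "ACGT")


def test_mean_pairwise_kaks_aggregations():
    rows = ["ATGGCTAAAGAA", "ATGGCCAAAGAA", "ATGGTTAAAGAG"]
    aln = Alignment(ids=list("abc"), rows=rows, codon_aware=True)
    omega_rm, ka, ks = mean_pairwise_kaks(aln, "ratio_of_means")
    assert omega_rm == pytest.approx(ka / ks)
    omega_mr, _, _ = mean_pairwise_kaks(aln, "mean_of_ratios")
    # only pairs with Ks > 0 contribute ratios
    assert omega_mr is None or omega_mr > 0


def test_gene_divergence_table_ranks_and_errors():
    good = Alignment(ids=list("ab"), rows=["ATGGCTAAA", "ATGGTTAAA"],
                     codon_aware=True)
    diverse = Alignment(ids=list("ab"), rows=["ATGGCTAAA", "ATGGTTGGG"],
                        codon_aware=True)
    single = Alignment(ids=["a"], rows=["ATGGCTAAA"], codon_aware=True)
    table = gene_divergence_table({"g1": good, "g2": diverse, "g3": single})
    assert table.loc["g3", "error"] != ""
    assert math.isnan(table.loc["g3", "pi"])
    assert table.loc["g2", "rank_pi"] == 1.0  # most diverse gene ranks first
    assert table.loc["g1", "rank_pi"] == 2.0
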