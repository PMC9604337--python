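"""Repeat and stem-loop detection in the control region.

Three scanners cover the motif classes reported in insect control regions:
microsatellites (1-2 bp motifs such as (TA)n), longer tandem repeats with
fractional copy number (self-alignment at a candidate period, identity
scored), and inverted repeats forming stem-loop hairpins whose loop carries
the T+(TC)(TC)T+ sequence implicated in minority-strand replication
initiation.  Scoring is deliberately simple and deterministic: period,
copies and identity, not a probabilistic repeat model or folding energy.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

from .io import extract_region
from .model import MitogenomeRecord, reverse_complement

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_LOOP_MOTIF = re.compile(r"T+TCTCT+")


@dataclass
class RepeatHit:
    motif: str
    period: int
    copies: float           # fractional copies allowed
    start: int              # 1-based inclusive within the searched sequence
    end: int
    identity: float         # matched fraction vs perfect repetition

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class StemLoopHit:
    arm5_start: int
    arm5_end: int
    arm3_start: int
    arm3_end: int
    stem_len: int           # paired positions, mismatches included
    mismatches: int
    loop_seq: str
    motif_match: bool


def _canonical_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def find_microsatellites(seq: str, max_motif: int = 2,
                         min_copies: int = 3) -> list[RepeatHit]:
    """Maximal runs of 1-2 bp motifs with at least ``min_copies`` copies.

    Motifs are reported in canonical (lexicographically least) rotation;
    homopolymeric runs appear only as period-1 hits, and overlapping reports
    are suppressed in favour of the longest run.
    """
    seq = seq.upper()
    n = len(seq)
    candidates: list[RepeatHit] = []
    for period in range(1, max_motif + 1):
        i = 0
        while i + period <= n:
            j = i + period
            while j < n and seq[j] == seq[j - period]:
                j += 1
            run_len = j - i
            motif = seq[i:i + period]
            if (run_len >= period * min_copies
                    and len(set(motif)) == period):  # homopolymers: period 1 only
                candidates.append(RepeatHit(
                    motif=_canonical_rotation(motif), period=period,
                    copies=run_len / period, start=i + 1, end=j,
                    identity=1.0))
            i = j - period + 1 if run_len > period else i + 1
    return _suppress_overlaps(candidates)


def _suppress_overlaps(hits: list[RepeatHit]) -> list[RepeatHit]:
    hits = sorted(hits, key=lambda h: (-h.length, -h.identity, h.period, h.start))
    kept: list[RepeatHit] = []
    for h in hits:
        if all(h.end < k.start or h.start > k.end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def _is_low_period(segment: str, min_identity: float) -> bool:
    """True when the segment is itself a 1-2 bp repeat (microsatellite turf)."""
    for period in (1, 2):
        if len(segment) <= period:
            continue
        matches = sum(segment[i] == segment[i - period]
                      for i in range(period, len(segment)))
        if matches / (len(segment) - period) >= min_identity:
            return True
    return False


def find_tandem_repeats(seq: str, min_period: int = 10,
                        max_period: int | None = None,
                        min_copies: float = 1.9,
                        min_identity: float = 0.85,
                        min_matches: int = 16) -> list[RepeatHit]:
    """Tandem repeats by self-alignment at each candidate period.

    For period p the sequence is compared against itself shifted by p; from
    each seed match the aligned extent grows to the point maximising
    matches - 3 x mismatches (so extension stops where agreement decays),
    and the region is reported when its identity is at least
    ``min_identity``, its copy number region length / p is at least
    ``min_copies`` (fractional copies permitted) and its aligned extent
    carries at least ``min_matches`` matching positions — the score floor
    that keeps chance self-matches in short windows from surfacing as hits.
    Regions that are really 1-2 bp microsatellites are left to
    :func:`find_microsatellites`.
    """
    if min_period < 3:
        raise ValueError("min_period must be >= 3; use find_microsatellites below that")
    seq = seq.upper()
    n = len(seq)
    if max_period is None:
        max_period = min(n // 2, 100)
    candidates: list[RepeatHit] = []
    for p in range(min_period, max_period + 1):
        m = [seq[i] == seq[i + p] for i in range(n - p)]
        i = 0
        while i < len(m):
            if not m[i]:
                i += 1
                continue
            score = best_score = 0
            matches = best_matches = 0
            best_j = i
            k = i
            while k < len(m) and score > best_score - 9:
                matches += m[k]
                score += 1 if m[k] else -3
                if score > best_score:
                    best_score, best_j, best_matches = score, k, matches
                k += 1
            j = best_j
            region_len = (j - i + 1) + p
            copies = region_len / p
            identity = best_matches / (j - i + 1)
            segment = seq[i:i + region_len]
            if (copies >= min_copies and identity >= min_identity
                    and best_matches >= min_matches
                    and not _is_low_period(segment, min_identity)):
                candidates.append(RepeatHit(
                    motif=seq[i:i + p], period=p, copies=copies,
                    start=i + 1, end=i + region_len, identity=identity))
            i = j + 1
    # smaller periods first so a p-repeat is not re-reported at 2p, 3p, ...
    candidates.sort(key=lambda h: (h.period, -h.length))
    kept: list[RepeatHit] = []
    for h in candidates:
        redundant = any(
            min(h.end, k.end) - max(h.start, k.start) + 1 >= 0.5 * h.length
            for k in kept)
        if not redundant:
            kept.append(h)
    return _suppress_overlaps(kept)


def find_stem_loops(seq: str, min_stem: int = 5, max_loop: int = 20,
                    max_mismatch: int = 1, min_loop: int = 3) -> list[StemLoopHit]:
    """Inverted repeats folding into hairpins.

    For every candidate loop the two arms are extended outwards while at most
    ``max_mismatch`` non-complementary pairs accumulate; terminal mismatches
    are trimmed so stems start and end on complementary pairs.  The reported
    ``motif_match`` flags loops (alone or with up to three flanking bases on
    each side) matching T+(TC)(TC)T+.
    """
    seq = seq.upper()
    n = len(seq)
    hits: list[StemLoopHit] = []
    for loop_start in range(1, n - min_loop):       # 0-based first loop base
        for loop_len in range(min_loop, max_loop + 1):
            i = loop_start - 1                       # last base before the loop
            j = loop_start + loop_len                # first base after the loop
            if j >= n:
                break
            pairs = []                               # (i, j, complementary)
            mismatches = 0
            while i >= 0 and j < n:
                comp = (seq[i], seq[j]) in _PAIRS
                if not comp:
                    mismatches += 1
                    if mismatches > max_mismatch:
                        break
                pairs.append((i, j, comp))
                i -= 1
                j += 1
            while pairs and not pairs[-1][2]:        # trim outer mismatches
                pairs.pop()
            if not pairs or not pairs[0][2]:
                continue
            if len(pairs) < min_stem:
                continue
            outer_i, outer_j, _ = pairs[-1]
            loop_seq = seq[loop_start:loop_start + loop_len]
            hits.append(StemLoopHit(
                arm5_start=outer_i + 1, arm5_end=loop_start,
                arm3_start=loop_start + loop_len + 1, arm3_end=outer_j + 1,
                stem_len=len(pairs),
                mismatches=sum(1 for p in pairs if not p[2]),
                loop_seq=loop_seq,
                motif_match=_loop_matches(seq, loop_start, loop_len)))
    # keep the strongest hairpin per overlapping cluster; strength is the
    # number of complementary pairs (mismatches add length, not strength).
    # Motif-carrying and plain hairpins are suppressed as separate classes,
    # so a loop-motif hairpin is never masked by a stronger overlapping fold.
    hits.sort(key=lambda h: (-(h.stem_len - h.mismatches), h.mismatches,
                             h.arm5_start))
    kept: list[StemLoopHit] = []
    for h in hits:
        if all(h.arm3_end < k.arm5_start or h.arm5_start > k.arm3_end
               for k in kept if k.motif_match == h.motif_match):
            kept.append(h)
    kept.sort(key=lambda h: h.arm5_start)
    return kept


def _loop_matches(seq: str, loop_start: int, loop_len: int) -> bool:
    for left in range(4):
        for right in range(4):
            lo = loop_start - left
            hi = loop_start + loop_len + right
            if lo < 0 or hi > len(seq):
                continue
            if _LOOP_MOTIF.fullmatch(seq[lo:hi]):
                return True
    return False


def scan_control_region(record: MitogenomeRecord,
                        min_period: int = 10, min_copies: float = 1.9,
                        min_identity: float = 0.85,
                        microsat_min_copies: int = 3,
                        min_stem: int = 5, max_loop: int = 20,
                        max_mismatch: int = 1) -> dict[str, list]:
    """All three scans restricted to the record's control region.

    Coordinates in the returned hits are relative to the CR sequence
    (1 = first CR base).
    """
    cr = record.control_region()
    if cr is None:
        raise KeyError(f"{record.id}: no control region annotated")
    seq = extract_region(record, cr)
    return {
        "microsatellites": find_microsatellites(seq, min_copies=microsat_min_copies),
        "tandem_repeats": find_tandem_repeats(seq, min_period=min_period,
                                              min_copies=min_copies,
                                              min_identity=min_identity),
        "stem_loops": find_stem_loops(seq, min_stem=min_stem,
                                      max_loop=max_loop,
                                      max_mismatch=max_mismatch),
    }


def reconstruct_repeat(hit: RepeatHit) -> str:
    """Perfect tiling of the motif over the hit's span (for identity checks)."""
    reps = -(-hit.length // hit.period)
    return (hit.motif * reps)[:hit.length]


__all__ = [
    "RepeatHit", "StemLoopHit", "find_microsatellites", "find_tandem_repeats",
    "find_stem_loops", "scan_control_region", "reconstruct_repeat",
    "reverse_complement",
]
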