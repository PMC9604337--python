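"""Census of tRNA secondary-structure geometry and base-pair mismatches.

Structures are inputs (dot-bracket strings from an external predictor), not
predictions.  The census distinguishes Watson-Crick pairs, GU wobble pairs,
and the named mismatch classes (AC, UU, AA) seen in mitochondrial tRNAs.
Because published mismatch totals usually count GU among the "unmatched"
pairs, both a GU-inclusive total and a strict non-canonical total are
reported.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import MitocompError

WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
ARM_NAMES = ("acceptor", "DHU", "anticodon", "TpsiC")


@dataclass
class Arm:
    name: str
    stem_pairs: int
    loop_len: int | None      # None for the acceptor (no closing loop)
    simple_loop: bool = False  # arm present only as an unpaired loop


@dataclass
class TrnaStructure:
    name: str
    sequence: str              # RNA alphabet internally (T -> U on input)
    pairing: str               # dot-bracket
    pairs: list[tuple[int, int]]  # 0-based (i, j) with i < j
    arms: dict[str, Arm] = field(default_factory=dict)


@dataclass
class MismatchCensus:
    class_counts: dict[str, int]          # WatsonCrick, GU, AC, UU, AA, other
    total_pairs: int
    gu_inclusive_mismatches: int          # every non-Watson-Crick pair
    strict_mismatches: int                # non-Watson-Crick, non-GU


def _extract_pairs(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs = []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise MitocompError(f"unbalanced bracket at position {i + 1}")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise MitocompError(f"unexpected character {ch!r} in dot-bracket")
    if stack:
        raise MitocompError(f"unbalanced bracket at position {stack[-1] + 1}")
    pairs.sort()
    return pairs


def _helices(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group pairs into stacked helices ((i, j) followed by (i+1, j-1))."""
    helices = []
    by_i = sorted(pairs)
    used = set()
    for p in by_i:
        if p in used:
            continue
        helix = [p]
        used.add(p)
        i, j = p
        while (i + 1, j - 1) in set(pairs):
            i, j = i + 1, j - 1
            helix.append((i, j))
            used.add((i, j))
        helices.append(helix)
    return helices


def parse_structure(name: str, seq: str, db: str) -> TrnaStructure:
    """Parse one sequence + dot-bracket pair and label cloverleaf arms.

    The outermost helix is the acceptor stem; the helices hanging off the
    central multiloop are labelled DHU, anticodon and TpsiC in 5'->3' order.
    When only two inner helices exist the DHU arm is recorded as a simple
    loop (the trnS1 configuration).
    """
    if len(seq) != len(db):
        raise MitocompError(f"{name}: sequence and structure lengths differ")
    seq = seq.upper().replace("T", "U")
    pairs = _extract_pairs(db)
    helices = _helices(pairs)
    struct = TrnaStructure(name=name, sequence=seq, pairing=db, pairs=pairs)
    if not helices:
        return struct
    # acceptor = helix whose outermost pair encloses everything else
    helices.sort(key=lambda h: h[0][0])
    acceptor = helices[0]
    inner = helices[1:]
    struct.arms["acceptor"] = Arm("acceptor", stem_pairs=len(acceptor),
                                  loop_len=None)
    inner_names = ["DHU", "anticodon", "TpsiC"]
    if len(inner) == 2:
        struct.arms["DHU"] = Arm("DHU", stem_pairs=0, loop_len=None,
                                 simple_loop=True)
        inner_names = ["anticodon", "TpsiC"]
    for arm_name, helix in zip(inner_names, inner):
        i, j = helix[-1]  # innermost pair closes the loop
        struct.arms[arm_name] = Arm(arm_name, stem_pairs=len(helix),
                                    loop_len=j - i - 1)
    return struct


def _classify_pair(x: str, y: str) -> str:
    if (x, y) in WATSON_CRICK:
        return "WatsonCrick"
    if {x, y} == {"G", "U"}:
        return "GU"
    if {x, y} == {"A", "C"}:
        return "AC"
    if x == y == "U":
        return "UU"
    if x == y == "A":
        return "AA"
    return "other"


def mismatch_census(structs: list[TrnaStructure]) -> MismatchCensus:
    """Aggregate pair-class counts over a set of structures.

    Classes partition the paired positions exactly; classification is
    unordered, so reversing a structure leaves the census unchanged.
    """
    counts = {c: 0 for c in ("WatsonCrick", "GU", "AC", "UU", "AA", "other")}
    for s in structs:
        for i, j in s.pairs:
            counts[_classify_pair(s.sequence[i], s.sequence[j])] += 1
    total = sum(counts.values())
    non_wc = total - counts["WatsonCrick"]
    return MismatchCensus(class_counts=counts, total_pairs=total,
                          gu_inclusive_mismatches=non_wc,
                          strict_mismatches=non_wc - counts["GU"])


def arm_geometry_report(structs: list[TrnaStructure]) -> pd.DataFrame:
    """Per-tRNA arm geometry with deviation flags.

    Mitochondrial tRNAs near-universally keep a 7-pair acceptor stem and a
    7-base anticodon loop; departures from either are flagged.
    """
    rows = []
    for s in structs:
        acc = s.arms.get("acceptor")
        anti = s.arms.get("anticodon")
        dhu = s.arms.get("DHU")
        tpc = s.arms.get("TpsiC")
        flags = []
        if acc and acc.stem_pairs != 7:
            flags.append(f"acceptor stem {acc.stem_pairs} pairs")
        if anti and anti.loop_len != 7:
            flags.append(f"anticodon loop {anti.loop_len} nt")
        if dhu and dhu.simple_loop:
            flags.append("DHU arm is a simple loop")
        rows.append({
            "trna": s.name,
            "acceptor_stem": acc.stem_pairs if acc else 0,
            "dhu_stem": dhu.stem_pairs if dhu else 0,
            "dhu_loop": dhu.loop_len if dhu and not dhu.simple_loop else None,
            "anticodon_stem": anti.stem_pairs if anti else 0,
            "anticodon_loop": anti.loop_len if anti else None,
            "tpsic_stem": tpc.stem_pairs if tpc else 0,
            "tpsic_loop": tpc.loop_len if tpc else None,
            "flags": "; ".join(flags),
        })
    return pd.DataFrame(rows).set_index("trna")


def read_structures(path) -> list[TrnaStructure]:
    """Read three-line records: '>name', sequence, dot-bracket."""
    structs = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise MitocompError(f"{path}: expected '>name' at line {i + 1}")
        structs.append(parse_structure(lines[i][1:].strip(),
                                       lines[i + 1], lines[i + 2]))
        i += 3
    return structs
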