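"""tRNA secondary-structure census from dot-bracket structures.

Structures come from an external predictor; here two illustrative
cloverleafs are written inline — one canonical, one with a GU wobble and
an AC mismatch in the acceptor stem and a DHU arm reduced to a simple
loop (the trnS1 configuration).
"""
from mitocomp import arm_geometry_report, mismatch_census, parse_structure

CANONICAL_DB = ("(((((((" + ".." + "((((" + "........" + "))))" + "." +
                "(((((" + "......." + ")))))" + "....." +
                "(((((" + "......." + ")))))" + ")))))))" + "....")
S1_DB = ("(((((((" + "......." +
         "(((((" + "......." + ")))))" + "..." +
         "(((((" + "......." + ")))))" + ")))))))")


def paired_seq(db, overrides=None):
    seq = ["G" if c == "(" else "C" if c == ")" else "A" for c in db]
    for pos, base in (overrides or {}).items():
        seq[pos] = base
    return "".join(seq)


structs = [
    parse_structure("trnK", paired_seq(CANONICAL_DB), CANONICAL_DB),
    # GU wobble at the outermost acceptor pair (G0-U57), AC mismatch at the
    # second (A1-C56)
    parse_structure("trnS1", paired_seq(S1_DB, {57: "U", 1: "A"}), S1_DB),
]

census = mismatch_census(structs)
print("pair-class census over", len(structs), "structures:")
for cls, n in census.class_counts.items():
    print(f"  {cls:12s} {n}")
print(f"  mismatches: {census.gu_inclusive_mismatches} counting GU, "
      f"{census.strict_mismatches} strict")

print("\narm geometry:")
print(arm_geometry_report(structs).to_string())
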