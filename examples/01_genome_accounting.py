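"""Coordinate-level accounting on the six bundled mole-cricket gene tables.

No sequence data needed: spacers/overlaps, strand census, control-region
span and cross-genome junction conservation all derive from the published
coordinates alone.
"""
from mitocomp import (load_all_references, load_reference, shared_junctions,
                      spacer_overlap_report, strand_census)

henana = load_reference("gryllotalpa_henana")
rep = spacer_overlap_report(henana, use_declared_ign=True)
census = strand_census(henana)

print(f"{henana.id}: {henana.length} bp, {len(henana.features)} features")
print(f"  strand census: {census['J']} genes on J, {census['N']} on N")
print(f"  spacers:  {rep.spacer_count:2d} junctions, {rep.spacer_total_bp} bp"
      f" (longest {rep.spacer_max_bp} bp)")
print(f"  overlaps: {rep.overlap_count:2d} junctions, {rep.overlap_total_bp} bp"
      f" (longest {rep.overlap_max_bp} bp)")
print(f"  control region: {henana.control_region().span(henana.length)} bp")

refs = load_all_references()
print(f"\nJunction conservation across {len(refs)} genomes:")
shared = shared_junctions(list(refs.values()), use_declared_ign=True)
for g in shared["overlaps"]:
    print(f"  conserved overlap {g.upstream} | {g.downstream}: {-g.ign} bp")
for g in shared["spacers"]:
    print(f"  conserved spacer  {g.upstream} | {g.downstream}: {g.ign} bp")
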