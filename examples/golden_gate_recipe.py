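"""From binding site to Golden Gate pipetting recipe.

Encodes a 15 bp binding site as RVD modules, picks the kit plasmids
(slot-cycled array modules plus the last-half-repeat plasmid) and scales
volumes from the local stock-concentration table at 75 ng per module.
"""

from talenforge import compute_volumes, pick_modules, rvd_encode
from talenforge.recipes import load_default_layout, load_default_reagents

site = "TCAGGCTGAACGGCT"
rvds = rvd_encode(site)
print("site:", site)
print("RVDs:", " ".join(rvds))

picks = pick_modules(rvds, load_default_layout())
rows = compute_volumes(picks, load_default_reagents(), target_mass_ng=75)
for row in rows:
    print(f"  position {row.position:>2}: {row.plasmid:<8} {row.volume_uL:>4} uL  ({row.mass_ng} ng)")
print("-> one module plasmid per repeat; the final repeat comes from the pLR half-repeat plasmid.")
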