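"""Restriction-site screening of a spacer for RFLP readout.

Plants a fragment whose spacer holds one NsiI site (ATGCAT), plus an
identical decoy 100 bp downstream, and screens it against the packaged
enzyme set.  NsiI is reported with the signed offset of the second cut;
an enzyme with a second cut closer than 80 bp would be dropped because
the RFLP gel could not resolve the bands.
"""

from talenforge import PlantSpec, analyze_pair, enumerate_pairs, load_default_db, parse_template
from talenforge.fixtures import DEFAULT_SPACER_SITE_OFFSET, generate_planted_fragment

spec = PlantSpec(seed=7, insert_at=60)
fragment, truth = generate_planted_fragment(spec)
nsii_pos = truth.spacer.start + DEFAULT_SPACER_SITE_OFFSET

decoyed = PlantSpec(seed=7, insert_at=60, decoy_sites=(("ATGCAT", nsii_pos + 100),))
fragment, truth = generate_planted_fragment(decoyed)

(pair,) = enumerate_pairs(fragment, parse_template(truth.template), truth.config)
for hit in analyze_pair(pair, fragment, load_default_db()):
    kind = "unique in amplicon" if hit.unique_in_amplicon else f"second cut at {hit.second_cut_rel:+d} bp"
    print(f"{hit.enzyme.name} ({hit.enzyme.prototype}): position {hit.spacer_pos} [{hit.strand}], {kind}")
print("-> position is the first base of the recognition site, 1-based from the fragment start.")
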