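"""Exon-targeted design from an annotated gene record.

Generates a synthetic two-exon GenBank record, lets the feature
prioritizer pick the mRNA, extracts exon 1 with its short (25 bp) and
long (150 bp) flanks, and enumerates TALEN pairs under the classical
consensus template Ts[ACG][CGT].*Te.  Reported spans are 1-based relative
to the exon start minus the short flank.
"""

from talenforge import (
    SearchConfig,
    enumerate_pairs,
    extract_fragment,
    parse_gene_record,
    parse_template,
    select_feature,
)
from talenforge.fixtures import generate_gene_record

gb_text = generate_gene_record(2, [400, 200], [100], [{"kind": "mRNA"}], seed=30, symbol="genx")
record = parse_gene_record(gb_text)
feature = select_feature(record)
print(f"selected feature: {feature.kind} with {len(feature.intervals)} exon blocks")

fragment = extract_fragment(record, feature, "E", 1)
print(f"fragment {fragment.region_label}: core {fragment.core}, {len(fragment.sequence)} bp with flanks")

pairs = enumerate_pairs(fragment, parse_template("Ts[ACG][CGT].*Te"), SearchConfig())
print(f"{len(pairs)} candidate pairs in exon 1")
p = pairs[0]
first = fragment.to_report_coord(p.site1.start)
print(f"Site 1: TAL1 {first}-{first + p.site1.length - 1}({p.site1.length})  {p.site1_seq}")
print("RVD1:", " ".join(p.rvd1))
print("-> each pair is a TAL1/spacer/TAL2 triple; the RVDs are the module order for assembly.")
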