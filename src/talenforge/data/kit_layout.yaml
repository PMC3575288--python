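# Golden Gate TALEN kit layout: module plasmids are named by RVD and slot
# (slots cycle within each 10-repeat sub-array); the final repeat uses the
# last-half-repeat plasmid. Edit this file for kit revisions.
name: golden-gate-talen-kit
min_rvds: 12
max_rvds: 31
slots_per_array: 10
module_plasmid: "p{rvd}{slot}"
last_repeat_plasmid: "pLR-{rvd}"
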