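"""End-to-end design from a FASTA file.

Writes a small synthetic fragment carrying one TALEN site to a temporary
FASTA, runs the full pipeline (template scan -> RVD encoding -> RFLP
screen) and prints the flat-text report.  The TAL1/TAL2 spans use the
first-last(length) notation; the enzyme line gives name, prototype, buffer
score [0-9], absolute cut position, strand and (empty here) the relative
second cut — empty means the enzyme cuts the amplicon exactly once, which
is what an RFLP readout needs.
"""

import tempfile
from pathlib import Path

from talenforge import PipelineConfig, PlantSpec, render_text, run_pipeline
from talenforge.fixtures import planted_fragment_fasta

with tempfile.TemporaryDirectory() as tmp:
    fasta = Path(tmp) / "fragment.fasta"
    fasta.write_text(planted_fragment_fasta(PlantSpec(seed=5, insert_at=60), name="frag5"))

    records = run_pipeline(
        PipelineConfig(fasta=str(fasta), site_min=15, site_max=15, spacer_min=16, spacer_max=16)
    )

print(render_text(records))
print(f"-> {len(records)} candidate site(s); the NsiI hit makes this pair RFLP-screenable.")
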