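import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from talenforge.annotation import Fragment
from talenforge.enzymes import load_default_db


def make_fragment(seq: str, short_flank: int = 0, long_flank: int = 0, core=None) -> Fragment:
    """Wrap a bare sequence as a whole-sequence fragment (flanks already in
    the string when nonzero)."""
    n = len(seq)
    if core is None:
        core = (long_flank, n - long_flank)
    return Fragment(
        region_kind="A",
        region_index=1,
        core=core,
        short_flank=short_flank,
        long_flank=long_flank,
        sequence=seq,
        offset_to_record=core[0] - long_flank,
    )


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def genbank_flat_text(seq: str, feature_lines: str, accession: str = "TESTREC01") -> str:
    """Assemble a GenBank flat file by hand (independently of any writer)."""
    origin = []
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60].lower()
        blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        origin.append(f"{i + 1:>9} {blocks}")
    return (
        f"LOCUS       {accession:<16}{len(seq):>12} bp    DNA     linear   SYN 01-JAN-2020\n"
        f"DEFINITION  synthetic test record.\n"
        f"ACCESSION   {accession}\n"
        f"VERSION     {accession}.1\n"
        f"FEATURES             Location/Qualifiers\n"
        f"{feature_lines}"
        f"ORIGIN\n" + "\n".join(origin) + "\n//\n"
    )


@pytest.fixture(scope="session")
def default_db():
    return load_default_db()
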