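"""Restriction-enzyme database: REBASE parsing, vendor filtering, buffer
scores.

Input is a Bairoch-style REBASE flat file (``ID`` name, ``RS`` recognition
site with optional cut-position annotations, ``CR`` commercial-source
letter codes, records closed by ``//``).  Only commercially available
enzymes — those with at least one supplier code — are retained.  Prototype
names (the first-described member of each isoschizomer family) come from a
separate two-column table, and PCR-buffer compatibility scores from a
three-column activity table, rescaled onto [0,9] with 0 meaning no
activity.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources

IUPAC_CODES = set("ACGTRYSWKMBDHVN")

BUFFERS = ("standard", "thermopol", "phusion", "crimson")

_CUT_ANNOTATION = re.compile(r"\^|\((-?\d+)(/-?\d+)?\)")


class RebaseParseError(ValueError):
    pass


@dataclass(frozen=True)
class Enzyme:
    name: str
    prototype: str
    recognition: str  # degenerate IUPAC, cut annotations stripped
    rs_raw: str  # RS field as parsed (cut annotations retained)
    vendor_codes: frozenset
    buffer_scores: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not self.recognition:
            raise ValueError(f"{self.name}: empty recognition site")
        bad = set(self.recognition) - IUPAC_CODES
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC letter(s) {sorted(bad)}")
        for buf, score in self.buffer_scores.items():
            if not 0 <= score <= 9:
                raise ValueError(f"{self.name}: buffer score {score} outside [0,9]")


@dataclass(frozen=True)
class EnzymeDb:
    enzymes: tuple
    source_version: str = "unknown"

    def __iter__(self):
        return iter(self.enzymes)

    def __len__(self):
        return len(self.enzymes)

    def names(self):
        return [e.name for e in self.enzymes]

    def get(self, name: str) -> Enzyme:
        for e in self.enzymes:
            if e.name == name:
                return e
        raise KeyError(name)


def rescale_buffer_score(raw: float, raw_max: float) -> int:
    """Rescale a raw activity value onto the displayed [0,9] range.

    0 means no activity and ``raw_max`` maps to 9; intermediate values
    round half up.
    """
    if raw_max <= 0:
        raise ValueError("raw_max must be > 0")
    if not 0 <= raw <= raw_max:
        raise ValueError(f"raw activity {raw} outside [0, {raw_max}]")
    return int(math.floor(9 * raw / raw_max + 0.5))


def _parse_two_col(text: str) -> dict:
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise RebaseParseError(f"bad prototype-table line: {line!r}")
        out[parts[0]] = parts[1]
    return out


def _parse_buffer_table(text: str, raw_max: float) -> dict:
    scores: dict = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise RebaseParseError(f"bad buffer-score line: {line!r}")
        name, buf, raw = parts[0], parts[1], float(parts[2])
        if buf not in BUFFERS:
            raise RebaseParseError(f"unknown buffer {buf!r} (expected one of {BUFFERS})")
        scores.setdefault(name, {})[buf] = rescale_buffer_score(raw, raw_max)
    return scores


def parse_rebase(
    rebase_text: str,
    prototype_table: str = "",
    buffer_table: str = "",
    raw_max: float = 100.0,
) -> EnzymeDb:
    """Parse a Bairoch-style REBASE file into an :class:`EnzymeDb`.

    Enzymes lacking any commercial-source (CR) code are dropped.  Cut
    annotations in the RS field (``^`` or parenthesized offsets such as
    ``(1/5)``) are stripped for matching but retained in ``rs_raw``.
    """
    prototypes = _parse_two_col(prototype_table) if prototype_table else {}
    buffer_scores = _parse_buffer_table(buffer_table, raw_max) if buffer_table else {}

    version = "unknown"
    enzymes = []
    fields: dict = {}
    for raw_line in rebase_text.splitlines():
        line = raw_line.rstrip()
        if line.startswith("CC"):
            m = re.search(r"REBASE version\s+(\S+)", line)
            if m:
                version = m.group(1)
            continue
        if not line:
            continue
        if line == "//":
            if fields:
                enzymes.extend(_finish_record(fields, prototypes, buffer_scores))
                fields = {}
            continue
        code, _, value = line.partition("   ")
        code, value = code.strip(), value.strip()
        if len(code) != 2 or not code.isalpha():
            raise RebaseParseError(f"unrecognized line in record {fields.get('ID', '?')!r}: {raw_line!r}")
        fields.setdefault(code, []).append(value)
    if fields:
        enzymes.extend(_finish_record(fields, prototypes, buffer_scores))
    return EnzymeDb(enzymes=tuple(enzymes), source_version=version)


def _finish_record(fields: dict, prototypes: dict, buffer_scores: dict):
    if "ID" not in fields:
        raise RebaseParseError(f"record without ID line: fields {sorted(fields)}")
    name = fields["ID"][0]
    if "RS" not in fields:
        raise RebaseParseError(f"record {name!r} has no RS recognition-site line")
    rs_raw = fields["RS"][0].rstrip(";")
    # some enzymes list two sites "A, B"; the first is used for matching
    first = rs_raw.split(",")[0].strip()
    recognition = _CUT_ANNOTATION.sub("", first).upper()
    vendor_letters = frozenset(
        c for chunk in fields.get("CR", []) for c in chunk if c.isalpha()
    )
    if not vendor_letters:
        return []  # not commercially available: dropped
    return [
        Enzyme(
            name=name,
            prototype=prototypes.get(name, name),
            recognition=recognition,
            rs_raw=rs_raw,
            vendor_codes=vendor_letters,
            buffer_scores=buffer_scores.get(name, {}),
        )
    ]


def filter_by_vendor(db: EnzymeDb, codes) -> EnzymeDb:
    """Keep enzymes sold by at least one of the given supplier codes.

    The kept enzymes' vendor codes are narrowed to the selection, so
    successive filters compose like a set intersection.
    """
    codes = set(codes)
    if not codes:
        raise ValueError("vendor code set must be nonempty")
    kept = tuple(
        Enzyme(
            name=e.name,
            prototype=e.prototype,
            recognition=e.recognition,
            rs_raw=e.rs_raw,
            vendor_codes=e.vendor_codes & codes,
            buffer_scores=e.buffer_scores,
        )
        for e in db
        if e.vendor_codes & codes
    )
    return EnzymeDb(enzymes=kept, source_version=db.source_version)


def write_rebase(db: EnzymeDb) -> str:
    """Serialize back to the Bairoch-style dialect (name/RS/CR fields)."""
    lines = [f"CC   REBASE version {db.source_version}"]
    for e in db:
        lines.append(f"ID   {e.name}")
        lines.append(f"RS   {e.rs_raw};")
        lines.append(f"CR   {''.join(sorted(e.vendor_codes))}.")
        lines.append("//")
    return "\n".join(lines) + "\n"


def _data(name: str) -> str:
    return resources.files("talenforge.data").joinpath(name).read_text()


def load_default_db(vendors=None) -> EnzymeDb:
    """Load the packaged miniature REBASE snapshot (with prototypes and
    buffer scores), optionally narrowed to the given vendor codes."""
    db = parse_rebase(
        _data("rebase_mini.txt"),
        prototype_table=_data("prototypes.tsv"),
        buffer_table=_data("buffer_scores.tsv"),
    )
    if vendors:
        db = filter_by_vendor(db, vendors)
    return db
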