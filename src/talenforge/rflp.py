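"""Restriction-site screening of TALEN spacers for RFLP readout.

After a TALEN cut is repaired by error-prone NHEJ, a restriction site in
the spacer is usually destroyed; an enzyme whose site occurs exactly once
in the PCR amplicon then reports editing as uncut product.  For each
candidate pair this module finds recognition-site matches inside the
spacer and classifies their uniqueness over the amplicon window (the pair
plus a long flank, default 150 bp, on each side).

A "cut position" throughout is the position of the first base of the
recognition-site match; enzymatic cut offsets within the site are not
modeled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .enzymes import Enzyme, EnzymeDb

IUPAC_TO_BASES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

#: Default minimum spacing (bp) to a second cut in the amplicon.
DEFAULT_MIN_SECOND_CUT = 80


def iupac_reverse_complement(pattern: str) -> str:
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(pattern.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC letter {exc.args[0]!r}") from None


def _compiled(pattern: str):
    # lookahead so overlapping occurrences are all reported; classes list
    # concrete bases only, so placeholder N in the sequence never matches
    parts = []
    for c in pattern.upper():
        if c not in IUPAC_TO_BASES:
            raise ValueError(f"invalid IUPAC letter {c!r} in recognition site")
        bases = IUPAC_TO_BASES[c]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("(?=" + "".join(parts) + ")")


def match_recognition(seq: str, recognition: str) -> list:
    """All matches of a degenerate recognition site on both strands.

    Returns sorted ``(position, strand)`` with 0-based positions of the
    match's first base on the forward strand.  For palindromic sites the
    reverse-strand scan would duplicate every forward hit, so only ``+``
    hits are reported (palindrome collapse).
    """
    seq = seq.upper()
    rec = recognition.upper()
    hits = [(m.start(), "+") for m in _compiled(rec).finditer(seq)]
    rc = iupac_reverse_complement(rec)
    if rc != rec:
        hits += [(m.start(), "-") for m in _compiled(rc).finditer(seq)]
    return sorted(hits)


@dataclass(frozen=True)
class EnzymeHit:
    """A usable RFLP enzyme for one candidate pair.

    ``spacer_pos`` is 1-based from the start of the extracted fragment
    (long flank included).  ``second_cut_rel`` is the signed offset of the
    nearest other amplicon match when one exists at an acceptable distance;
    it is absent for enzymes that cut the amplicon exactly once.
    """

    enzyme: Enzyme
    spacer_pos: int
    strand: str
    unique_in_amplicon: bool
    second_cut_rel: int | None = None

    def __post_init__(self):
        if self.unique_in_amplicon and self.second_cut_rel is not None:
            raise ValueError("unique hit cannot carry a second-cut offset")


def amplicon_window(pair, fragment, long_flank: int = 150) -> tuple:
    """(start, end) of the amplicon span: pair plus long flanks, clipped to
    the fragment."""
    start = max(0, pair.site1.start - long_flank)
    end = min(len(fragment.sequence), pair.site2.end + long_flank)
    return start, end


def analyze_pair(
    pair,
    fragment,
    db: EnzymeDb,
    long_flank: int = 150,
    min_second_cut: int = DEFAULT_MIN_SECOND_CUT,
) -> list:
    """Screen every enzyme in ``db`` against one candidate pair.

    An enzyme qualifies when a recognition-site match lies entirely within
    the spacer.  If it is the only match in the amplicon window the hit is
    unique; if other matches exist and the nearest is at least
    ``min_second_cut`` bp away (first base to first base) the hit carries
    that signed offset; enzymes with a closer second match are dropped.
    The leftmost spacer match is the primary hit.  Hits are sorted by
    enzyme name.  Spacers containing the placeholder N yield no hits.
    """
    seq = fragment.sequence
    spacer_seq = seq[pair.spacer.start : pair.spacer.end]
    if "N" in spacer_seq:
        return []
    win_start, win_end = amplicon_window(pair, fragment, long_flank)

    hits = []
    for enzyme in db:
        rec_len = len(enzyme.recognition)
        matches = match_recognition(seq, enzyme.recognition)
        in_spacer = [
            m for m in matches if m[0] >= pair.spacer.start and m[0] + rec_len <= pair.spacer.end
        ]
        if not in_spacer:
            continue
        in_amplicon = [m for m in matches if m[0] >= win_start and m[0] + rec_len <= win_end]
        primary = in_spacer[0]
        others = [m for m in in_amplicon if m != primary]
        if not others:
            hits.append(
                EnzymeHit(enzyme=enzyme, spacer_pos=primary[0] + 1, strand=primary[1], unique_in_amplicon=True)
            )
            continue
        nearest = min(others, key=lambda m: (abs(m[0] - primary[0]), m[0]))
        if abs(nearest[0] - primary[0]) >= min_second_cut:
            hits.append(
                EnzymeHit(
                    enzyme=enzyme,
                    spacer_pos=primary[0] + 1,
                    strand=primary[1],
                    unique_in_amplicon=False,
                    second_cut_rel=nearest[0] - primary[0],
                )
            )
        # else: a second cut too close for RFLP band resolution — dropped
    hits.sort(key=lambda h: h.enzyme.name)
    return hits
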