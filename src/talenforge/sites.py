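"""Binding-site consensus templates and TALEN pair enumeration.

A TALEN pair is two TAL-effector binding sites separated by a spacer in
which the FokI domains dimerize and cut.  Candidate sites are found with a
small consensus-template notation:

* ``T`` before the ``s`` marker — a thymine must immediately precede the
  binding site (the one empirically robust constraint);
* ``s`` / ``e`` — start and end of the binding site;
* ``[ACG]`` — an allowed-base set at the next site position;
* ``.*`` — unconstrained interior;
* a ``T`` directly before ``e`` mirrors the preceding-T requirement onto
  the second arm (which binds the reverse strand).

The default template is ``Ts.*e``; the classical, more restrictive one is
``Ts[ACG][CGT].*Te``.  The first arm is matched on the forward strand and
the second arm on the reverse strand, so on the forward strand a pair reads
``T <site1> <spacer> <site2> A``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .rvd import rvd_encode

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class TemplateError(ValueError):
    """Raised for malformed template notation; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (N stays N)."""
    s = seq.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"non-IUPAC character(s) in sequence: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Template:
    """Compiled binding-site consensus."""

    require_preceding_t: bool
    leading_constraints: tuple[frozenset, ...] = ()
    notation: str = ""


def parse_template(notation: str) -> Template:
    """Compile template notation into a :class:`Template`.

    Raises :class:`TemplateError` on unknown tokens, a missing ``s``/``e``
    marker, or ``e`` occurring before ``s``.
    """
    if "s" not in notation:
        raise TemplateError("missing 's' site-start marker", len(notation))
    if "e" not in notation:
        raise TemplateError("missing 'e' site-end marker", len(notation))
    si, ei = notation.index("s"), notation.index("e")
    if ei < si:
        raise TemplateError("'e' marker before 's'", ei)

    prefix, body, suffix = notation[:si], notation[si + 1 : ei], notation[ei + 1 :]
    if suffix:
        raise TemplateError(f"unexpected token {suffix[0]!r} after 'e'", ei + 1)
    if prefix not in ("", "T"):
        raise TemplateError(f"unknown token {prefix!r} before 's'", 0)
    require_t = prefix == "T"

    leading: list[frozenset] = []
    j = 0
    while j < len(body) and not body.startswith(".*", j):
        c = body[j]
        if c == "[":
            k = body.find("]", j)
            if k < 0:
                raise TemplateError("unterminated '['", si + 1 + j)
            bases = body[j + 1 : k]
            if not bases or set(bases) - set("ACGT"):
                raise TemplateError(f"invalid base set {bases!r}", si + 1 + j)
            leading.append(frozenset(bases))
            j = k + 1
        elif c in "ACGT":
            leading.append(frozenset(c))
            j += 1
        else:
            raise TemplateError(f"unknown token {c!r}", si + 1 + j)
    if not body.startswith(".*", j):
        raise TemplateError("missing '.*' wildcard interior", si + 1 + j)
    j += 2
    rest = body[j:]
    if rest == "T":
        require_t = True  # mirrored preceding-T of the reverse-strand arm
    elif rest:
        raise TemplateError(f"unknown token {rest[0]!r} after '.*'", si + 1 + j)
    return Template(require_t, tuple(leading), notation)


@dataclass(frozen=True)
class SearchConfig:
    """Length ranges and scan options for pair enumeration.

    Defaults match the published tool: binding sites 15-17 bp, spacer
    15-16 bp.
    """

    site_len_range: tuple = (15, 17)
    spacer_len_range: tuple = (15, 16)
    increment_override: int | None = None
    single_site: bool = False

    def __post_init__(self):
        for lo, hi in (self.site_len_range, self.spacer_len_range):
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid length range ({lo}, {hi}): need 1 <= min <= max")
        if self.increment_override is not None and self.increment_override < 1:
            raise ValueError("increment override must be >= 1")


def increment_for_length(fragment_core_length: int, override: int | None = None) -> int:
    """Scan-start increment for the first arm.

    Enumeration is exhaustive (step 1) for cores of 999 bp or less; long
    regions are thinned to keep output usable: step 10 from 1000 bp and
    step 20 from 5000 bp.
    """
    if fragment_core_length < 0:
        raise ValueError("length must be >= 0")
    if override is not None:
        if override < 1:
            raise ValueError("increment override must be >= 1")
        return override
    if fragment_core_length >= 5000:
        return 20
    if fragment_core_length >= 1000:
        return 10
    return 1


@dataclass(frozen=True)
class Span:
    """Half-open interval given as (start, length), 0-based."""

    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class CandidatePair:
    """One enumerated TALEN pair, in fragment coordinates (0-based)."""

    index: int
    site1: Span
    spacer: Span
    site2: Span
    site1_seq: str
    spacer_seq: str
    site2_seq: str
    site2_revcomp: str
    rvd1: tuple = field(default=())
    rvd2: tuple = field(default=())


@dataclass(frozen=True)
class SingleSite:
    """A forward-strand binding site found in single-site mode."""

    index: int
    site: Span
    site_seq: str
    rvd: tuple = field(default=())


def _forward_site_ok(seq: str, start: int, length: int, t: Template) -> bool:
    if start < 0 or start + length > len(seq):
        return False
    site = seq[start : start + length]
    if length < len(t.leading_constraints):
        return False
    for b in site:
        if b not in "ACGT":
            return False
    if t.require_preceding_t and (start == 0 or seq[start - 1] != "T"):
        return False
    for cset, b in zip(t.leading_constraints, site):
        if b not in cset:
            return False
    return True


def _reverse_site_ok(seq: str, start: int, length: int, t: Template) -> bool:
    """Template check for the second arm, which binds the reverse strand."""
    if start < 0 or start + length > len(seq):
        return False
    site = seq[start : start + length]
    if length < len(t.leading_constraints):
        return False
    for b in site:
        if b not in "ACGT":
            return False
    # preceding T on the reverse strand == A immediately after the site on
    # the forward strand
    if t.require_preceding_t and (start + length >= len(seq) or seq[start + length] != "A"):
        return False
    rc = reverse_complement(site)
    for cset, b in zip(t.leading_constraints, rc):
        if b not in cset:
            return False
    return True


def _scan_window(fragment) -> tuple[int, int]:
    # the first arm must start inside core +/- short flank, never in the
    # long flank beyond it
    lo = max(0, fragment.long_flank - fragment.short_flank)
    hi = min(len(fragment.sequence), fragment.long_flank + fragment.core_length + fragment.short_flank)
    return lo, hi


def enumerate_pairs(fragment, template: Template, config: SearchConfig | None = None) -> list:
    """Enumerate every TALEN pair satisfying the template and length ranges.

    First-arm starts are stepped by :func:`increment_for_length` of the core
    length; pairs are ordered by (site1 start, site1 length, spacer length,
    site2 length) and numbered from 1.  Arms containing the placeholder N
    are rejected; spacers may contain N (downstream enzyme analysis then
    yields nothing for that pair).
    """
    config = config or SearchConfig()
    seq = fragment.sequence
    inc = increment_for_length(fragment.core_length, config.increment_override)
    lo, hi = _scan_window(fragment)
    l1min, l1max = config.site_len_range
    smin, smax = config.spacer_len_range
    pairs = []
    for p in range(lo, hi, inc):
        for len1 in range(l1min, l1max + 1):
            if not _forward_site_ok(seq, p, len1, template):
                continue
            for sp in range(smin, smax + 1):
                s2 = p + len1 + sp
                for len2 in range(l1min, l1max + 1):
                    if _reverse_site_ok(seq, s2, len2, template):
                        site1 = Span(p, len1)
                        spacer = Span(p + len1, sp)
                        site2 = Span(s2, len2)
                        s1seq = seq[p : p + len1]
                        spseq = seq[spacer.start : spacer.end]
                        s2seq = seq[s2 : s2 + len2]
                        s2rc = reverse_complement(s2seq)
                        pairs.append(
                            CandidatePair(
                                index=len(pairs) + 1,
                                site1=site1,
                                spacer=spacer,
                                site2=site2,
                                site1_seq=s1seq,
                                spacer_seq=spseq,
                                site2_seq=s2seq,
                                site2_revcomp=s2rc,
                                rvd1=rvd_encode(s1seq),
                                rvd2=rvd_encode(s2rc),
                            )
                        )
    return pairs


def enumerate_single_sites(fragment, template: Template, config: SearchConfig | None = None) -> list:
    """Enumerate forward-strand single binding sites (no pairing, and no
    downstream enzyme analysis in this mode)."""
    config = config or SearchConfig(single_site=True)
    seq = fragment.sequence
    inc = increment_for_length(fragment.core_length, config.increment_override)
    lo, hi = _scan_window(fragment)
    l1min, l1max = config.site_len_range
    out = []
    for p in range(lo, hi, inc):
        for length in range(l1min, l1max + 1):
            if _forward_site_ok(seq, p, length, template):
                s = seq[p : p + length]
                out.append(SingleSite(index=len(out) + 1, site=Span(p, length), site_seq=s, rvd=rvd_encode(s)))
    return out
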