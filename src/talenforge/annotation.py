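"""Gene records, feature prioritization and fragment extraction.

A :class:`GeneRecord` is a genomic sequence plus its subsequence features
(mRNA / CDS / misc RNA / exon).  Targets are designed against an exon, an
intron, or the whole sequence; the extracted :class:`Fragment` carries two
flank widths:

* the *short* flank (default 25 bp) lets binding sites near the ends of a
  short exon be found — reported positions are 1-based relative to the
  region start minus this flank;
* the *long* flank (default 150 bp) defines the PCR-amplicon window within
  which restriction-site uniqueness is judged for RFLP readout.

Sequence beyond the record boundary is padded with the placeholder N,
which never matches a template position or an enzyme site.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

#: Reported-position flank default (bp).
DEFAULT_SHORT_FLANK = 25
#: Amplicon-window flank default (bp).
DEFAULT_LONG_FLANK = 150

_GENBANK_KINDS = {"mRNA": "mRNA", "CDS": "CDS", "misc_RNA": "miscRNA", "exon": "exon"}
#: Feature priority when the user states no preference.
FEATURE_PRIORITY = ("mRNA", "CDS", "miscRNA", "exon")


class GenBankParseError(ValueError):
    pass


class SelectionError(ValueError):
    pass


class RegionError(ValueError):
    pass


class FeatureSelectionWarning(UserWarning):
    pass


@dataclass(frozen=True)
class Feature:
    kind: str
    label: str | None
    transcript_id: str | None
    intervals: tuple  # ordered, non-overlapping (start, end) 0-based half-open

    def __post_init__(self):
        if not self.intervals:
            raise ValueError("feature has no intervals")
        prev_end = -1
        for s, e in self.intervals:
            if s >= e or s < prev_end:
                raise ValueError(f"intervals not sorted/non-overlapping: {self.intervals}")
            prev_end = e


@dataclass(frozen=True)
class GeneRecord:
    accession: str
    symbol: str
    aliases: tuple
    sequence: str
    contig_span: tuple
    strand: str
    features: tuple

    def __post_init__(self):
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.intervals:
                if s < 0 or e > n:
                    raise ValueError(f"feature interval ({s},{e}) outside sequence of length {n}")


@dataclass(frozen=True)
class WholeSequenceSelection:
    """Sentinel: no subsequence feature available, use the entire sequence."""

    region_kind: str = "A"


WHOLE_SEQUENCE = WholeSequenceSelection()


@dataclass(frozen=True)
class FeaturePreference:
    kind: str | None = None
    index: int | None = None  # 1-based among candidate features of the kind
    transcript_id: str | None = None


@dataclass(frozen=True)
class Fragment:
    """An exon/intron/whole-sequence slice with flanks, in its own 0-based
    coordinates; ``offset_to_record`` maps fragment position 0 back to the
    record (may be negative when the long flank over-runs the start)."""

    region_kind: str  # E, I or A
    region_index: int
    core: tuple  # (start, end) in record coordinates
    short_flank: int
    long_flank: int
    sequence: str
    offset_to_record: int

    def __post_init__(self):
        if len(self.sequence) != self.core_length + 2 * self.long_flank:
            raise ValueError("fragment length inconsistent with core and long flank")

    @property
    def core_length(self) -> int:
        return self.core[1] - self.core[0]

    @property
    def region_label(self) -> str:
        return f"{self.region_kind}{self.region_index}"

    def to_record_coord(self, fragment_pos: int) -> int:
        return fragment_pos + self.offset_to_record

    def to_report_coord(self, fragment_pos: int) -> int:
        """1-based reported position, relative to core start minus the
        short flank."""
        return fragment_pos - (self.long_flank - self.short_flank) + 1


def parse_gene_record(genbank_text: str) -> GeneRecord:
    """Parse a GenBank flat-file record into a :class:`GeneRecord`.

    Captures every mRNA/CDS/misc_RNA/exon feature with its /gene label and
    (where present) /transcript_id; the gene symbol and aliases come from
    the record's gene feature.  The sequence is upper-cased.
    """
    try:
        rec = SeqIO.read(io.StringIO(genbank_text), "genbank")
    except Exception as exc:  # Biopython raises several error types here
        raise GenBankParseError(f"malformed GenBank record: {exc}") from exc
    try:
        seq = str(rec.seq).upper()
    except Exception as exc:
        raise GenBankParseError("record has no usable ORIGIN sequence") from exc
    if not seq:
        raise GenBankParseError("record has no ORIGIN sequence")

    symbol, aliases = "", []
    features = []
    for f in rec.features:
        if f.type == "gene" and not symbol:
            symbol = f.qualifiers.get("gene", [""])[0]
            for q in f.qualifiers.get("gene_synonym", []):
                aliases.extend(a.strip() for a in q.split(";") if a.strip())
        elif f.type in _GENBANK_KINDS:
            intervals = tuple(sorted((int(p.start), int(p.end)) for p in f.location.parts))
            features.append(
                Feature(
                    kind=_GENBANK_KINDS[f.type],
                    label=f.qualifiers.get("gene", [None])[0],
                    transcript_id=f.qualifiers.get("transcript_id", [None])[0],
                    intervals=intervals,
                )
            )
    return GeneRecord(
        accession=rec.id or rec.name,
        symbol=symbol,
        aliases=tuple(aliases),
        sequence=seq,
        contig_span=(0, len(seq)),
        strand="+",
        features=tuple(features),
    )


def _label_ok(feature: Feature, allowed: set) -> bool:
    # features annotated under another gene (other reading frames etc.) are
    # excluded; unlabeled features are kept as they cannot be attributed
    if not allowed or feature.label is None:
        return True
    return feature.label.casefold() in allowed


def select_feature(record: GeneRecord, preference: FeaturePreference | None = None):
    """Pick the subsequence feature to design against.

    Priority is mRNA > CDS > misc RNA (> grouped exon features); only
    features labeled with the gene symbol or one of its aliases are
    considered.  With several candidates the first is used and a warning
    issued, unless the preference names an index or transcript identifier.
    A kind in the preference restricts the search to that kind (e.g. CDS
    skips mRNA).  Returns :data:`WHOLE_SEQUENCE` when no feature applies.
    """
    pref = preference or FeaturePreference()
    if pref.kind and pref.kind not in FEATURE_PRIORITY:
        raise SelectionError(f"unknown feature kind {pref.kind!r}")
    if not record.features:
        warnings.warn("record has no subsequence features; using the entire sequence", FeatureSelectionWarning)
        return WHOLE_SEQUENCE

    allowed = {x.casefold() for x in (record.symbol, *record.aliases) if x}
    order = (pref.kind,) if pref.kind else FEATURE_PRIORITY
    for kind in order:
        if kind == "exon":
            exon_feats = [f for f in record.features if f.kind == "exon" and _label_ok(f, allowed)]
            if not exon_feats:
                continue
            # exon features are the smallest unit and are used as a group
            intervals = tuple(sorted(iv for f in exon_feats for iv in f.intervals))
            cands = [Feature(kind="exon", label=exon_feats[0].label, transcript_id=None, intervals=intervals)]
        else:
            cands = [f for f in record.features if f.kind == kind and _label_ok(f, allowed)]
        if not cands:
            continue
        if pref.transcript_id is not None:
            hits = [f for f in cands if f.transcript_id == pref.transcript_id]
            if not hits:
                raise SelectionError(f"no {kind} feature with transcript id {pref.transcript_id!r}")
            return hits[0]
        if pref.index is not None:
            if not 1 <= pref.index <= len(cands):
                raise SelectionError(f"feature index {pref.index} out of range 1..{len(cands)} for kind {kind}")
            return cands[pref.index - 1]
        if len(cands) > 1:
            warnings.warn(
                f"{len(cands)} {kind} features match; using the first (set an index or transcript id to override)",
                FeatureSelectionWarning,
            )
        return cands[0]

    if pref.kind:
        raise SelectionError(f"record has no {pref.kind} features matching the gene symbol")
    warnings.warn("no matching subsequence features; using the entire sequence", FeatureSelectionWarning)
    return WHOLE_SEQUENCE


def _introns(feature: Feature) -> list:
    ivs = feature.intervals
    return [(ivs[k][1], ivs[k + 1][0]) for k in range(len(ivs) - 1)]


def extract_fragment(
    record: GeneRecord,
    feature_or_whole,
    region_kind: str,
    region_index: int = 1,
    short_flank: int = DEFAULT_SHORT_FLANK,
    long_flank: int = DEFAULT_LONG_FLANK,
) -> Fragment:
    """Slice the requested exon (E), intron (I) or whole sequence (A) out of
    the record with ``long_flank`` bp on each side, padding with N beyond
    the record boundary.  Intron k lies between exon k and exon k+1."""
    if short_flank < 0 or long_flank < 0:
        raise ValueError("flanks must be >= 0")
    if region_kind == "A" or isinstance(feature_or_whole, WholeSequenceSelection):
        core = (0, len(record.sequence))
        region_kind, region_index = "A", 1
    elif region_kind == "E":
        ivs = feature_or_whole.intervals
        if not 1 <= region_index <= len(ivs):
            raise RegionError(f"exon index {region_index} out of range; available exons: 1..{len(ivs)}")
        core = ivs[region_index - 1]
    elif region_kind == "I":
        gaps = _introns(feature_or_whole)
        if not gaps:
            raise RegionError("feature has a single exon block: no introns available")
        if not 1 <= region_index <= len(gaps):
            raise RegionError(f"intron index {region_index} out of range; available introns: 1..{len(gaps)}")
        core = gaps[region_index - 1]
    else:
        raise RegionError(f"unknown region kind {region_kind!r}; expected E, I or A")

    start, end = core[0] - long_flank, core[1] + long_flank
    n = len(record.sequence)
    left_pad = max(0, -start)
    right_pad = max(0, end - n)
    seq = "N" * left_pad + record.sequence[max(0, start) : min(n, end)] + "N" * right_pad
    return Fragment(
        region_kind=region_kind,
        region_index=region_index,
        core=core,
        short_flank=short_flank,
        long_flank=long_flank,
        sequence=seq,
        offset_to_record=start,
    )


_EUTILS_BASE = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def build_efetch_request(accession: str, start: int, end: int, strand: str = "+") -> str:
    """Deterministic NCBI EFetch URL for a genomic span (1-based inclusive).

    Only constructed, never executed, by this package; pass the URL to your
    own HTTP client if online retrieval is wanted.
    """
    if not accession:
        raise ValueError("empty accession")
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    if start < 1:
        raise ValueError("EFetch coordinates are 1-based")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    strand_code = 1 if strand == "+" else 2
    return (
        f"{_EUTILS_BASE}?db=nuccore&id={accession}"
        f"&seq_start={start}&seq_stop={end}&strand={strand_code}"
        f"&rettype=gb&retmode=text"
    )
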