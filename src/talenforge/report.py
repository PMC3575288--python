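"""Report rendering and the end-to-end design pipeline.

Reports are one block (or CSV row group) per candidate site.  The two
arms are labeled TAL1 and TAL2; the first site and spacer read in the
forward direction regardless of source strand, and TAL2's reverse
complement — the strand the second TAL protein actually binds — is shown
alongside.  Binding-site spans use the ``first-last(length)`` notation,
1-based relative to the region start minus the short flank; enzyme
positions are 1-based from the start of the extracted fragment (long
flank included).  For an enzyme that cuts the amplicon once the
second-cut column is empty.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace

from Bio import SeqIO

from . import annotation, enzymes, rflp, sites
from .rvd import rvd_text


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class HitRow:
    """One report row for a usable RFLP enzyme."""

    enzyme: str
    prototype: str
    buffer_score: int | None
    position: int  # 1-based, fragment coordinates
    strand: str
    second_cut_rel: int | None


@dataclass(frozen=True)
class SiteRecord:
    gene_symbol: str
    region_label: str
    site_index: int
    tal1_span: tuple  # (first, last, length) in reported coordinates
    tal1_seq: str
    rvd1: tuple
    spacer_span: tuple | None
    spacer_seq: str
    tal2_span: tuple | None
    tal2_seq: str
    tal2_revcomp: str
    rvd2: tuple
    hits: tuple = field(default=())

    def __post_init__(self):
        for span in (self.tal1_span, self.spacer_span, self.tal2_span):
            if span is not None and span[1] - span[0] + 1 != span[2]:
                raise ValueError(f"inconsistent span {span}: last-first+1 != length")


def _span(fragment, s: sites.Span) -> tuple:
    first = fragment.to_report_coord(s.start)
    return (first, first + s.length - 1, s.length)


def span_str(span: tuple | None) -> str:
    return "" if span is None else f"{span[0]}-{span[1]}({span[2]})"


def _parse_span(text: str) -> tuple | None:
    if not text:
        return None
    left, _, rest = text.partition("(")
    first, _, last = left.partition("-")
    return (int(first), int(last), int(rest.rstrip(")")))


def build_site_records(
    pairs,
    hits_by_index: dict,
    fragment,
    gene_symbol: str,
    buffer: str = "standard",
) -> list:
    """Assemble report records from enumerated pairs (or single sites) and
    their enzyme hits."""
    records = []
    for item in pairs:
        if isinstance(item, sites.CandidatePair):
            hit_rows = tuple(
                HitRow(
                    enzyme=h.enzyme.name,
                    prototype=h.enzyme.prototype,
                    buffer_score=h.enzyme.buffer_scores.get(buffer),
                    position=h.spacer_pos,
                    strand=h.strand,
                    second_cut_rel=h.second_cut_rel,
                )
                for h in hits_by_index.get(item.index, ())
            )
            records.append(
                SiteRecord(
                    gene_symbol=gene_symbol,
                    region_label=fragment.region_label,
                    site_index=item.index,
                    tal1_span=_span(fragment, item.site1),
                    tal1_seq=item.site1_seq,
                    rvd1=item.rvd1,
                    spacer_span=_span(fragment, item.spacer),
                    spacer_seq=item.spacer_seq,
                    tal2_span=_span(fragment, item.site2),
                    tal2_seq=item.site2_seq,
                    tal2_revcomp=item.site2_revcomp,
                    rvd2=item.rvd2,
                    hits=hit_rows,
                )
            )
        else:  # single-site mode: no pairing, no enzyme analysis
            records.append(
                SiteRecord(
                    gene_symbol=gene_symbol,
                    region_label=fragment.region_label,
                    site_index=item.index,
                    tal1_span=_span(fragment, item.site),
                    tal1_seq=item.site_seq,
                    rvd1=item.rvd,
                    spacer_span=None,
                    spacer_seq="",
                    tal2_span=None,
                    tal2_seq="",
                    tal2_revcomp="",
                    rvd2=(),
                    hits=(),
                )
            )
    return records


TEXT_HEADER = (
    "# TALEN design report\n"
    "# spans: first-last(length), 1-based, relative to the region start minus the short flank\n"
    "# enzyme positions: 1-based from the start of the extracted fragment (long flank included)\n"
    "# enzyme columns: name, prototype, buffer score [0-9], position, strand, second cut (empty when the amplicon is cut once)\n"
)


def render_text(records) -> str:
    """Flat-text report, one block per site."""
    out = [TEXT_HEADER]
    for r in records:
        lines = [f"{r.gene_symbol}\t{r.region_label}\tSite {r.site_index}"]
        lines.append(f"TAL1\t{span_str(r.tal1_span)}\t{r.tal1_seq}")
        lines.append(f"RVD1\t{rvd_text(r.rvd1)}")
        if r.tal2_span is not None:
            lines.append(f"Spacer\t{span_str(r.spacer_span)}\t{r.spacer_seq}")
            lines.append(f"TAL2\t{span_str(r.tal2_span)}\t{r.tal2_seq}")
            lines.append(f"TAL2 (reverse complement)\t{span_str(r.tal2_span)}\t{r.tal2_revcomp}")
            lines.append(f"RVD2\t{rvd_text(r.rvd2)}")
        if r.hits:
            lines.append("Enzymes:")
            for h in r.hits:
                score = "" if h.buffer_score is None else str(h.buffer_score)
                second = "" if h.second_cut_rel is None else str(h.second_cut_rel)
                lines.append(f"\t{h.enzyme}\t{h.prototype}\t{score}\t{h.position}\t{h.strand}\t{second}")
        out.append("\n".join(lines) + "\n")
    return "\n".join(out)


CSV_COLUMNS = [
    "gene", "region", "site",
    "tal1_span", "tal1_seq", "tal1_rvds",
    "spacer_span", "spacer_seq",
    "tal2_span", "tal2_seq", "tal2_revcomp", "tal2_rvds",
    "enzyme", "prototype", "buffer_score", "position", "strand", "second_cut",
]


def render_csv(records) -> str:
    """RFC-4180 CSV, one row per (site, enzyme hit); a site without hits
    still yields one row with empty enzyme columns."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(CSV_COLUMNS)
    for r in records:
        base = [
            r.gene_symbol, r.region_label, r.site_index,
            span_str(r.tal1_span), r.tal1_seq, rvd_text(r.rvd1, sep=" "),
            span_str(r.spacer_span), r.spacer_seq,
            span_str(r.tal2_span), r.tal2_seq, r.tal2_revcomp, rvd_text(r.rvd2, sep=" "),
        ]
        if not r.hits:
            w.writerow(base + [""] * 6)
        else:
            for h in r.hits:
                w.writerow(
                    base
                    + [
                        h.enzyme,
                        h.prototype,
                        "" if h.buffer_score is None else h.buffer_score,
                        h.position,
                        h.strand,
                        "" if h.second_cut_rel is None else h.second_cut_rel,
                    ]
                )
    return buf.getvalue()


def parse_csv(text: str) -> list:
    """Inverse of :func:`render_csv` for the serializable fields."""
    rows = list(csv.reader(io.StringIO(text)))
    if not rows or rows[0] != CSV_COLUMNS:
        raise ValueError("unrecognized CSV header")
    records: dict = {}
    order = []
    for row in rows[1:]:
        d = dict(zip(CSV_COLUMNS, row))
        key = (d["gene"], d["region"], int(d["site"]))
        if key not in records:
            order.append(key)
            records[key] = SiteRecord(
                gene_symbol=d["gene"],
                region_label=d["region"],
                site_index=int(d["site"]),
                tal1_span=_parse_span(d["tal1_span"]),
                tal1_seq=d["tal1_seq"],
                rvd1=tuple(d["tal1_rvds"].split()) if d["tal1_rvds"] else (),
                spacer_span=_parse_span(d["spacer_span"]),
                spacer_seq=d["spacer_seq"],
                tal2_span=_parse_span(d["tal2_span"]),
                tal2_seq=d["tal2_seq"],
                tal2_revcomp=d["tal2_revcomp"],
                rvd2=tuple(d["tal2_rvds"].split()) if d["tal2_rvds"] else (),
                hits=(),
            )
        if d["enzyme"]:
            hit = HitRow(
                enzyme=d["enzyme"],
                prototype=d["prototype"],
                buffer_score=int(d["buffer_score"]) if d["buffer_score"] else None,
                position=int(d["position"]),
                strand=d["strand"],
                second_cut_rel=int(d["second_cut"]) if d["second_cut"] else None,
            )
            records[key] = replace(records[key], hits=records[key].hits + (hit,))
    return [records[k] for k in order]


def render_html(records) -> str:
    """Minimal HTML wrapper around the text report (reverse-strand enzyme
    hits are already marked with '-' in the strand column)."""
    body = render_text(records)
    return "<html><body><pre>\n" + body.replace("<", "&lt;").replace(">", "&gt;") + "</pre></body></html>\n"


@dataclass
class PipelineConfig:
    """Everything the end-to-end design run needs; exactly one of ``fasta``
    or ``gene_file`` must be given."""

    fasta: str | None = None
    gene_file: str | None = None
    record_id: str | None = None
    region: str = "A"
    region_index: int = 1
    feature_kind: str | None = None
    feature_index: int | None = None
    transcript_id: str | None = None
    short_flank: int = annotation.DEFAULT_SHORT_FLANK
    long_flank: int = annotation.DEFAULT_LONG_FLANK
    template: str = "Ts.*e"
    site_min: int = 15
    site_max: int = 17
    spacer_min: int = 15
    spacer_max: int = 16
    increment: int | None = None
    single_site: bool = False
    rebase: str | None = None
    prototypes: str | None = None
    buffer_scores: str | None = None
    vendors: str | None = None
    buffer: str = "standard"
    min_second_cut: int = rflp.DEFAULT_MIN_SECOND_CUT


def _load_fasta(path: str, record_id: str | None):
    recs = list(SeqIO.parse(path, "fasta"))
    if not recs:
        raise PipelineError(f"no FASTA records in {path}")
    if record_id is None:
        rec = recs[0]
    else:
        matches = [r for r in recs if r.id == record_id]
        if not matches:
            raise PipelineError(f"no FASTA record {record_id!r} in {path}")
        rec = matches[0]
    seq = str(rec.seq).upper()
    return annotation.GeneRecord(
        accession=rec.id, symbol=rec.id, aliases=(), sequence=seq,
        contig_span=(0, len(seq)), strand="+", features=(),
    )


def run_pipeline(config: PipelineConfig) -> list:
    """Run annotation -> site search -> RVD -> RFLP and return the report
    records.  Deterministic for fixed inputs."""
    if bool(config.fasta) == bool(config.gene_file):
        raise PipelineError("exactly one of fasta or gene_file must be given")

    if config.fasta:
        record = _load_fasta(config.fasta, config.record_id)
        selection = annotation.WHOLE_SEQUENCE
        if config.region != "A":
            raise PipelineError("FASTA input carries no features; only region A is available")
    else:
        with open(config.gene_file) as fh:
            record = annotation.parse_gene_record(fh.read())
        pref = annotation.FeaturePreference(
            kind=config.feature_kind, index=config.feature_index, transcript_id=config.transcript_id
        )
        selection = annotation.select_feature(record, pref)

    fragment = annotation.extract_fragment(
        record, selection, config.region, config.region_index,
        short_flank=config.short_flank, long_flank=config.long_flank,
    )
    template = sites.parse_template(config.template)
    search = sites.SearchConfig(
        site_len_range=(config.site_min, config.site_max),
        spacer_len_range=(config.spacer_min, config.spacer_max),
        increment_override=config.increment,
        single_site=config.single_site,
    )

    if config.single_site:
        found = sites.enumerate_single_sites(fragment, template, search)
        return build_site_records(found, {}, fragment, record.symbol, buffer=config.buffer)

    pairs = sites.enumerate_pairs(fragment, template, search)
    if config.rebase:
        with open(config.rebase) as fh:
            rebase_text = fh.read()
        proto = open(config.prototypes).read() if config.prototypes else ""
        bufs = open(config.buffer_scores).read() if config.buffer_scores else ""
        db = enzymes.parse_rebase(rebase_text, prototype_table=proto, buffer_table=bufs)
        if config.vendors:
            db = enzymes.filter_by_vendor(db, set(config.vendors))
    else:
        db = enzymes.load_default_db(vendors=set(config.vendors) if config.vendors else None)

    hits_by_index = {
        p.index: rflp.analyze_pair(p, fragment, db, long_flank=config.long_flank, min_second_cut=config.min_second_cut)
        for p in pairs
    }
    return build_site_records(pairs, hits_by_index, fragment, record.symbol, buffer=config.buffer)
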