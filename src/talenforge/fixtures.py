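"""Deterministic synthetic inputs: fragments with planted TALEN pairs and
enzyme sites, and GenBank records with chosen feature combinations.

The planted-fragment generator emulates a test sequence designed to hold a
single TALEN site: a ``T <site1> <spacer> <site2> A`` construct dropped
into a seeded background, optionally with restriction-site decoys planted
outside the spacer.  Uniqueness is verified by brute force at the planted
geometry (site lengths and spacer length pinned); the default background
is G/C-only because T...A pair anchors in an A/T-containing background
would recreate spurious candidates at almost every position, which no
amount of redrawing could remove.  All coordinates of the construct are
returned as ground truth.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .annotation import Fragment
from .sites import SearchConfig, Span, Template, _forward_site_ok, _reverse_site_ok, parse_template


class FixtureError(RuntimeError):
    pass


#: Default planted arms (G/C-only so they contribute no pair anchors) and a
#: 16 bp spacer carrying a unique NsiI site (ATGCAT) at offset 5.
DEFAULT_SITE1 = "CCGGCCGGCGCGCGC"
DEFAULT_SITE2 = "GCGCGCGGCCGGCCG"
DEFAULT_SPACER = "CGCGG" + "ATGCAT" + "CCGCG"
#: Offset of the NsiI recognition site within DEFAULT_SPACER.
DEFAULT_SPACER_SITE_OFFSET = 5


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one planted fragment; every field is explicit so the same
    spec always regenerates the same sequence."""

    seed: int
    background_length: int = 300
    gc_fraction: float = 1.0
    site1: str = DEFAULT_SITE1
    site2: str = DEFAULT_SITE2
    spacer: str = DEFAULT_SPACER
    decoy_sites: tuple = ()  # ((concrete ACGT sequence, fragment position), ...)
    insert_at: int | None = None  # position of the anchor T; seeded when None
    template: str = "Ts.*e"
    max_attempts: int = 50


@dataclass(frozen=True)
class PlantTruth:
    """Ground-truth coordinates recorded alongside a planted fragment."""

    site1: Span
    spacer: Span
    site2: Span
    config: SearchConfig
    template: str
    decoy_sites: tuple


def _draw_background(rng: random.Random, length: int, gc_fraction: float) -> list:
    w_gc = gc_fraction / 2.0
    w_at = (1.0 - gc_fraction) / 2.0
    return rng.choices("GCAT", weights=[w_gc, w_gc, w_at, w_at], k=length)


def _brute_force_pairs(seq: str, template: Template, config: SearchConfig) -> list:
    """Exhaustive scan at increment 1 over the whole sequence."""
    l1min, l1max = config.site_len_range
    smin, smax = config.spacer_len_range
    found = []
    for p in range(len(seq)):
        for len1 in range(l1min, l1max + 1):
            if not _forward_site_ok(seq, p, len1, template):
                continue
            for sp in range(smin, smax + 1):
                for len2 in range(l1min, l1max + 1):
                    if _reverse_site_ok(seq, p + len1 + sp, len2, template):
                        found.append((p, len1, sp, len2))
    return found


def generate_planted_fragment(spec: PlantSpec) -> tuple:
    """Build a fragment holding exactly one TALEN pair at the planted
    geometry; returns ``(Fragment, PlantTruth)``.

    Raises :class:`FixtureError` when no background satisfying uniqueness
    is found within the attempt budget (longer background or lower A/T
    content usually fixes this).
    """
    for s in (spec.site1, spec.site2, spec.spacer):
        if set(s) - set("ACGT"):
            raise FixtureError(f"planted sequence must be concrete ACGT text: {s!r}")
    construct = "T" + spec.site1 + spec.spacer + spec.site2 + "A"
    L = spec.background_length
    if L < len(construct) + 2:
        raise FixtureError(f"background of {L} bp cannot hold a {len(construct)} bp construct")

    rng = random.Random(spec.seed)
    p0 = spec.insert_at if spec.insert_at is not None else rng.randrange(1, L - len(construct) - 1)
    site1 = Span(p0 + 1, len(spec.site1))
    spacer = Span(site1.end, len(spec.spacer))
    site2 = Span(spacer.end, len(spec.site2))

    template = parse_template(spec.template)
    config = SearchConfig(
        site_len_range=(min(len(spec.site1), len(spec.site2)), max(len(spec.site1), len(spec.site2))),
        spacer_len_range=(len(spec.spacer), len(spec.spacer)),
    )
    expected = {(site1.start, site1.length, spacer.length, site2.length)}

    for decoy_seq, pos in spec.decoy_sites:
        if set(decoy_seq) - set("ACGT"):
            raise FixtureError(f"decoy must be concrete ACGT text: {decoy_seq!r}")
        if pos < 0 or pos + len(decoy_seq) > L:
            raise FixtureError(f"decoy at {pos} falls outside the {L} bp fragment")
        if pos + len(decoy_seq) > spacer.start and pos < spacer.end:
            raise FixtureError(f"decoy at {pos} overlaps the spacer; decoys must lie outside it")
        if pos + len(decoy_seq) > p0 and pos < p0 + len(construct):
            raise FixtureError(f"decoy at {pos} overlaps the planted construct")

    for _ in range(spec.max_attempts):
        chars = _draw_background(rng, L, spec.gc_fraction)
        chars[p0 : p0 + len(construct)] = construct
        for decoy_seq, pos in spec.decoy_sites:
            chars[pos : pos + len(decoy_seq)] = decoy_seq
        seq = "".join(chars)
        if set(_brute_force_pairs(seq, template, config)) == expected:
            fragment = Fragment(
                region_kind="A",
                region_index=1,
                core=(0, L),
                short_flank=0,
                long_flank=0,
                sequence=seq,
                offset_to_record=0,
            )
            truth = PlantTruth(
                site1=site1,
                spacer=spacer,
                site2=site2,
                config=config,
                template=spec.template,
                decoy_sites=tuple(spec.decoy_sites),
            )
            return fragment, truth
    raise FixtureError(
        f"no unique planting found in {spec.max_attempts} attempts; "
        "try a longer background or a lower A/T content"
    )


_KIND_TO_GENBANK = {"mRNA": "mRNA", "CDS": "CDS", "miscRNA": "misc_RNA", "exon": "exon"}


def generate_gene_record(
    n_exons: int,
    exon_lengths,
    intron_lengths,
    features,
    seed: int,
    symbol: str = "genx",
    aliases=(),
    margin: int = 60,
) -> str:
    """Emit a syntactically valid GenBank flat file with the requested
    exon/intron structure and subsequence features.

    ``features`` is a list of dicts with keys ``kind`` (mRNA / CDS /
    miscRNA / exon), optional ``label`` (defaults to the gene symbol) and
    optional ``transcript_id``.  mRNA/CDS/miscRNA features span all exon
    blocks; an ``exon`` entry emits one single-interval feature per exon.
    """
    if isinstance(exon_lengths, int):
        exon_lengths = [exon_lengths] * n_exons
    if isinstance(intron_lengths, int):
        intron_lengths = [intron_lengths] * max(0, n_exons - 1)
    if len(exon_lengths) != n_exons or len(intron_lengths) != max(0, n_exons - 1):
        raise ValueError("exon/intron length lists inconsistent with n_exons")
    if any(x <= 0 for x in [*exon_lengths, *intron_lengths]):
        raise ValueError("lengths must be positive")

    intervals = []
    pos = margin
    for i, elen in enumerate(exon_lengths):
        intervals.append((pos, pos + elen))
        pos += elen
        if i < len(intron_lengths):
            pos += intron_lengths[i]
    total = pos + margin

    rng = random.Random(seed)
    seq = "".join(rng.choices("ACGT", k=total))

    def _location(ivs):
        locs = [SimpleLocation(s, e, strand=1) for s, e in ivs]
        return locs[0] if len(locs) == 1 else CompoundLocation(locs)

    gene_q = {"gene": [symbol]}
    if aliases:
        gene_q["gene_synonym"] = ["; ".join(aliases)]
    seq_features = [SeqFeature(SimpleLocation(intervals[0][0], intervals[-1][1], strand=1), type="gene", qualifiers=gene_q)]
    for spec in features:
        kind = spec["kind"]
        if kind not in _KIND_TO_GENBANK:
            raise ValueError(f"unknown feature kind {kind!r}")
        quals = {"gene": [spec.get("label", symbol)]}
        if spec.get("transcript_id"):
            quals["transcript_id"] = [spec["transcript_id"]]
        if kind == "exon":
            for iv in intervals:
                seq_features.append(SeqFeature(_location([iv]), type="exon", qualifiers=dict(quals)))
        else:
            seq_features.append(SeqFeature(_location(intervals), type=_KIND_TO_GENBANK[kind], qualifiers=quals))

    rec = SeqRecord(
        Seq(seq),
        id="SYN000001.1",
        name="SYN000001",
        description=f"synthetic {symbol} locus ({n_exons} exons)",
        features=seq_features,
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    out = io.StringIO()
    SeqIO.write(rec, out, "genbank")
    return out.getvalue()


def planted_fragment_fasta(spec: PlantSpec, name: str = "planted") -> str:
    """FASTA text of a planted fragment (for end-to-end pipeline runs)."""
    fragment, _ = generate_planted_fragment(spec)
    return f">{name} seed={spec.seed}\n" + "\n".join(
        fragment.sequence[i : i + 70] for i in range(0, len(fragment.sequence), 70)
    ) + "\n"
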