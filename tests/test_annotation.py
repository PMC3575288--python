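"""GenBank parsing, feature prioritization and fragment extraction."""

import random

import pytest

from talenforge.annotation import (
    Feature,
    FeaturePreference,
    GenBankParseError,
    GeneRecord,
    RegionError,
    SelectionError,
    WHOLE_SEQUENCE,
    build_efetch_request,
    extract_fragment,
    parse_gene_record,
    select_feature,
)
from talenforge.fixtures import generate_gene_record

from conftest import genbank_flat_text, random_dna

FEATURES = """\
     gene            61..540
                     /gene="abcd1"
                     /gene_synonym="abc-old; zgc:999"
     mRNA            join(61..160,281..380,481..540)
                     /gene="abcd1"
                     /transcript_id="XM_001.1"
     mRNA            join(61..160,481..540)
                     /gene="abcd1"
                     /transcript_id="XM_002.1"
     CDS             join(91..160,281..380)
                     /gene="abcd1"
"""


@pytest.fixture(scope="module")
def record():
    seq = random_dna(random.Random(11), 600)
    return parse_gene_record(genbank_flat_text(seq, FEATURES))


def test_parse_captures_all_subsequence_features(record):
    kinds = sorted(f.kind for f in record.features)
    assert kinds == ["CDS", "mRNA", "mRNA"]
    assert record.symbol == "abcd1"
    assert record.aliases == ("abc-old", "zgc:999")
    assert record.sequence == record.sequence.upper()
    assert len(record.sequence) == 600


def test_parse_converts_locations_to_zero_based_half_open(record):
    mrna = record.features[0]
    assert mrna.intervals == ((60, 160), (280, 380), (480, 540))
    assert mrna.transcript_id == "XM_001.1"


def test_record_without_features_parses_to_empty_list():
    seq = random_dna(random.Random(12), 200)
    rec = parse_gene_record(genbank_flat_text(seq, ""))
    assert rec.features == ()


def test_malformed_or_sequenceless_records_rejected():
    with pytest.raises(GenBankParseError):
        parse_gene_record("this is not genbank\n")
    no_origin = (
        "LOCUS       EMPTY01                  100 bp    DNA     linear   SYN 01-JAN-2020\n"
        "DEFINITION  no sequence.\nACCESSION   EMPTY01\n//\n"
    )
    with pytest.raises(GenBankParseError):
        parse_gene_record(no_origin)


# --- feature selection ----------------------------------------------------

def _rec(features, symbol="abcd1", aliases=("zgc:999",), length=1000):
    return GeneRecord(
        accession="X", symbol=symbol, aliases=tuple(aliases),
        sequence="A" * length, contig_span=(0, length), strand="+",
        features=tuple(features),
    )


def mk(kind, label="abcd1", tid=None, intervals=((10, 50), (100, 150))):
    return Feature(kind=kind, label=label, transcript_id=tid, intervals=tuple(intervals))


def test_mrna_preferred_over_cds():
    got = select_feature(_rec([mk("CDS"), mk("mRNA")]))
    assert got.kind == "mRNA"


def test_cds_then_miscrna_fallback():
    assert select_feature(_rec([mk("CDS"), mk("miscRNA")])).kind == "CDS"
    assert select_feature(_rec([mk("miscRNA")])).kind == "miscRNA"


def test_no_features_falls_back_to_whole_sequence():
    with pytest.warns(UserWarning):
        assert select_feature(_rec([])) is WHOLE_SEQUENCE


def test_multiple_mrnas_first_used_with_warning():
    first = mk("mRNA", tid="t1")
    with pytest.warns(UserWarning, match="first"):
        got = select_feature(_rec([first, mk("mRNA", tid="t2"), mk("mRNA", tid="t3")]))
    assert got is first


def test_index_preference_overrides_first_entry_rule():
    feats = [mk("mRNA", tid="t1"), mk("CDS"), mk("mRNA", tid="t2"), mk("mRNA", tid="t3")]
    got = select_feature(_rec(feats), FeaturePreference(index=2))
    assert got.transcript_id == "t2"
    with pytest.raises(SelectionError, match="out of range"):
        select_feature(_rec(feats), FeaturePreference(index=9))


def test_transcript_id_preference():
    feats = [mk("mRNA", tid="t1"), mk("mRNA", tid="t2")]
    assert select_feature(_rec(feats), FeaturePreference(transcript_id="t2")).transcript_id == "t2"
    with pytest.raises(SelectionError):
        select_feature(_rec(feats), FeaturePreference(transcript_id="missing"))


def test_kind_preference_skips_mrna():
    feats = [mk("mRNA"), mk("CDS", intervals=((20, 60),))]
    got = select_feature(_rec(feats), FeaturePreference(kind="CDS", index=1))
    assert got.kind == "CDS"


def test_features_of_other_genes_excluded_and_aliases_accepted():
    other = mk("mRNA", label="unrelated7")
    aliased = mk("CDS", label="zgc:999")
    got = select_feature(_rec([other, aliased]))
    assert got is aliased  # the alias-labeled CDS beats the foreign mRNA


def test_selection_is_order_independent_given_index():
    rng = random.Random(13)
    feats = [mk("mRNA", tid="t1"), mk("mRNA", tid="t2"), mk("CDS"), mk("miscRNA")]
    for _ in range(10):
        rng.shuffle(feats)
        mrnas = [f for f in feats if f.kind == "mRNA"]
        got = select_feature(_rec(feats), FeaturePreference(index=2))
        assert got is mrnas[1]


def test_exon_features_used_as_a_group_when_nothing_else_matches():
    exons = [mk("exon", intervals=((10, 50),)), mk("exon", intervals=((100, 150),))]
    got = select_feature(_rec(exons))
    assert got.kind == "exon"
    assert got.intervals == ((10, 50), (100, 150))


# --- fragment extraction --------------------------------------------------

def test_exon_at_record_start_is_left_padded():
    rec = _rec([mk("mRNA", intervals=((0, 100), (200, 300)))], length=400)
    frag = extract_fragment(rec, rec.features[0], "E", 1, short_flank=25, long_flank=150)
    assert len(frag.sequence) == 400
    assert frag.sequence[:150] == "N" * 150
    assert "N" not in frag.sequence[150:]
    assert frag.offset_to_record == -150


def test_whole_sequence_with_zero_flanks_is_identity():
    rec = _rec([], length=321)
    frag = extract_fragment(rec, WHOLE_SEQUENCE, "A", 1, short_flank=0, long_flank=0)
    assert frag.sequence == rec.sequence
    assert frag.region_label == "A1"


def test_intron_k_lies_between_exons_k_and_k_plus_one():
    f = mk("mRNA", intervals=((10, 50), (100, 150), (400, 500)))
    rec = _rec([f], length=600)
    frag = extract_fragment(rec, f, "I", 2, short_flank=0, long_flank=0)
    assert frag.core == (150, 400)
    assert frag.region_label == "I2"


def test_region_index_errors_list_available_regions():
    f = mk("mRNA", intervals=((10, 50), (100, 150)))
    rec = _rec([f], length=600)
    with pytest.raises(RegionError, match="1..2"):
        extract_fragment(rec, f, "E", 3)
    with pytest.raises(RegionError, match="1..1"):
        extract_fragment(rec, f, "I", 2)
    with pytest.raises(RegionError):
        extract_fragment(rec, f, "Q", 1)


def test_placeholder_count_equals_window_overhang():
    rec = _rec([mk("mRNA", intervals=((5, 30),))], length=50)
    frag = extract_fragment(rec, rec.features[0], "E", 1, short_flank=0, long_flank=40)
    assert frag.sequence.count("N") == (40 - 5) + (40 - 20)


def test_fragment_positions_map_back_to_the_record():
    for seed in range(5):
        gb = generate_gene_record(3, [120, 80, 140], [60, 90], [{"kind": "mRNA"}], seed=seed)
        rec = parse_gene_record(gb)
        feat = select_feature(rec)
        rng = random.Random(seed)
        kind, idx = rng.choice([("E", 1), ("E", 2), ("E", 3), ("I", 1), ("I", 2)])
        frag = extract_fragment(rec, feat, kind, idx, short_flank=25, long_flank=150)
        for fp in rng.sample(range(len(frag.sequence)), 40):
            rp = frag.to_record_coord(fp)
            if 0 <= rp < len(rec.sequence):
                assert frag.sequence[fp] == rec.sequence[rp]
            else:
                assert frag.sequence[fp] == "N"


def test_report_coordinates_are_relative_to_core_minus_short_flank():
    rec = _rec([mk("mRNA", intervals=((200, 300),))], length=600)
    frag = extract_fragment(rec, rec.features[0], "E", 1, short_flank=25, long_flank=150)
    # fragment position of the core start is long_flank; reported position
    # counts 1-based from core start - short flank
    assert frag.to_report_coord(150) == 26
    assert frag.to_report_coord(150 - 25) == 1


# --- EFetch URL construction ---------------------------------------------

def test_efetch_url_contains_accession_and_indices():
    url = build_efetch_request("NC_007118.5", 21501610, 21527471, "+")
    assert "NC_007118.5" in url and "21501610" in url and "21527471" in url
    assert "strand=1" in url


def test_efetch_degenerate_span_and_reverse_strand():
    url = build_efetch_request("X1", 5, 5, "-")
    assert "seq_start=5" in url and "seq_stop=5" in url and "strand=2" in url


def test_efetch_rejects_bad_arguments():
    with pytest.raises(ValueError):
        build_efetch_request("", 1, 2)
    with pytest.raises(ValueError):
        build_efetch_request("X1", 10, 2)
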