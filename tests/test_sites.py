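"""Template compilation, pair enumeration and its brute-force invariants."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from talenforge.sites import (
    CandidatePair,
    SearchConfig,
    TemplateError,
    enumerate_pairs,
    enumerate_single_sites,
    increment_for_length,
    parse_template,
    reverse_complement,
)

from conftest import make_fragment, random_dna
from oracles import brute_force_pairs, brute_force_single_sites

DNA = st.text(alphabet="ACGT", min_size=0, max_size=60)


# --- template notation ----------------------------------------------------

def test_classical_template_structure():
    t = parse_template("Ts[ACG][CGT].*Te")
    assert t.require_preceding_t
    assert t.leading_constraints == (frozenset("ACG"), frozenset("CGT"))


def test_default_template_structure():
    t = parse_template("Ts.*e")
    assert t.require_preceding_t
    assert t.leading_constraints == ()


def test_permissive_template_has_no_preceding_t():
    t = parse_template("s.*e")
    assert not t.require_preceding_t


@pytest.mark.parametrize(
    "notation",
    ["T.*e", "Ts.*", "Te.*s", "Ts[AC.*e", "Ts[XY].*e", "Qs.*e", "Ts.*Ge", "Ts.*eZ", "Ts[].*e"],
)
def test_malformed_templates_rejected(notation):
    with pytest.raises(TemplateError):
        parse_template(notation)


def test_template_error_reports_position():
    with pytest.raises(TemplateError) as err:
        parse_template("Ts[XY].*e")
    assert err.value.position == 2


# --- scan increment -------------------------------------------------------

@pytest.mark.parametrize(
    "length,expected",
    [(0, 1), (500, 1), (999, 1), (1000, 10), (1500, 10), (4999, 10), (5000, 20), (6000, 20)],
)
def test_increment_thresholds(length, expected):
    assert increment_for_length(length) == expected


def test_increment_override_wins():
    assert increment_for_length(6000, override=3) == 3
    with pytest.raises(ValueError):
        increment_for_length(100, override=0)


# --- reverse complement ---------------------------------------------------

def test_reverse_complement_examples():
    assert reverse_complement("ACGT") == "ACGT"
    assert reverse_complement("AAN") == "NTT"
    with pytest.raises(ValueError):
        reverse_complement("ACGU")


@settings(derandomize=True, max_examples=200)
@given(DNA)
def test_reverse_complement_is_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


# --- enumeration ----------------------------------------------------------

SITE1 = "CCGGCCGGCGCGCGC"
SITE2 = "GCGCGCGGCCGGCCG"
SPACER = "CGCGGATGCATCCGCG"
EXACT = SearchConfig(site_len_range=(15, 15), spacer_len_range=(16, 16))


def planted_sequence(pad="CCCCC"):
    return pad + "T" + SITE1 + SPACER + SITE2 + "A" + pad


def test_planted_pair_recovered_with_exact_coordinates():
    seq = planted_sequence()
    frag = make_fragment(seq)
    pairs = enumerate_pairs(frag, parse_template("Ts.*e"), EXACT)
    assert len(pairs) == 1
    p = pairs[0]
    assert (p.site1.start, p.site1.length) == (6, 15)
    assert (p.spacer.start, p.spacer.length) == (21, 16)
    assert (p.site2.start, p.site2.length) == (37, 15)
    assert p.site1_seq == SITE1 and p.spacer_seq == SPACER and p.site2_seq == SITE2
    assert p.site2_revcomp == reverse_complement(SITE2)
    assert p.index == 1


def test_unsatisfiable_sequence_yields_empty_list():
    frag = make_fragment("C" * 120)
    assert enumerate_pairs(frag, parse_template("Ts.*e"), SearchConfig()) == []


def test_sites_containing_placeholder_are_rejected():
    seq = planted_sequence()
    broken = seq[:10] + "N" + seq[11:]  # N inside site1
    pairs = enumerate_pairs(make_fragment(broken), parse_template("Ts.*e"), EXACT)
    assert pairs == []


def test_spacer_with_placeholder_still_emits_pair():
    seq = planted_sequence()
    broken = seq[:25] + "N" + seq[26:]  # N inside the spacer only
    pairs = enumerate_pairs(make_fragment(broken), parse_template("Ts.*e"), EXACT)
    assert len(pairs) == 1


@pytest.mark.parametrize("notation", ["Ts.*e", "Ts[ACG][CGT].*Te"])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_enumeration_equals_brute_force(notation, seed):
    rng = random.Random(seed)
    seq = random_dna(rng, 200)
    frag = make_fragment(seq)
    t = parse_template(notation)
    cfg = SearchConfig()
    got = {(p.site1.start, p.site1.length, p.spacer.length, p.site2.length)
           for p in enumerate_pairs(frag, t, cfg)}
    want = brute_force_pairs(seq, t.require_preceding_t, t.leading_constraints,
                             cfg.site_len_range, cfg.spacer_len_range)
    assert got == want


def test_single_sites_equal_brute_force_and_planted_case():
    rng = random.Random(3)
    seq = random_dna(rng, 200)
    t = parse_template("Ts[ACG][CGT].*Te")
    cfg = SearchConfig(single_site=True)
    got = {(s.site.start, s.site.length)
           for s in enumerate_single_sites(make_fragment(seq), t, cfg)}
    want = brute_force_single_sites(seq, t.require_preceding_t, t.leading_constraints,
                                    cfg.site_len_range)
    assert got == want

    planted = "CC" + "T" + SITE1 + "CC"
    singles = enumerate_single_sites(
        make_fragment(planted), parse_template("Ts.*e"),
        SearchConfig(site_len_range=(15, 15), single_site=True),
    )
    assert [(s.site.start, s.site.length) for s in singles] == [(3, 15)]


def test_every_emitted_pair_passes_independent_recheck():
    rng = random.Random(4)
    seq = random_dna(rng, 250)
    frag = make_fragment(seq)
    cfg = SearchConfig()
    for p in enumerate_pairs(frag, parse_template("Ts.*e"), cfg):
        assert seq[p.site1.start - 1] == "T"
        assert seq[p.site2.end] == "A"
        assert cfg.site_len_range[0] <= p.site1.length <= cfg.site_len_range[1]
        assert cfg.site_len_range[0] <= p.site2.length <= cfg.site_len_range[1]
        assert cfg.spacer_len_range[0] <= p.spacer.length <= cfg.spacer_len_range[1]
        assert p.site1.end == p.spacer.start and p.spacer.end == p.site2.start


def test_widening_ranges_never_removes_pairs():
    rng = random.Random(5)
    seq = random_dna(rng, 250)
    frag = make_fragment(seq)
    t = parse_template("Ts.*e")
    narrow = {(p.site1.start, p.site1.length, p.spacer.length, p.site2.length)
              for p in enumerate_pairs(frag, t, SearchConfig((15, 16), (15, 15)))}
    wide = {(p.site1.start, p.site1.length, p.spacer.length, p.site2.length)
            for p in enumerate_pairs(frag, t, SearchConfig((15, 17), (15, 16)))}
    assert narrow <= wide


def test_skipping_restricts_to_congruent_start_positions():
    rng = random.Random(6)
    seq = random_dna(rng, 250)
    frag = make_fragment(seq)
    t = parse_template("Ts.*e")
    full = {(p.site1.start, p.site1.length, p.spacer.length, p.site2.length)
            for p in enumerate_pairs(frag, t, SearchConfig())}
    skipped = {(p.site1.start, p.site1.length, p.spacer.length, p.site2.length)
               for p in enumerate_pairs(frag, t, SearchConfig(increment_override=7))}
    assert skipped == {x for x in full if x[0] % 7 == 0}


def test_first_arm_must_start_inside_core_plus_short_flank():
    # pair planted entirely within the long flank: must not be reported
    seq = planted_sequence() + "C" * 110
    n = len(seq)
    frag = make_fragment(seq, short_flank=0, long_flank=60, core=(60, n - 60))
    pairs = enumerate_pairs(frag, parse_template("Ts.*e"), EXACT)
    assert pairs == []  # site1 starts at 6, inside the 60 bp long flank
    frag2 = make_fragment(seq, short_flank=0, long_flank=0)
    assert len(enumerate_pairs(frag2, parse_template("Ts.*e"), EXACT)) == 1


def test_pairs_are_ordered_and_numbered_from_one():
    rng = random.Random(7)
    seq = random_dna(rng, 250)
    pairs = enumerate_pairs(make_fragment(seq), parse_template("Ts.*e"), SearchConfig())
    keys = [(p.site1.start, p.site1.length, p.spacer.length, p.site2.length) for p in pairs]
    assert keys == sorted(keys)
    assert [p.index for p in pairs] == list(range(1, len(pairs) + 1))


def test_search_config_validation():
    with pytest.raises(ValueError):
        SearchConfig(site_len_range=(0, 5))
    with pytest.raises(ValueError):
        SearchConfig(spacer_len_range=(10, 5))
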