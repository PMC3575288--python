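# Methods

## Model and procedure

A TALEN pair is modeled as two binding sites on opposite strands separated
by a spacer. On the forward strand the arrangement is
`T <site1> <spacer> <site2> A`: the consensus template is applied to the
first arm on the forward strand and to the second arm on the reverse
strand, so the second arm's "preceding T" appears as an A immediately 3'
of site2. Both arms are required to satisfy the *same* template; no
per-arm templates are supported.

The template notation is compiled into two components: a boolean
preceding-T requirement and an ordered list of allowed-base sets applied
to the first site positions. The grammar is `[T] s (set|base)* .* [T] e`.
A literal `T` directly before `e` (as in the classical
`Ts[ACG][CGT].*Te`) is interpreted as the mirrored preceding-T marker of
the reverse-strand arm, not as a constraint on the last site base: the
classical consensus constrains only the 5' T and the first two site
positions, and a trailing-base constraint would have no biological
counterpart in the repeat array. Arbitrary trailing constraints after `.*`
are therefore a parse error rather than silently accepted.

Enumeration iterates first-arm start positions (stepped by the increment
rule below) and all (site1 length, spacer length, site2 length) triples in
range, emitting pairs ordered by that tuple and numbered from 1. This
ordering is a deliberate choice to make "Site N" labels reproducible
across runs. Sites containing the placeholder N are rejected outright;
spacers may contain N but then yield no enzyme hits.

## Parameters

| parameter | default | meaning |
|---|---|---|
| site length range | 15–17 bp | TAL repeat counts that assemble well |
| spacer length range | 15–16 bp | FokI dimerization distance |
| template | `Ts.*e` | only the 5' T is a robust constraint |
| short flank | 25 bp | extends the scan window past region ends; reported positions count from region start − short flank. Chosen to exceed the longest default site so edge sites are findable; no canonical value exists |
| long flank | 150 bp | amplicon half-width for uniqueness screening |
| min second cut | 80 bp | smallest resolvable distance between two cuts on an RFLP gel |
| buffer score range | 0–9 | rescaled raw activity; 0 = no activity, raw maximum → 9, round half up |
| scan increment | 1 / 10 / 20 | exhaustive to 999 bp; ≥1000 bp steps 10; ≥5000 bp steps 20 |
| recipe target mass | 75 ng/module | pragmatic equimolar default; configurable |

Boundary semantics of the increment rule: "longer than 1000" and
"exhaustive up to 999" conflict at exactly 1000 bp; the thresholds are
implemented as ≥1000 → 10 and ≥5000 → 20 so the 999 bp exhaustiveness
guarantee is preserved. The increment applies to the *core* (exon/intron)
length, not the flanked length. The first arm must start within the core
± short flank; the long flank is searched only for enzyme uniqueness,
never for binding sites.

Site lengths and RVD counts exclude the preceding T (the notation places
it before the `s` marker). A 15-RVD arm therefore binds a 15 bp site with
an additional 5' T requirement.

## Coordinates

Internally everything is 0-based half-open. Reported TAL spans use the
`first-last(length)` notation, 1-based, relative to the region start minus
the short flank; reported enzyme positions are 1-based from the start of
the extracted fragment including the long flank. These two origins differ
by design — they mirror how the amplicon (primer-design) frame and the
subsequence (site-selection) frame are used at the bench.

## RFLP screening

A "cut position" is the first base of the recognition-site match;
within-site cut offsets (the `^`/`(n/m)` annotations in REBASE records)
are parsed and retained but not modeled. A recognition site must lie
entirely inside the spacer to qualify; matches straddling a binding-site
boundary do not count, since the indel spectrum is centered on the spacer.
Uniqueness is judged over the pair plus both long flanks, clipped to the
fragment. Degenerate matching covers the full IUPAC alphabet on both
strands, counts overlapping occurrences, and collapses forward/reverse
hits of palindromic sites into a single + hit. When several spacer matches
exist, the leftmost is the primary; the second-cut offset is signed,
measured first base to first base. Vendor filtering narrows both the
enzyme list and each enzyme's stored supplier codes, so successive filters
compose like a set intersection.

## Synthetic data

The planted-fragment generator emulates a test sequence designed to carry
a single TALEN site: a `T site1 spacer site2 A` construct (default: two
G/C-only 15-mers around a 16 bp spacer holding one NsiI ATGCAT site)
inserted into a seeded background, plus optional concrete decoy sites
outside the spacer. Uniqueness is verified by an internal brute-force scan
**at the planted geometry** — site and spacer lengths pinned to the
planted values — and the generator redraws the background (bounded
attempts) until exactly the planted pair is found. Two facts force this
design: (a) under the full default ranges a 15/16/15 planting always
admits alternative splits of the same span (e.g. 16/15/15), so "exactly
one pair" is unattainable by any sequence; (b) with A/T in the background,
`T…A` anchors at the right distance occur at roughly 1 in 16 positions, so
the default background is G/C-only (`gc_fraction = 1.0`) and plantings in
A/T-rich backgrounds fail fast with a clear error. Consequently the
generator exercises coordinate bookkeeping, template logic and enzyme
classification exactly, but its fragments are not composition-realistic
DNA; passing tests demonstrate algorithmic correctness, not performance on
genomic base composition. The GenBank generator covers the feature
combinations (mRNA/CDS/misc RNA/exon counts, alias labels) that drive
feature prioritization.

## Degenerate inputs and numerical choices

Empty feature lists fall back to whole-sequence mode with a warning;
multiple matching features use the first with a warning unless an index or
transcript id is given. Placeholder N never matches any template position
or recognition site. Buffer rescaling rounds half up (the published rule
fixes only the range). Recipe volumes round to 0.1 µL and floor at 0.1 µL
with a warning. Records are read whole; very large records are not
streamed.

## Scope and limitations

Network retrieval is reduced to deterministic EFetch URL construction
(never executed); GenBank flat files stand in for online records. The
packaged enzyme set is a ~40-enzyme miniature REBASE-dialect snapshot with
illustrative supplier codes and buffer activities; any full REBASE
Bairoch-style file can be substituted via `--rebase`. No off-target
scoring, RVD-efficiency weighting, methylation sensitivity, star activity,
primer design or digestion-gel prediction is attempted. The Golden Gate
recipe module reproduces the pick-list structure (slot-cycled array
modules plus a last-half-repeat plasmid, concentration-scaled volumes) of
the standard kit layout; exact per-well volumes of any particular lab
spreadsheet are not claimed. Test problem sizes (fragments ≤ 999 bp, 100
plantings, 1000-draw matching checks) were chosen so the whole suite runs
in a few seconds while still crossing every boundary in the increment and
distance rules.
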