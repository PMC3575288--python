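# talenforge

Offline design of TALEN pairs for genome editing, with built-in screening
for restriction-enzyme sites that make nuclease activity measurable by
RFLP, and Golden Gate assembly recipes for building the constructs.

## Who this is for

TAL effectors bind DNA through tandem ~34-aa repeats, one repeat per base;
the repeat-variable di-residue (RVD) sets the base preference (NI=A, HD=C,
NN=G, NG=T). Fused to a FokI nuclease domain and deployed as a pair, they
cut in the *spacer* between the two binding sites; error-prone NHEJ repair
then introduces small indels. A molecular biologist planning such an
experiment needs (1) candidate binding-site pairs in their exon or intron
of interest, (2) a restriction enzyme whose recognition site sits in the
spacer and nowhere else in the PCR amplicon — loss of that site after
editing is the RFLP readout — and (3) the plasmid pick list to assemble
each TALEN arm. This package does all three, fully offline, from FASTA or
GenBank input.

## The algorithm

Candidate sites are found against a consensus **template**. In the
template notation, `s`/`e` mark the binding site boundaries, a `T` before
`s` requires a thymine immediately 5' of the site, `[ACG]` is an
allowed-base set at the next site position, and `.*` is an unconstrained
interior. The default is `Ts.*e` (only the 5' T is a robust constraint);
the classical, stricter form is `Ts[ACG][CGT].*Te`. For a pair on the
forward strand the layout is

```
5'-- T <site1> <spacer> <site2> A --3'
```

with the template applied to site1 on the forward strand and to site2 on
the reverse strand (hence the trailing A, a T on the bottom strand). The
scanner iterates every first-arm start and every length triple
(site 15–17 bp, spacer 15–16 bp by default) and is exhaustive for regions
up to 999 bp; longer regions are thinned (start increment 10 from 1000 bp,
20 from 5000 bp) to keep output usable.

Each arm is encoded as RVDs by the single cipher above. For RFLP
screening, every commercially available enzyme in a REBASE-format database
is matched degenerately (full IUPAC alphabet, both strands, palindromes
collapsed) against the fragment: an enzyme qualifies if its site lies
entirely within the spacer and is either unique in the amplicon window
(pair ± 150 bp by default) or has its nearest second cut at least 80 bp
away, in which case the signed offset is reported. Enzymes are annotated
with prototype names and PCR-buffer compatibility scores rescaled to
[0, 9] (0 = no activity).

## Worked example

`python examples/design_from_fasta.py` writes a 300 bp synthetic fragment
carrying one planted TALEN site to FASTA, runs the pipeline and prints:

```
frag5	A1	Site 1
TAL1	87-101(15)	CCGGCCGGCGCGCGC
RVD1	HD	HD	NN	NN	HD	HD	NN	NN	HD	NN	HD	NN	HD	NN	HD
Spacer	102-117(16)	CGCGGATGCATCCGCG
TAL2	118-132(15)	GCGCGCGGCCGGCCG
TAL2 (reverse complement)	118-132(15)	CGGCCGGCCGCGCGC
RVD2	HD	NN	NN	HD	HD	NN	NN	HD	HD	NN	HD	NN	HD	NN	HD
Enzymes:
	NsiI	AvaIII	7	232	+	
```

Reading it: region `A1` means the whole sequence was used (E#/I# would be
an exon/intron). `87-101(15)` is the first/last index and length of the
TAL1 site, 1-based relative to the region start minus the 25 bp short
flank. RVDs are tab-delimited for direct transfer to an assembly
spreadsheet; RVD2 belongs to the reverse-complement strand that the second
TAL protein binds. The enzyme line says NsiI (prototype AvaIII), buffer
score 7 of 9 in standard PCR buffer, recognition site starting at fragment
position 232 on the + strand — and the empty final column means it cuts
the amplicon exactly once, so it is usable for RFLP. The other examples
cover exon-targeted design from GenBank (`genbank_exon_design.py`), decoy
second-cut handling (`rflp_screen.py`) and recipes
(`golden_gate_recipe.py`).

The same pipeline is available as a thin CLI:

```bash
talenforge design --fasta fragment.fasta --out csv
talenforge fixtures --out bundle/ --seed 1
talenforge recipe --rvds "NG,HD,NI,NN,..."
```

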