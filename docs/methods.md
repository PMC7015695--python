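# Methods

This note documents the models, parameters, and design choices behind
editquant: what the synthetic data emulate, how the two estimators are
defined, and where the open design decisions were resolved.

## The measurement problem

After co-delivery of a nuclease vector (SaCas9 + sgRNA) and a donor vector
(promoter–transgene–polyA cassette between ~0.9-kb homology arms), a cut
site in the target locus can resolve as: unedited (parental), an NHEJ indel,
HDR-mediated cassette knock-in, or NHEJ capture of a vector fragment
(promoter, polyA, transgene, ITR, or nuclease-vector sequence). Two assays
measure this: amplicon deep sequencing across the cut (indel frequency), and
ligation-mediated UMI PCR (LMU-PCR) for unique-molecule counting and HDR
classification — the long homology arms make simpler junction PCRs
uninterpretable, which is why the molecule-counting assay exists.

## Synthetic sequence universe

All sequences are generated, never taken from a genome; coordinates are
0-based half-open, restriction cuts are between-base offsets.

**Target locus** (`build_synthetic_locus`, default 2,000 bp): 100-bp flanks
around two abutting 900-bp homology arms; the cut sits between them. A
protospacer (21 nt) + PAM (`TTGAAT`, NNGRRT-compatible) spans the cut; the
nuclease is modeled as a blunt cutter 3 bp 5′ of the PAM (`cut_offset`
parameter — the literature's "predicted cleavage site" without a stated
offset). One recognition site per enzyme is planted in each arm at a
configured distance from the cut (defaults HaeIII 870 bp, TaqI 850 bp) and
all other in-arm occurrences are removed by seeded point-mutation masking,
so digestion geometry is exact by construction. Base composition is uniform.

**Donor vector** (~3.6 kb): ITR(145) – U6-sgRNA(250) – HA_L(900) –
TBG promoter(400) – transgene(650) – polyA(200) – HA_R(900) – ITR(145).
Arms are copied verbatim from the locus; the untargeted control simply lacks
the protospacer inside the U6-sgRNA cassette. One cut site per enzyme is
planted inside the cassette (defaults HaeIII at 830, TaqI at 910 from the
cassette start), other cassette occurrences are masked, and the knock-in
junctions are made *alignment-sharp*: no recognition site spans an
arm|cassette boundary, and the first/last cassette base differs from the
parental base that would continue across the cut (otherwise a junction
read's locus alignment would wobble into the cassette and the junction
coordinate would be ambiguous).

**Assay geometry.** The GSP3 nested primer occupies [cut−120, cut−100) in
the left arm and is used for both digestion assays (the original protocol
uses side-specific primers; one side carries all the information at desk
scale and the 60/55-bp aligned-length filters are both satisfied). Ligation
fragments (primer 5′ end → first downstream cut) are then: parental 990 bp
(HaeIII) / 970 bp (TaqI); knock-in 950 / 1,030 bp — near 1 kb and
deliberately similar in size between parental and targeted alleles, the
design rationale of the restriction-anchored scheme. True ~1.2-kb fragments
would demand arm sites beyond the 900-bp arms; the geometry constraint wins
over the exact published amplicon sizes, which are properties of the real
locus sequence. A consequence faithful to the real assay: 250-bp read pairs
from ~1-kb fragments cannot overlap-merge, so the unique-molecule consensus
falls back to the GSP3-anchored mate, which carries the junction. With the
primer 120 bp from the cut, a junction read aligns 120 bp of arm and clips
130 bp of cassette — inside the ±150-bp junction references.

## Simulator

`simulate_alleles` draws category counts multinomially from an `AlleleMix`.
Indels are centered at the cut, sizes categorical over ±1..20 (deletions
remove genomic bases, insertions add random bases). Vector-fragment alleles
insert a 10–200-bp sub-interval of a donor/nuclease feature at the cut in
either orientation, weighted ITR 0.40 / TBG 0.15 / transgene 0.15 / polyA
0.15 / SaCas9 0.10 / other 0.05 (ITR-heavy, reflecting the dominance of ITR
capture at nuclease breaks). Promoter fragments starting within 5 bp of the
cassette 5′ end are resampled: such a molecule is *molecularly identical* to
an HDR left junction, so truth labels would be unidentifiable — a genuine
limit of junction-based HDR calling, made explicit here.

Library prep is collapsed to what the analysis can see: per-molecule PCR
duplication is one draw (default geometric, mean 5); UMIs are 8-nt uniform
random (errors applied to UMI bases at the same substitution rate);
qualities are flat Phred encodings of the configured substitution rate;
R2 of the LMU library reads `[UMI][12-nt adapter][fragment, reverse]`.
`unique_umis=True` draws UMIs from a single-parity-check code over GF(4)
(pairwise Hamming ≥ 2), the regime in which UMI deduplication is provably
unambiguous — used to isolate PCR-bias immunity from UMI-space effects.
With *random* UMIs at realistic depth (5,000 molecules in a 65,536 space),
~1-in-14 pairs of molecules sit at Hamming distance ≤ 1 of another and
directional collapse legitimately merges a few tens of percent of them;
the loss is class-independent (the absorbed molecule is the lower-count
one), so ratio estimates stay unbiased while molecule counts shrink —
visible as `total_after_filtering` < n in the worked example.

What the simulator does **not** model: size selection, chimeric PCR,
quality-score variation, large deletions extending beyond the arms, ITR
hairpin PCR suppression, side-specific primers. Passing tests therefore
demonstrate correctness of the quantification logic under the stated noise
model, not performance on any particular real library.

## Alignment core

Exact Smith-Waterman/Gotoh local alignment (numba-compiled), match +1,
mismatch −4, gap open 6, gap extend 1 (a k-gap costs 6 + k), the common
short-read scoring regime. Tie-breaking is deterministic: diagonal over
deletion over insertion, smallest end coordinates. Mapping quality is a
uniqueness proxy: `min(60, max(0, best − score_on_shuffled_decoy))`; random
reads score similarly on reference and decoy (proxy ≈ 0 < 20), genuine
reads clear 60. Pipelines align against anchored windows (the amplicon; the
GSP3 window for LMU molecules) — exactness within the window is preserved,
and the primer-prefix filter independently enforces the anchoring
assumption. Identical reads/consensuses share cached alignments.

## Estimators and their edge cases

**Indel frequency.** Window endpoints inclusive (±20 → 41 positions). A
read counts as indel-containing iff a D op deletes a window base or an I op
anchors inside the window; substitutions never count; unmerged pairs are
excluded from numerator and denominator; an empty denominator raises,
never returns NaN. HDR reads (cassette soft-clip, no window indel) stay in
the denominator — the assay sees them as mapped, indel-free reads.

**LMU classification.** The unaligned portion is the maximal terminal soft
clip; internal insertions ≥ 10 bp are routed to classification as well
(both are evidence of non-locus sequence at the junction). A panel hit
qualifies at ≥ 90% identity when it is anchored at the clip 5′ end (query
start ≤ 2) and aligns ≥ 10 clip bases, or covers ≥ 80% of the clip. The
pure-coverage rule alone would leave genuine captures unclassified whenever
a short fragment is followed by resumed locus sequence in the clip; the
prefix-anchored rule reflects the data-generating process (the junction
always starts the clip). Hits on the junction references must additionally
be junction-anchored — start (left junction) or truly cross (right
junction) the arm|cassette boundary within a ±3-bp wobble tolerance —
which is what separates an HDR junction from an NHEJ-captured fragment of
the same cassette element; score ties resolve HDR > transgene > promoter >
polyA > ITR > SaCas9 > other. Both orientations are tried by
reverse-complementing the *reference*, so clip coordinates (and the prefix
anchor) stay meaningful. Random inserted bases (insertion indels ≥ 10 bp)
match no panel element and come out `unclassified`; they remain in the
HDR denominator ("total after filtering"), as do all non-HDR categories.
Filter thresholds (mapq 20, aligned ≥ 60/55, ≥/"more than" read as ≥) and
the 10-bp arm-prefix length are configuration, not claims.

## Problem sizes and defaults used in the tests

Zero-noise exactness and the sweeps run 5,000 molecules per sample; the
recovery sweep covers HDR ∈ {0, 0.02, 0.06, 0.10} (LMU pipeline, enzymes
alternating by seed) and indel ∈ {0.05, 0.28, 0.40} (amplicon pipeline),
20 seeds each, at 0.5% substitution error, scoring each run against the
99% binomial CI of its realized truth fraction. The amplicon sweep uses one
read pair per molecule — amplicon PCR duplicates are i.i.d. copies that add
no information to a read-level statistic, while duplicate structure *is*
exercised where it matters, in the UMI assay (geometric mean 5 by default,
mean 20 in the PCR-bias checks). Exactness checks use `unique_umis`;
noise-regime checks use realistic random UMIs.

## Known limitations

- Forward-strand-only restriction scanning (both default enzymes are
  palindromic); non-palindromic enzymes would need a reverse scan.
- One GSP3 primer side for both assays; no side-specific ITR-representation
  differences between enzymes can emerge.
- The mapping-quality proxy is not BWA's MAPQ model; only its use as a ≥ 20
  uniqueness gate is contractual.
- No reconstruction of full insertion structures: classification stops at
  the best junction-proximal element, as the read length dictates.
- Cohort reporting stops at mean ± SEM; comparative statistics are left to
  standard tools.
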