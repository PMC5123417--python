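# Methods

## The model

`promprof` computes positional profiles over sets of fixed-length DNA
sequences aligned at the transcription start site (TSS). The coordinate
system is the standard core-promoter one: the TSS base is +1, the base
immediately upstream is −1, and position 0 does not exist. The default
geometry is 60 nt spanning −50…+10 (TSS at 0-based index 50); both length
and TSS offset are configurable.

Two strands are distinguished. The *upper* strand is the input sequence as
given — the strand complementary to the template, with its 5′→3′ vector
running toward the TSS from upstream. The *lower* (template) strand is
always derived by reverse complementation, never read from input.

### Window labelling

A length-k window starting at 0-based index j covers j…j+k−1 and is
labelled with the position of its (k/2 + 1)-th base — the base immediately
3′ of the central phosphodiester bond. On the default geometry this yields
59 dinucleotide labels −49…+10, 57 tetranucleotide labels −48…+9 and
55 hexanucleotide labels −47…+8, and the bond-spanning windows (−1,+1),
(−2,−1,+1,+2), (−3,−2,−1,+1,+2,+3) are all labelled +1. Odd k has no
central bond and is rejected by `assign_window_labels`; composition and
motif profiles extend the same offset rule (j + k//2) to k = 1 (the base
itself) and odd k (the middle base).

An exact consequence of this rule: the central dinucleotide of the
tetranucleotide window labelled p is itself the dinucleotide window
labelled p. The S-index identity below is therefore exact, not
approximate.

### Property profiles

Given a complete k-mer → value table, the profile value at a window
position is the mean table value over all sequences whose window is free
of N; the count of contributing sequences is reported as `n_eff` per
position. A position where every window contains N is reported as missing
("NA" in TSV), never as 0. Lower-strand profiles look windows up through
the reverse complement and are reported at the same position label as the
upper-strand window (the one-bond registration offset between complementary
cleavage sites is deliberately ignored for display; see Limitations).

Tables carry `strand_semantics`:

* `duplex_step` — base-pair-step parameters (stacking energy, Roll, Slide,
  stiffnesses, entropy, melting temperature): constrained to
  value(w) = value(revcomp(w)), 10 unique values among 16 dinucleotide
  steps. Upper and lower profiles coincide and the strand difference is
  identically zero.
* `per_strand` — single-strand indexes (ultrasonic cleavage R/T/S, DNase I
  hexamer indexes, mobility to bend): a word and its reverse complement
  may differ.

The cleavage context index is S = T − R(centre): for tetranucleotide
n1n2n3n4, S subtracts the dinucleotide index of the central step n2n3.
Negative S means the flanks damp cleavage at the central bond. S is
shift-invariant (adding a constant to both T and R leaves it unchanged),
and profile(S) = profile(T) − profile(R) exactly on shared labels.

### Composition statistics

* k-mer frequency profiles divide the per-window word counts by the number
  of contributing (N-free) sequences; columns sum to 1 (or 100 in percent
  mode). Collapsed alphabets map bases before counting: purine/pyrimidine
  (R = A,G; Y = C,T) or weak/strong (W = A,T; S = G,C), giving 2^k classes.
* The dinucleotide-distribution spread at a position is the standard
  deviation of the 16 observed frequencies around their mean 1/16. The
  population convention (divide by 16) is the default because only relative
  values along the profile matter; `ddof=1` switches to the sample
  convention (a constant factor √(16/15)). A single dominant dinucleotide
  gives the maximum √15/16 ≈ 0.2421; a flat distribution gives 0.
* Motif-occurrence profiles report, per window, the fraction of sequences
  matching an IUPAC pattern at that window (overlaps allowed; degenerate
  classes per the IUPAC code; motif N matches any base including an
  unknown one, determinate letters never match N).

### Subset analysis

`split_by_motif` partitions a set into sequences with ≥1 upper-strand match
of a motif anywhere and the rest — the canonical literal-TATA split into
"TATA-containing" and "TATA-less" subsets. This is deliberately the literal
word split, not a TATAWAAR-consensus classification. Percentages are
rounded half-up to 2 decimals. A `both_strands` option also accepts matches
on the reverse complement (off by default; the input sets are
strand-oriented). The whole-set profile equals the count-weighted mean of
the subset profiles at every position, which is tested as an identity.

## Packaged tables

The experimentally measured ultrasonic cleavage tables (16 dinucleotide R
values, 256 tetranucleotide T values) and the DNase I hexamer table are
journal supplementary material not redistributed here. The package ships
**synthetic stand-ins**, generated in code:

* R: additive model base5(n1) + context3(n2), anchored exactly to the two
  published values R(CA) = 1.130 and R(TG) = 0.900, with cytosine-led steps
  cleaving fastest and weak (A/T) steps slowest — the qualitative direction
  of the measurements (pyrimidine sugar repuckering is the fastest backbone
  motion; W-rich TATA regions show depressed cleavage).
* T: left(n1) + R(n2n3) + right(n4), anchored to T(ACGA) = 1.537 and
  T(TCGT) = 1.263.
* DNase I hexamer: 1 + 0.3·(#S − #W)/6 + 0.1·(#R − #Y)/6 — a minor-groove
  proxy (A-tract-like words narrow the groove and cleave least) with a
  purine term breaking reverse-complement symmetry.

Outside the four anchors these values carry no experimental meaning;
profiles built from them demonstrate the machinery and the planted-signal
recovery, not biology. Real tables drop in as generic two-column TSV
(`kmer<TAB>value`) or DiProDB-export rows (header of dinucleotide column
names, one row per property, selectable by name or ID; rows carrying only
the 10 canonical steps are completed by reverse complementation).

## The synthetic generator

`generate_promoter_set` draws n i.i.d. sequences from a global or
per-position background base distribution, then plants IUPAC motifs — each
with its own insertion probability, degenerate letters resolved uniformly
over their class. All randomness comes from one explicitly seeded stream;
background draws precede motif draws so the background part of the output
is stable when the motif list changes. Presets:

* `uniform` — flat 25% background, no motifs.
* `mammal_like` — GC-rich background (A/T 0.20, C/G 0.30) with a balanced
  W/S patch at −30…−26; TATAWAAR at −31 with probability 0.15 (the classic
  consensus is found in roughly 10–20% of metazoan core promoters); YR
  initiator at (−1,+1) with probability 0.75.
* `at_rich_like` — globally AT-rich (A/T 0.325, C/G 0.175); TATAWAAR at
  −31 with probability 0.29 (about 29% of A. thaliana promoters carry a
  TATA motif near −32); the same YR initiator.

The generator emulates background composition and fixed-position motif
insertion only. It does **not** emulate dinucleotide correlation structure,
species-fitted backgrounds, CpG islands, or placement jitter of the
TATA-box across −34…−24. Tests that pass on generated sets validate the
profiling machinery (labelling, strand handling, exact identities,
recovery of planted signals at the planted position); they say nothing
about profile shapes in real promoter sets.

## Numerical choices

* Profiles are exact means in double precision; the vectorized path is
  tested against a naive per-sequence double loop to 1e−12.
* Percentages: decimal half-up rounding to 2 places (Python's bankers'
  rounding would disagree on ties).
* Validation tolerances: background columns and frequency-column sums to
  1e−9; duplex symmetry of loaded tables to 1e−9 absolute.
* Missing data: N-containing windows are excluded from numerator and
  n_eff; all-N positions propagate as NaN/"NA".
* Determinism: a fixed config + seed reproduces byte-identical FASTA and
  TSV output (fixed float formatting, single RNG stream).

## Problem sizes

Unit and property tests run on sets of 1–500 sequences; statistical checks
(background convergence, chance-occurrence recovery, preset composition)
use 10,000–20,000 sequences of 60 nt, where binomial standard errors are
small enough for 3–5 SD bounds to be discriminating. The planted-signal
recovery in `scripts/acceptance.py` uses 10,000 sequences. The chance
probability of a literal TATA in a uniform 60-mer is computed exactly by
dynamic programming over the motif's prefix automaton, not simulated.

## Known limitations

* Same-label convention for lower-strand and difference profiles: the
  physical cleavage sites on complementary strands at one duplex step are
  offset by one bond; profiles are nevertheless plotted/reported at the
  shared upper-strand label. Differences near sharp features shift by up
  to one position relative to a bond-registered convention.
* Wrong-length input records are dropped (with a logged count), never
  trimmed; there is no genome-coordinate extraction — inputs are
  pre-extracted TSS-aligned windows.
* No smoothing, peak calling, or significance testing of profile extrema;
  extrema are reported as argmin/argmax of the raw mean profile.
* The literal-TATA subset split is sensitive to the motif given; it does
  not classify promoters against consensus categories.
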