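# Methods

This note describes the models and numerical choices behind `satreads`:
what each stage assumes, which parameters matter, what the synthetic data
generator does and does not emulate, and where the design was genuinely
open.

## Array detection from similarity hits

The unit of analysis is a single ultra-long read.  A reference database
supplies one or more consensus sequences per repeat family, all placed in
the family's forward orientation; an aligner (LASTZ in the intended
setting) reports read-vs-reference hits in the "general" 12-column
format.  We do not run the aligner: hits are ingested, converted once to
0-based half-open coordinates on the read's forward strand, and carry a
strand equal to the hit's orientation relative to the forward-oriented
reference.

Hit filtering uses two thresholds: a bit-score floor (default 7000,
inclusive) removing weak matches, and a length cap (default 1.23× the
reference sequence length) removing "bridging" hits that span unrelated
sequence inserted between two genuine matches.  Both are configuration
fields, not constants.

Arrays are the interval union of same-family hits on a read, merged when
overlapping or separated by at most `max_gap` bases.  `max_gap` defaults
to 0 (strict overlap); noisy reads fragment alignments, so the flag
exists for practical use, but the default reproduces the strict
"covered by overlapping hits" definition.  Regions shorter than a
per-class minimum (satellite 300 bp; rDNA and telomere 500 bp, because
those references recur internally) are dropped; the minimum is inclusive,
so a planted array exactly at the threshold is kept.

Orientation of a merged region is the base-weighted majority strand of
its hits, ties broken toward forward, with the supporting fraction stored
as `orientation_purity`.  No rule for mixed-strand regions is imposed
beyond this; recording purity lets a user split or discard impure arrays
rather than having the library guess.

Truncation: an array is flagged truncated on a side when it comes within
`edge_tolerance` bases of that read end (default 100 bp, absorbing ragged
alignment ends on noisy reads; 0 demands exact contact).  A truncated
array's length is a lower bound on the genomic array length and is
labelled as such everywhere downstream.

## Coded reads

A coded read assigns every base exactly one character: array-forming
families get letters (A–Z in reference order), uppercase for forward and
lowercase for reverse arrays; dispersed repeats get digits 1–9 with no
case semantics; `0` marks unannotated bases and `X` annotation conflicts.
Conflicts are resolved by tier: satellites/rDNA/telomeres always override
dispersed repeats; two distinct equal-tier families claiming a base yield
`X` (this applies within the dispersed tier too).  The run-length
representation is checked on construction: runs must sum exactly to the
read length.

## Length distributions

Array lengths are pooled per family and binned into half-open
`[k·w, (k+1)·w)` bins (default w = 5 kb), with everything at or above the
terminal floor (default 120 kb) pooled in the last, open-ended bin.  Each
array contributes weight equal to its length and count 1; complete and
truncated arrays are tallied separately.  The weighted view estimates how
the genome's satellite bp are distributed over array-size classes (a read
set sampling the genome uniformly makes detected bp proportional to
genomic bp); the count view is the companion cross-check and equals the
weighted view with all weights forced to 1.  A per-family histogram of
the lengths of reads carrying the family guards against length-sampling
bias.

## Flank and domain profiles

For each array of a focal family we examine a window (default 10 kb) on
each side, expressed in the array's own frame: positions −1…−window are
upstream, 1…window downstream, and for a reverse-oriented array the
genomic right flank is upstream and flank codes are case-swapped.  All
profiles are therefore "as seen by a forward-oriented array", and
reverse-complementing the entire dataset leaves them exactly unchanged
(a property test enforces this).

Proportions are per position, with the denominator at position p equal to
the number of focal arrays whose read extends at least |p| bases beyond
the relevant array end.  Many flanks are cut short by read ends —
especially for families whose arrays span whole reads — and a total-array
denominator would silently dilute those positions; the available-flank
denominator was chosen for that reason, and the per-position `n_available`
is part of every output table.  A presence/absence summary can be derived
from the full table; per-position is the primary output.  Families never
exceeding a report threshold (default 0.05) at any position are omitted
from the compact report but retained in the full table.

Protein-domain hits (GAG, PROT, RT, RH, aRH, INT) are filtered on five
quality cutoffs (minimum identity 0.3, similarity 0.4, alignment-length
proportion 0.7; maximum 10 interruptions, length proportion 1.2) and
profiled with the same geometry and denominators, split by relative
orientation: "same" when the domain strand matches the array orientation,
"opposite" otherwise.  Arrays that are genuinely embedded in
LTR-retrotransposons show the six domains upstream, same-oriented, in
element order with integrase innermost; random adjacency produces no such
fixed layout.

## Periodicity

A tandem array is turned into a numeric signal with A,C,G,T → 1,2,3,4;
ambiguity codes get 2.5 (the mean, contributing no bias of their own).
The mean is subtracted before the FFT — the zero-frequency term carries
no periodicity information and would dominate averaged spectra — and
amplitude is reported against period T = L/f for f = 1…L/2.  Only arrays
of at least 30 kb (configurable) are analysed, extracted from the read
and reverse-complemented to family-forward orientation.

Averaging across arrays requires a common period axis (arrays differ in
L, hence in native grids): each spectrum is linearly interpolated onto a
2–2000 bp grid at 1-bp steps and amplitudes are averaged unweighted, with
the number of arrays recorded.  Amplitude (not power) averaging is the
default; it is a config knob in the averaging function.

Peak calling accepts local maxima above `prominence_factor` × median
amplitude (default 5).  The 1/2/3/4 encoding is far from sinusoidal, so a
true period p echoes at p/m; a peak is flagged as a harmonic when an
accepted peak of **at least equal amplitude** exists near m × its period
(relative tolerance 0.02).  The amplitude condition matters: a genuine
monomer period underneath a weaker higher-order-repeat peak at twice its
length must not be suppressed.  Peak positions are refined by an
amplitude-weighted centroid over the neighbouring bins, since indel-rich
noise spreads a periodicity across adjacent bins.

The *fundamental* unit length (the "what is the monomer?" statistic) is
not the tallest line: for a random-sequence monomer the Fourier
coefficients of the monomer are i.i.d., so the tallest comb line is
usually one of the harmonics.  The fundamental is instead scored as in
harmonic-sum pitch detection: each candidate peak is credited with the
summed amplitude of all accepted peaks on its harmonic series, and the
largest total wins.  The true unit's series contains every harmonic, so
it dominates any of its sub-periods deterministically; for a two-variant
HOR array the fundamental is, correctly, the full HOR unit, while the
monomer remains the strongest genuine peak in the call list.

Autocorrelation uses four 0/1 indicator tracks (one per base), the
lag-adjusted (unbiased-denominator) normalization — chosen so a perfect
tandem of unit p scores exactly 1 at lag p — clipped to [−1, 1], over
lags 2–2000, and combines the four tracks by unweighted mean.  The
combination rule is a parameter in spirit: the tracks are also returned
individually.

## Synthetic data

The generator's defaults mirror the data regime the analysis targets:
reads uniform over 30–348 kb; per-family array lengths drawn from a
mixture of a short lognormal mode (median 1.5 kb, σ = 0.6, clipped to
0.4–5 kb) and an expanded uniform tail (30–120 kb) with configurable
weight; monomers of any length from the 32–660 bp range with chosen GC;
independent per-base substitutions plus geometric-length indels
(mean 2 bp); optional k-variant HOR cycles (variants diverged at 8 % of
positions by default); and an "ogre_embedded" context that wraps the
array in an element — 1.5-kb direct repeats at both ends and the ordered
GAG(1200)–PROT(450)–RT(2100)–RH(540)–aRH(540)–INT(900) cassette upstream,
200-bp spacers between parts.  About 30 % of reads begin inside a
feature, and features overrunning the read end are cut, producing
truncated truth.  Noise is applied segment-wise before assembly, so truth
coordinates are exact on the final read; identical seeds give
byte-identical output.

Hit tables are emitted from truth in the exact ingestion dialect:
each array is tiled by overlapping windows of the reference length
(stride = half a window, boundaries exact), scores scale as ~90 per
matched base as with LASTZ's large default match scores, element bodies
emit dispersed-family hits, and planted domains emit GFF3 rows passing
the default cutoffs.

What the generator does **not** emulate: nanopore error phasing and
homopolymer-specific errors, quality scores, chimeric reads, alignment
boundary jitter, and reference databases diverged from the planted
monomers.  Passing tests therefore demonstrate the correctness of the
interval logic, coding, profiling geometry and spectral analysis — not
the sensitivity of any particular aligner parameterization on real noisy
reads.

## Problem sizes in the shipped tests and examples

The test suite runs on simulations of 5–10 reads of 30–150 kb (a few
megabases total), 1000 randomized instances for the merging oracle, and
100 seeded replicates of 40-kb arrays for monomer recovery; the whole
suite completes in well under a minute on one CPU.  These sizes were
chosen as the smallest at which the verified properties are
non-trivial — exactness properties (conservation, oracle equivalence,
noise-free recovery) do not depend on scale.

## Known limitations

- Arrays longer than the read are only ever observed truncated; the
  package reports lower bounds and never extrapolates true array lengths.
- Orientation is a whole-region majority call; a genuine inversion inside
  an array lowers purity but does not split the array.
- The harmonic-sum fundamental assumes the spectrum contains at least the
  first few harmonics of the true unit; for units approaching half the
  analysis band it degrades to the tallest-peak rule.
- Flank profiles describe co-occurrence on reads, not statistical
  enrichment; no significance testing is performed.
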