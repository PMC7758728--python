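# Methods

This note documents the models, estimators and design choices behind
`quantmir`, and what the synthetic-data tests do and do not demonstrate.

## Read model and parsing

Libraries are built from 3'-ligation products of the form

```
NNNN - insert(18-30 nt) - NNNNNN - XXXXX - 3' adapter
```

where `XXXXX` is a 5-nt inline sample barcode and the two N-runs together
form a 10-nt unique molecular identifier (UMI), concatenated in read order.
Parsing locates the 3' adapter — leftmost full-length occurrence allowing
one mismatch per 10 adapter nt, else an exact adapter *prefix* of at least
10 nt at the read end (the common case when the adapter runs off the read)
— and splits the remaining payload positionally. Inserts outside 18–30 nt
are rejected (`bad_length`), reads without a locatable adapter as
`no_adapter`. Barcode routing is exact-match only: 5-nt barcodes leave no
safe margin for mismatch rescue, so the barcode map is required to be
pairwise Hamming distance ≥ 2 and anything else lands in `undetermined`.
Count conservation (total = assigned + undetermined + rejected) is asserted
structurally and tested on every simulated library.

With the default 50-nt read length, payloads up to 39 nt leave ≥ 10 adapter
nt visible; inserts near the 30-nt ceiling would leave less and be dropped
as `no_adapter`. The packaged synthetic references use 21–23-nt smalls
(miRNA-realistic), where this never occurs; for longer species, raise
`read_length` or lower `min_overlap`.

## Reference model

Mature miRNAs are located on their hairpins by 1-based inclusive
coordinates (miRBase convention) and validated as exact substrings.
Sequences are stored in DNA letters (reads are DNA-space); FASTA output is
written back as RNA. Arm consistency (5p vs 3p) is checked against the
loop midpoint, taken as the midpoint of the innermost base pair of the
max-pairing fold (sequence midpoint if the hairpin does not fold). Each
hairpin may carry a short downstream genomic context so that templated 3'
extensions can be distinguished from non-templated tailing at the hairpin
boundary.

The spike-in ladder is 8 oligos whose per-embryo concentrations are
geometric from 20 to 10,000 molecules per embryo — a 500-fold range with
step 500^(1/7). The concentrations of the original reagent set are not
public, so the ladder is a configuration parameter with this default; the
500-fold span and 8-oligo count are fixed design facts. Ladder sequences
are composition-balanced shuffled 22-mers screened to sit ≥ 4 mismatches
from every reference sequence (and from each other) at every alignment
offset.

piRNAs (21U-RNAs in the packaged synthetic references) are user-supplied in
real analyses; no particular annotation set is mandated.

## isomiR assignment

Class priority for exact matches is spike-in > piRNA > mature miRNA;
spike-ins are engineered to be unique, so collisions indicate a reference
design problem and surface as `ambiguous` rather than being silently
resolved. Failing an exact hit, the insert is aligned to each hairpin
window around the annotated mature: the 5' end may shift by at most ±2 nt,
the genome-templated body must match with **zero mismatches**, the 3' end
may be trimmed ≤ 4 nt or extended along the template ≤ 4 nt, and up to 3
trailing bases whose first position disagrees with (or lies beyond) the
template are a non-templated tail (`nta`). The zero-mismatch body rule is
this package's decision (recorded in output metadata): the analysis
quantifies discrete end variants, not internal edits, and the simulator's
default error rate is zero. Among admissible decompositions the one with
minimal total deviation (|5' offset| + trim + extension + tail length)
wins, with a deterministic tie-break; two references tied at minimal cost
give `ambiguous`. A brute-force enumerator over all admissible
(offset, trim, extension, tail) tuples serves as the test oracle.

`end_profile` summarizes per-reference heterogeneity: iso-class fractions,
the fraction of NTA tails that are pure U, the insert-length histogram, and
the modal length (ties resolved toward the shorter length — trimming-driven
shifts, e.g. 24→23 nt, are therefore detected conservatively).

## Quantification

UMI collapse counts distinct (reference, insert, UMI) triples; the insert
sequence is part of the key, so end variants sharing a UMI count
separately. Distinct counts are corrected for UMI-space saturation by
inverting the birthday expectation, n = −U·ln(1 − d/U) with U = 4^10; the
correction is negligible below ~10^4 molecules per species and a few
percent at 10^5, where ignoring it would visibly compress the top of the
spike-in ladder.

Calibration uses the median over detected oligos of (known molecules ×
embryos / corrected count), requiring ≥ 3 detected oligos; the median is
robust to single-oligo dropout, and a least-squares-through-origin
alternative sits behind `method="lsq"`. Background correction subtracts
the mean contamination-control molecule estimate per reference on the
molecules-per-embryo scale (whether the original analysis subtracted on
count or molecule scale is not documented; molecule scale is recorded in
output metadata), clipping at zero since molecule counts are non-negative.
piRNA normalization returns per-sample factors
(reference-sample piRNA total / sample piRNA total) and is used as a
cross-check of the spike-in scaling, not as the primary estimator.

Depletion summaries use miRNA references only (spike-ins and piRNAs never
enter content totals), and replicate averaging is the arithmetic mean of
per-replicate totals — the averaging basis is ambiguous in prose
descriptions of such analyses, so it is fixed here and recorded.

## Synthetic-data generator

`simlib` emulates the study conditions: lognormal (σ = 1.5) per-miRNA
abundances rescaled so the miR-35/miR-51 families jointly carry a
configurable share (default 50%) of total content; per-miRNA retention
factors for depletion conditions; Poisson ligation capture with default
efficiency 0.05 (no public figure exists for this protocol's efficiency;
it is configurable and cancels out of calibrated estimates); one UMI per
ligated molecule with a shifted-geometric PCR duplicate count (mean 4 —
overdispersed with a single parameter); mirtron 3'-end events drawn per
molecule as mutually exclusive single-U tailing / 1-nt trimming;
contamination as Poisson(rate × endogenous ligated molecules) drawn from an
alphabet-shuffled decoy pool ≥ 4 mismatches from all references (default
rate 1%, matching the contamination level such controls typically show);
constant `I` quality lines (qualities are unused downstream). Absolute
molecule scale is anchored only loosely by reality (tens of embryos yield
low-nanogram RNA); fixtures use totals of 10^4–10^5 molecules per embryo.

What the generator does **not** model: ligation sequence bias, indels,
instrument error profiles, partial adapter chimeras. Recovery results on
synthetic data therefore demonstrate estimator correctness under the
stated stochastic model, not robustness to those real-data artifacts.

Determinism: one `numpy` generator seeded per library; identical seeds give
byte-identical FASTQ.

## Structure prediction and mirtron design

The internal folding backend is a Nussinov-style maximum base-pairing
dynamic program (Watson-Crick + G·U wobble, minimum loop 3, traceback ties
resolved toward 5'-most pairing, hence deterministic). It is a counting
model, not a thermodynamic one; any predictor returning the same
`Structure` contract can be plugged in where folds are taken. Structure
similarity is measured as base-pair distance (symmetric difference of pair
sets).

Design procedure: the last 6 hairpin nt are replaced by the splice-acceptor
consensus (default `UUUCAG` — pyrimidine-rich, canonical AG; the consensus
derived from endogenous mirtrons is an input, not a constant). For each
grafted position paired in the original fold, the 5' partner is proposed
for mutation to the Watson-Crick complement of the new base; proposals are
accepted greedily, each kept only if it does not increase base-pair
distance to the original structure (under a global max-pairing fold a
local swap can occasionally rearrange distant pairs, so unconditional
application would violate the never-worse guarantee). Compensation targets
inside the mature 3p arm are a hard error. Validation flags — intron
starts `GT`, ends `AG`, mature seed (nts 2–8) preserved, base-pair distance
within budget (default 4 pairs; "highly similar" has no canonical number)
— are always reported; a design is accepted only if all hold, and failing
designs are returned flagged, never silently dropped. Branch points are
not scored: essentially any A near the 3' splice site supports lariat
formation in this organism.

Seed mutants swap n (default 3) paired seed positions, transversions
preferred, each with the compensatory partner substitution; candidate
substitution combinations are searched until the mutant's pair count
equals the input design's, and the mutant's seed differs at exactly n
positions. Seed-mutant outputs carry `seed_preserved = False` by
construction — they are control constructs meant to lose target
specificity while keeping hairpin integrity.

## Problem sizes and tolerances in the test suite

Simulation-based checks run at desk scale: libraries of ~10^5 reads for
conservation/inversion properties; 50 wild-type/depleted pairs at 8,000
molecules per embryo × 5 embryos (≈ 25,000 reads per pair) for
percent-remaining recovery, asserted within 3 Monte-Carlo standard errors
of the realized molecule-weighted retention; 200 Poisson replicates for
calibration-factor recovery; 3 pairs with constant piRNA content for the
piRNA-vs-spike-in cross-check at 10% relative agreement; exhaustive
oracles for assignment (≤ 3 references, hundreds of random inserts) and
folding (all sequences ≤ 14 nt against brute-force enumeration). The
acceptance script simulates the spike-in ladder over 400 embryos (~1.4M
reads, rarest oligo ≈ 1,600 expected reads) and recovers the 500-fold
ladder range from raw reads.

## Known limitations

- Multi-mapping inserts are reported `ambiguous`, with no probabilistic
  rescue; genome-scale alignment and novel-miRNA discovery are out of
  scope (assignment is against a curated reference set).
- The zero-mismatch body rule makes assignment sensitive to sequencing
  errors; with nonzero simulated error rates, assignment rates drop
  rather than degrade gracefully.
- The max-pairing fold overestimates pairing relative to thermodynamic
  models; base-pair-distance budgets calibrated on it do not transfer
  numerically to free-energy predictors.
- Calibration assumes spike-ins experience the same capture efficiency as
  endogenous smalls; ligation bias differing by sequence would bias
  absolute (not relative) estimates, as in the real protocol.
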