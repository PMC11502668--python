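# Methods

## Problem and approach

Guide-RNA-directed pseudouridine synthases can be targeted to a chosen uridine
in an mRNA — for example the U of a premature stop codon, whose isomerization
to pseudouridine (Ψ) permits stop-codon readthrough. Quantifying how much of a
target transcript is modified, and how selective the targeting is between a
recruited reporter (mCherry with recruitment tags) and an untagged bystander
reporter (eGFP), requires three independent readouts, all implemented here:

1. **Direct RNA sequencing (DRS) classification.** On nanopore direct RNA
   reads, Ψ perturbs the current signal so that the basecaller tends to call
   the modified uridine as a cytosine (the characteristic U→C mismatch) and,
   with a Ψ-aware basecalling model, emits a per-base modification
   probability stored in the SAM MM/ML tags. A read is called *modified* at a
   target site when it shows the U→C mismatch **or** carries a probability
   tag decoding strictly above a threshold (default 0.95). Site stoichiometry
   is the percentage of modified reads among reads covering the site with a
   base call; the same percentage measured in a non-targeting control sample
   is subtracted per site (clamped at zero) to remove motif-specific
   background error. Selectivity is the ratio of corrected percentages at the
   recruited (mCherry) versus bystander (eGFP) site.
2. **BID-seq deletion scoring.** Bisulfite treatment converts Ψ positions
   into deletions in the sequenced library; the per-position deletion
   fraction (`del_score` in [0, 1]) estimates stoichiometry and
   cross-validates the DRS readout.
3. **Flow-cytometry statistics.** Reporter fluorescence per cell, gated
   against a reporter-only control: efficiency is the double-positive (Q2)
   percentage of live cells normalized by relative transfection rates
   (iRFP⁺ percentages); selectivity is the ratio of median mCherry to median
   eGFP intensity over the non-double-negative population (NOT Q4),
   normalized to the cytoplasmic-enzyme ("NES") reference condition.

Because the real sequencing and cytometry data require a nanopore/Illumina
run and GPU basecalling, all inputs are produced by a first-class simulator
with known ground truth; every quantitative claim of the package is a
recovery statement about that ground truth.

## Probability-tag coding

Tag codes are integers 0–255. Decoding uses the standard base-modification
bin-midpoint convention, `decode(c) = (2c + 1)/512`; encoding is
`encode(p) = min(255, floor(256 p))`, making the round trip exact on all 256
codes and decoding strictly monotone. A commonly printed shorthand for this
coding, P = p·256 − 1, is not invertible at the edges (it would map p = 0 to
−1), so the bin semantics above are used. With a threshold of 0.95 applied
strictly to decoded midpoints, the smallest qualifying code is 243, i.e. a
continuous probability must reach 243/256 ≈ 0.9492 before its encoded tag
clears the threshold; the Beta-tail calibrations below account for this.

## The simulator

`simdata` emits sorted, indexed BAM alignments over two reporter references
("eGFP", "mCherry"), each a parameterized 11-mer motif with the target U at
its center embedded between random 50-nt flanks. Target motifs are
construct-specific, so they are taken as parameters; the defaults are
synthetic UAG-context stand-ins, not real reporter sequence. Coordinates are
0-based
half-open internally, with 1-based display coordinates in reports. All reads
are forward-strand and full-length by default; RNA is written in the DNA
alphabet.

Per read, the generative model is:

* true modification status ~ Bernoulli(`frac_modified`), applied at the
  target site;
* basecall at the target: C with probability `p_mismatch_given_mod` (modified
  reads) or `p_mismatch_given_unmod` (unmodified), else T;
* a modification probability drawn from a status-conditional Beta
  distribution, encoded to a tag code; the MM/ML tag (pseudouridine code
  17802, single strand, `?` skip semantics) is attached only when the
  read's basecall at the target is still T — mirroring a basecaller, which
  can only tag positions it called as U;
* independent background substitutions and single-base deletions at all
  other positions at flat rates (defaults 0.007 and 0.003, chosen so
  simulated runs show a mean base accuracy of roughly 98.4–99%, consistent
  with modern direct-RNA chemistry).

Default emission rates are the per-motif values measured on fully
modified/unmodified synthetic oligos — U→C in 88.3%/3.9% of eGFP-motif reads
and 34.2%/1.3% of mCherry-motif reads — and the default Beta tails are
calibrated one-parameter families (`Beta(a, 1)` for modified, `Beta(1, b)`
for unmodified) whose mass above 243/256 makes the *union* call rate match
the oligo benchmark (96.6%/4.4% eGFP, 91.8%/1.4% mCherry). The simulator is
deterministic and byte-identical per seed: reads are generated in coordinate
order and written directly, avoiding a re-sort step whose @PG header line
would embed run-specific paths.

BID-seq mode replaces the mismatch channel with a single-base deletion at
the target (probability `p_del_given_mod` / `p_del_given_unmod`) and encodes
deletions explicitly in the CIGAR.

Flow events are a four-population log-normal mixture (untransfected,
transfected-low, transfected-high, dead; default fractions 0.40/0.20/0.30/
0.10) over four channels (gfp, mcherry, irfp, viability dye). Transfected
cells express the reporters and the iRFP transfection marker; dead cells
take up the viability dye (median ~5000 units versus ~50 for live cells).

**What the simulator does not model:** signal-level (squiggle) data, basecall
quality-score error profiles, motif-dependent background error beyond the
target emission rates, reverse-strand or spliced alignments, partial/ragged
read starts (spans are configurable but uniform), doublets and scatter-based
cytometry gating, and channel spillover. Passing tests therefore demonstrate
the correctness of the *analysis* given the stated error model, not the
fidelity of that model to any particular flow cell or cytometer.

## Pileup and accuracy

`pileup` counts A/C/G/T/deletion per reference position with pysam's pileup
engine (stepper "samtools"). The base-quality filter (default ≥13) is applied
per base call in this module rather than inside the engine so that deletions
are counted regardless of quality; 'N' calls are excluded from numerator and
denominator; insertions consume no reference position and are ignored. Depth
is capped at `max_depth` (default 10,000 for accuracy metrics, 100,000 for
modification calling), truncating in BAM order for reproducibility. Mean base
accuracy is the depth-weighted mean of per-position match percentages over
covered positions (depth weighting is this package's choice; an unweighted
position mean differs only at uneven coverage). Context profiles report the
full composition at offsets −5…+5 around a target site.

## Classifier details and edge cases

* The threshold comparison is strict (`decoded p > threshold`) on decoded
  midpoints.
* Reads with a deletion at the target, or not covering it, are excluded from
  the stoichiometry denominator: a deletion is the signature of a different
  chemistry (BID-seq), and counting such reads as unmodified would bias
  stoichiometry downward.
* Reads without a probability tag at the site participate through the
  mismatch channel only.
* Zero usable reads is an undefined result (an error), never 0%.
* Control subtraction is per site (eGFP control percentage at the eGFP site,
  mCherry at mCherry); negative differences clamp to 0 and the clamping is
  flagged.
* A fold change against a zero off-target percentage is undefined and raised
  as an error carrying the resolution-limited lower bound
  (`target_pct / (100/n)`); the orchestrator records NaN plus that bound.

## BID-seq scoring

Depth at a position counts every primary alignment spanning it
(deletion-bearing reads included; soft-clipped-away reads and N-gap spans
excluded); deletions are counted once per covered position from CIGAR D
operations. No depth or quality filter is applied by default. Zero-coverage
positions report a missing (NaN) `del_score`, not 0. The implementation is a
per-read CIGAR walk with difference arrays; tests check it against the
independent pysam pileup-column oracle.

## Flow gating numerics

The live gate takes the viability threshold as a quantile (default 0.85) of
the reporter-only control's viability channel — the control is mostly live,
so the quantile sits above the live dye mode and far below the dead mode.
Quadrant thresholds per fluorescence channel are the `quadrant_quantile`
(default 0.999) quantiles of the control's live population, computed with the
*higher* order-statistic method so each threshold is an observed control
intensity: at least a fraction `q` of control live events then sit at or
below it per channel, which guarantees the control's own Q4 containment is
at least `1 − 2(1 − q)` (99.8% at the default) deterministically rather than
only in expectation. Axes follow the convention x = eGFP, y = mCherry, so
Q1 = mCherry⁺ only, Q2 = double-positive, Q3 = eGFP⁺ only, Q4 =
double-negative. The iRFP⁺ threshold is an explicit parameter (default 1000
generator units, between the untransfected background and the transfected
marker mode) because the reporter-only control itself expresses iRFP and
cannot set that gate. Medians use linear interpolation on even counts. The
iRFP normalization of efficiency is multiplicative:
`q2_pct × irfp⁺%(reference) / irfp⁺%(sample)`, which reduces to the raw Q2
percentage for the reference itself.

## Scenario conditions

`oligo_control` simulates a fully modified and a fully unmodified run
(5,000 reads per motif) under the default oligo-calibrated emission model
and reports the component and union percentages plus mean base accuracy.

`oreo_vs_nes` encodes the target effect sizes of the three-condition
comparison as generator ground truth, since true per-site stoichiometries
are not independently known:

* DRS: the organelle condition ("oreo") has mCherry-site stoichiometry 0.60,
  the cytoplasmic reference ("nes") 0.30; each condition's eGFP off-target
  stoichiometry is derived so the expected corrected-percentage fold change
  is 25.1 (oreo) and 2.9 (nes) under the oligo-calibrated per-motif detection
  rates. The control condition is fully unmodified. 100,000 reads per
  reference and condition keep the Monte-Carlo error of the extreme fold
  change (whose off-target denominator is ~2%) near 5%.
* BID-seq: deletion conversion 0.9 given modified, 0 given unmodified, with
  per-site stoichiometries (nes: 0.34/0.10; oreo: 0.314/0.02) encoding
  del_score ratios of 3.4 and 15.7. The two assays carry separate ground
  truths deliberately: with shared stoichiometries and any non-negative
  background, the DRS-implied fractions bound the nes deletion-score ratio
  below 3.0, so a single shared truth cannot reproduce both readouts — the
  assays are modeled as having assay-specific conversion efficiencies.
* Flow: the oreo condition shifts the mCherry log-intensity of transfected
  populations by ln(4) relative to nes; since transfected cells sit above
  the eGFP quadrant threshold with ~99% probability in both conditions, the
  NOT-Q4 population is essentially the same and the normalized selectivity
  fold change recovers 4.0 within Monte-Carlo error at 50,000 events.

Stage seeds are derived from the run seed and a stage label (CRC-folded into
a `SeedSequence`), so adding a stage never shifts another stage's stream.

## Known limitations

* The per-read probability model is independent of the mismatch outcome
  conditional on true status; real basecaller error and modification
  probability are correlated through the same signal.
* Background error is position-independent and uniform across substitution
  targets; real direct-RNA error is strongly sequence-context-dependent.
* The classifier evaluates annotated target sites only; transcriptome-wide
  de novo Ψ discovery is out of scope.
* Quadrant gating assumes compensated, positive intensities in CSV tables;
  FCS parsing, spillover correction, and scatter-based singlet gating are
  not implemented (the simulator carries a singlet flag instead).
* Statistical testing across biological replicates (t-tests on fold changes)
  is out of scope; the package produces the per-sample descriptive
  statistics such tests consume.
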