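# Methods

This note documents the statistical models behind `bindshift`, the
parameter defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions a
maintainer needs to know.

## Binding-distribution model

A `BindingModel` is a probability mass function m(d) over signed
offsets d ∈ [−W, +W] (default W = 250 bp) giving the chance that a
sequenced 5' end lands at offset d from a binding event.  Sonication
ChIP libraries sequence both fragment ends, so single-TF data produce a
two-shouldered shape: forward-strand reads pile up a few tens of bp
upstream, reverse-strand reads the mirror image downstream.  The
default model is symmetric with geometric-decay peaks at ±35 bp
(per-bp ratio 0.95); it is a configurable stand-in used only until the
caller refits an empirical model from the data at hand.

Three conventions follow from one modelling decision — m(d) is the
**two-sided** distribution of raw signed offsets, with read strand
determined by the offset's sign (upstream → forward):

* *Generation*: the synthetic generator draws d ~ m, places the read at
  event + d, and assigns the strand by sign(d).
* *Estimation*: `estimate_binding_model` histograms raw signed offsets
  around re-centred strong events (raw p < 10⁻⁷, fold > 10, at least
  20 events, else the prior model is kept), then explicitly
  symmetrises the histogram (averaging m(d) and m(−d)).  The
  symmetrisation encodes the strand mirror-symmetry assumption of
  sonication ChIP; it recovers symmetric generating models exactly
  (validated at total-variation ≤ 0.05 with 20,000 reads) and projects
  any asymmetric reality onto its symmetric part.  A 5-bp moving
  average smooths the histogram before normalisation, since empirical
  histograms at modest read counts are noisy.
* *Scoring*: peak refinement maximises Σ log m(offset), mirroring
  reverse-strand offsets; under the symmetric models used the mirror
  is a no-op.  Zero-mass offsets contribute log(10⁻⁶) instead of −∞ so
  one stray read cannot veto a position; ties break leftmost for
  determinism.

Read extension uses the offsets where m(d) crosses the uniform density
1/(2W+1): the maximal contiguous run around the mode with mass at or
above uniform.  An everywhere-uniform model degenerates to the full
support.  Intervals are half-open and the reverse-strand interval is
the exact coordinate reflection of the forward one.

## Event caller

Defaults (all exposed in `DetectionConfig`): 50-bp bins every 25 bp;
candidate Poisson threshold 10⁻⁹ (strict inequality — equality at the
threshold is not a candidate); corrected-p cutoff 0.001; local
background windows 5 and 10 kbp; model-refit thresholds p < 10⁻⁷ and
fold > 10; scaling windows 10 kbp; exactly two passes.  The domain
variant uses 500/250 bins, a homogeneous background and cutoff 0.01.

The binomial test uses **raw** integer control counts with success
probability q = σ/(σ+1) rather than rounding scaled counts — the same
null hypothesis without rounding artifacts.  Merged regions carry the
*maximal* (least significant) constituent bin p-value; this is
deliberately conservative, and a `merged_p_rule="min"` switch provides
the anti-conservative alternative.  Benjamini–Hochberg is applied with
m equal to the number of merged candidate regions, not all genomic
bins: the hypothesis family is the candidate set.

Pass order: pass-1 candidates (both channel directions) define the
event-free windows; σ is refit first by through-origin least squares
of signal on control window counts (slope = Σsc/Σc²; fallback to the
total-count ratio with a warning below 10 eligible windows); the
binding model is refit from provisional events under the new σ; pass 2
re-runs detection with both.  σ recovery was validated to within 5%
on 2,000 windows.

Duplicate capping precedes everything: with per-base rate λ =
reads/mappable bases, the cap is the largest stack depth whose Poisson
upper tail still reaches 10⁻⁷, clamped at 1 (the literal rule would
discard all reads in very sparse data).  Duplicates are counted per
(position, strand) because 5' coordinates of opposite-strand reads
refer to different fragment ends; a strand-blind switch exists.  The
mappable-base count is a required input — synthetic runs use genome
length × mappable fraction.

## Exclusivity and site-set comparison

"Within 200 bp" is closed point-to-point distance (|Δ| ≤ 200); for
domains, distance to the interval.  The three-criterion exclusivity
rule reuses the full two-pass caller unchanged for the
condition-vs-condition call (criterion iii), including its scaling
regression.  Sites passing (i) and (ii) but failing (iii) are kept as
an explicit *ambiguous* class — they are neither constitutive nor
exclusive, and the four classes always partition the site union
(asserted at runtime).  On suites with no planted exclusive events,
exclusive calls stay below 5% of all sites.

Random background sites are rejection-sampled to lie ≥ 500 bp from
every excluded site and inside 500-bp windows ≥ 80% uniquely mappable
(26-mer convention); sampling is deterministic under the seed and
aborts if the feasible space appears smaller than 1% of proposals.
Saturation thresholds (for pileup display scaling) find the smallest
count t such that at most a 10⁻⁵ fraction of 50-bp windows exceed t,
with reads extended to 200 bp and control-artifact regions excluded.

## Motif analysis

All log-likelihood scores use natural log.  Half-site PWMs are built
from an aligned set of half-sites with pseudocount 0.25 per base per
column against the background base composition (uniform by default).
The bundled model derives from a curated list of 21 accepted HRE
half-site 6-mers; it is an approximation of the original
alignment-derived model (whose exact counts are not recoverable) and
any user alignment can replace it.

A dimer match requires *each* half ≥ the half-site threshold (default
5.0); this is stricter than a monolithic scan at twice the threshold,
which would accept one excellent half compensating for a failing one —
the test suite demonstrates the difference with a constructed
counterexample.  Spacers contribute nothing to the score; footprints
containing N are skipped entirely.

Threshold calibration simulates 10⁶ 100-bp sequences from a
third-order Markov model (maximum-likelihood fit with pseudocount 0.25
per transition, N-containing contexts excluded) and measures the
per-sequence probability of at least one match on either strand.  PWM
scores form a discrete lattice — many words share the same
column-weight sum — so no threshold achieves an arbitrary target rate
exactly.  The default rule returns the observed score whose match rate
is *closest* to the target, which keeps held-out false-positive rates
inside 99% binomial confidence intervals of the targets at 10⁶
sequences; a conservative `rule="le"` variant (smallest score whose
rate does not exceed the target) is available but undershoots rare
targets by up to ~10% relative, precisely because of the lattice.

Differential motif frequency between two site sets counts sites
containing ≥ 1 match and applies a two-sided Fisher's exact test per
motif; p-values are reported unadjusted, as the output is a screening
table.

## Prediction from prior state

Features are reads-per-million in 500-bp windows ([pos−250, pos+250)).
Rank normalisation maps sums to (rank−1)/(N−1) with mean ranks for
ties (a single position scores 1 by convention); combined rankings
multiply two rank scores and re-rank the product.  Conservation is the
arithmetic mean over [pos−10, pos+10), missing data counting as zero.

The SVM harness standardises features by training-set mean/SD (RBF
kernels need comparable scales; a raw mode exists), trains
scikit-learn's `SVC` with library defaults (C-classification, RBF
kernel), holds out 50 positives + 50 negatives per repeat, and reports
mean ± SD ROC-AUC over 100 repeats, all deterministic under the seed.

## Synthetic generator

The generator's defaults define the study conditions: background 0.05
reads/bp, point events of strength 200 (expected read count, Poisson-
distributed per event), events ≥ 2 kbp apart, equal-depth control,
duplicate artifacts by resampling existing reads at a configurable
rate, auxiliary prior-state tracks enriched at a true event
independently with probability *informativeness* (strength 100 over
0.02 reads/bp background).  Conservation is elevated (0.9 vs ~0.1
noise) over planted motifs; mappability defaults to 1 outside
explicitly planted unmappable blocks.  Genomes are sampled from a
Markov model (default: order 0 at 42% GC, mammalian-like); planted HRE
dimers draw both halves from the top quantile (default 0.75) of the
PWM's own distribution with uniform spacers and random strand, never
overlapping one another.

What it does **not** emulate: sequencing errors, read mappability
structure of a real genome, paired-end fragments, copy-number or
chromatin-accessibility biases shared between channels, and motif
context (planted dimers sit in Markov background, not in real
regulatory sequence).  Passing tests therefore demonstrate the
correctness and calibration of the *algorithms* under their stated
assumptions, not performance on real libraries whose biases violate
them.

## Problem sizes and determinism

The validation suite exercises: exact brute-force equivalence on
100-kbp instances; null calibration over 50 seeds (200-kbp genomes,
0.2 reads/bp); planted-event recovery on a 5-Mbp suite with 200 events
(100 shared / 50 + 50 exclusive); scaling recovery over 2,000 10-kbp
windows; binding-model recovery at ~20,000 reads; threshold
calibration at 10⁶ + 10⁶ sequences; ranking dominance over 10 suite
seeds; and SVM runs with 150 bound / 1,000 unbound sites at 100
repeats.  These sizes keep the whole suite in the low minutes while
leaving every statistical check well-powered.

Every operation is a pure function of its inputs and an explicit seed
(`numpy.random.Generator` / `SeedSequence` spawning throughout; the
sequential Markov walk is JIT-compiled with numba).  The pipeline
summary is byte-identical across reruns of the same configuration; no
golden outputs are checked in, since cross-version floating-point
drift would make them brittle — determinism is asserted by re-running.
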