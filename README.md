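# bindshift

Ligand-dependent transcription-factor occupancy analysis for ChIP-seq.

Nuclear hormone receptors such as the retinoic acid receptor (RAR) were
long assumed to sit on their genomic targets constitutively, switching
between repression and activation when the ligand arrives.  Testing
that model requires comparing a TF's genome-wide binding profile
*across conditions* — before and after ligand exposure — which raises
four analysis problems that this package solves as a library:

1. **Binding-event detection.** A two-pass caller finds positions where
   the ChIP signal channel is enriched over a depth-scaled control.
   Reads are extended to the support of an empirical binding-distribution
   model m(d) (the probability of a sequenced 5' end at signed offset d
   from an event) and counted in 50-bp bins every 25 bp.  A bin is a
   candidate when its count x exceeds a dynamic Poisson background,
   P(X ≥ x | λ) < 10⁻⁹ with λ = max(genome-wide, 5-kbp, 10-kbp mean
   scaled-control count).  Candidate bins are scored against the raw
   control counts with a one-sided binomial test — s signal and c
   control reads give p = P(X ≥ s), X ~ Bin(s + c, σ/(σ+1)) where σ is
   the control scaling factor — merged, Benjamini–Hochberg corrected,
   and kept at corrected p ≤ 0.001.  Pass 1 estimates σ (through-origin
   regression over event-free 10-kbp windows) and refits m(d) from
   strong events; pass 2 re-detects with the refined parameters.  A
   broad-domain mode (500/250 bins, homogeneous background, p ≤ 0.01)
   handles dispersed marks, and a channel-swap rerun gives an empirical
   FDR.
2. **Constitutive vs condition-exclusive classification.** A site is
   constitutive when the other condition has an event within 200 bp;
   it is exclusive to condition A when it is (i) significant in A vs
   the common control, (ii) not significant in B, and (iii) still
   significant when A is re-called using B as the control channel —
   criterion (iii) rejects sites whose B enrichment merely falls just
   below the significance threshold.
3. **Hormone-response-element motif analysis.** HREs are two ~6-bp
   half-sites (consensus near TGACCT) in direct/inverted/everted repeat
   geometry with a 0–8 bp spacer (DR0–DR8, IR, ER).  A log-likelihood
   half-site PWM scans both strands; a dimer match requires *both*
   halves ≥ 5.0 (natural log) with the spacer unpenalised.  Score
   thresholds for full dimers are calibrated to 1%/0.5%/0.1%
   per-sequence false-positive rates on 10⁶ × 100-bp sequences from a
   third-order Markov model of the genome, and motif frequencies
   between two site sets are compared with Fisher's exact test.
4. **Predicting future binding from prior state.** Reads-per-million
   counts in 500-bp windows around every motif match, taken from
   *earlier-stage* ChIP experiments, are rank-combined (product of
   rank-normalised scores) with motif similarity; true-positive vs
   additional-prediction curves quantify the gain, and a repeated-
   holdout RBF-kernel SVM (100 repeats, 50+50 held out) classifies
   bound vs unbound motif instances by ROC-AUC.

Because real deposited reads are not desk-reproducible, the package
ships a first-class synthetic generator (`bindshift.synth`) that
produces genomes (Markov-sampled), planted HRE dimers, model-shaped
read pileups over Poisson background, two-condition suites with
shared/exclusive events, duplicate-read artifacts, auxiliary
"prior-state" tracks with controllable informativeness, and
mappability/conservation tracks — all with ground truth and exact
seeding.

## Worked example

```python
import numpy as np
from bindshift import call_events, call_exclusive
from bindshift.synth import SyntheticSpec, simulate_experiment_suite

spec = SyntheticSpec(
    genome_length=2_000_000, background_rate=0.05,
    n_shared=40, n_a_only=20, n_b_only=20, event_strength=200.0, seed=7,
)
suite = simulate_experiment_suite(spec, make_genome=False)

events, scaling, model = call_events(suite.datasets["signal_A"],
                                     suite.datasets["control"])
print(f"called {len(events)} events (sigma = {scaling.sigma:.3f}, {scaling.mode})")
top = max(events, key=lambda e: e.fold)
print(f"strongest event: {top.chrom}:{top.peak}  fold = {top.fold:.1f}  "
      f"corrected p = {top.p_corrected:.2e}")

result = call_exclusive(suite.datasets["signal_A"], suite.datasets["signal_B"],
                        suite.datasets["control"])
print(f"constitutive = {len(result.constitutive)}  A-exclusive = {len(result.a_exclusive)}  "
      f"B-exclusive = {len(result.b_exclusive)}  ambiguous = {len(result.ambiguous)}")
```

prints

```
called 58 events (sigma = 0.996, regression)
strongest event: chr1:1839219  fold = 29.6  corrected p = 1.63e-05
constitutive = 72  A-exclusive = 18  B-exclusive = 19  ambiguous = 2
```

Of the 60 events truly present in condition A (40 shared + 20
A-exclusive), 58 are recovered; the scaling regression correctly finds
the two channels at equal depth (σ ≈ 1); and the exclusivity
three-criterion rule assigns almost every shared event to the
constitutive class and the planted condition-specific events to their
exclusive classes, with two borderline sites flagged ambiguous rather
than mislabelled.

A `bindshift` command-line tool wraps the same library surface
(`simulate`, `callpeaks`, `calldomains`, `exclusivity`, `background`,
`coincide`, `scanmotifs`, `calibrate`, `predict`, `run-all`); `run-all`
executes the whole synthetic analysis and writes a machine-readable
`summary.json` that is byte-identical across reruns of the same
configuration.

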