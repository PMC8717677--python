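# Methods

## Outcome definition

A patient's treatment outcome is derived from the five daily (SBP, DBP)
readings immediately following therapy initiation: *successful* iff the
arithmetic 5-day mean SBP is strictly below 140 mmHg and the mean DBP strictly
below 90 mmHg.  Equality at either threshold labels the patient unsuccessful
("less than" is taken literally), and the label is invariant to day order.
Pre-initiation attribute values are assumed to have been measured within the
valid window; the schema carries no timestamps, because the synthetic
generator controls timing and a tie-break for repeated measurements is not
part of the method.

## Cleaning funnel

Records are excluded in a fixed order — non-monotherapy, off-label dose, any
missing value among the 19 attributes — and each excluded record is counted
once, under the first rule that fires.  This makes the exclusion log a
partition of the input (`kept + Σ counts = total`) and cleaning idempotent.

## Normalisation

Each attribute is mapped onto [0, 1] by a fixed affine transform with
per-attribute constants `attr_min`/`attr_max` (the builtin table's values are
the observed extremes of the reference cohort; they are configuration, not
re-estimated from data).  Out-of-range raw values abort in the default
*strict* mode, since they indicate input outside the attribute's plausible
span; a *clip* mode clamps instead for exploratory use.  Sex (codes 1 = male,
2 = female) normalises to {0, 1} like any other attribute.

Clinical reference intervals pass through the same transform and are reported
at half-up 3-decimal rounding.  Three published normalised bounds are not
reproducible from their printed raw ranges under any standard rounding —
Urea lower (computed 0.068 vs published 0.070), PLT lower (0.199 vs 0.200)
and DBP (printed raw range "60–60", yet a published upper bound of 0.480
that back-maps to 90 mmHg).  The package stores the DBP reference as
(60, 90) mmHg for internal consistency and reports all three discrepancies
(`verify_reference_table`) instead of hard-coding the published figures.

## Spectra

Per group, each attribute's normalised values are histogrammed over B
equal-width bins on [0, 1]; bins are half-open `[lo, hi)` with the last bin
closed so 1.0 stays in range.  B defaults to 50 (0.02 resolution — finer
than the 2-dp precision at which breakpoints are reported).  The difference
spectrum subtracts *frequencies*, not counts, because the groups differ in
size; each difference row sums to zero by construction.  Binary attributes
use the same binning and concentrate in the outermost bins.  An empty group
yields an explicit all-zero grid rather than a division error.  Counts and
frequencies are both exposed, and either can drive the heatmaps.

## Classification

The visual three-way categorisation (symmetric / asymmetric with a breakpoint
/ asymmetric but interleaved) is formalised with three statistics:

* **Asymmetry** — total-variation distance ½ Σ|Δ| between the binned group
  distributions, threshold τ = 0.10.  TVD is the natural magnitude of the
  difference map: 0 for identical rows, 1 for disjoint ones.
* **Breakpoint location** — the interior bin edge maximising |F_s − F_u|,
  the two-sample Kolmogorov–Smirnov location, with ties broken toward the
  smallest edge.  This is exactly the point where cumulative dominance flips.
* **Dominance purity** — on each side of the candidate edge, the fraction of
  that side's mass belonging to the group dominating it, averaged over the
  two sides; threshold 0.75.  Interleaved groups score ≈ 0.5 regardless of
  asymmetry, which is what separates the "asymmetric without a breakpoint"
  category.  Degenerate inputs (zero CDF gap everywhere) never yield a
  breakpoint; a breakpoint whose interior bins carry no mass (binary
  attributes such as Sex) is reported but flagged degenerate, with the
  tie-break rule placing it at the first interior edge.

An attribute is **important** iff asymmetric *and* a breakpoint exists.  The
independent support rule — |mean_s − mean_u| > 0.05, strict — is reported
alongside rather than folded in: the published reference cohort itself
contains one attribute (HR) that is important under the breakpoint rule yet
falls below the mean-difference threshold, and the package reproduces that
disagreement instead of hiding it.  Breakpoints are displayed at 2 dp
(half-up), matching the precision of the published estimates.

The thresholds are deliberately conservative in combination: under the null
(identical group distributions, n = 2000, B = 50) the empirical TVD between
two finite-sample histograms hovers near τ, but the purity of the best KS
split stays far below 0.75, so the important rate per attribute × seed is
bounded at 5% empirically (see the acceptance suite).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes — a
two-outcome cohort with per-attribute group distributions on the normalised
scale — and nothing more.  Values are sampled on [0, 1] per group and family
(`truncated_normal` via exact inverse-CDF sampling, `uniform`, or the
`two_block` dominance-crossover construction that places each group entirely
on one side of a configurable breakpoint) and mapped to native units through
the attribute table, so normalisation inverts generation exactly.  Sex is a
Bernoulli draw on the group's location parameter, coded 1/2.  BP day-series
are the intended group's base level (125/78 vs 152/96 mmHg) plus N(0, sd)
daily noise, resampled (deterministic reflection as a fallback) until the
5-day means land on the intended side of the 140/90 thresholds — so outcome
labelling always reproduces the intended group.

Defaults: group locations equal to the published reference-cohort group
means (the only distributional information available about it), scale 0.15
on the normalised scale as a realistic lab-value dispersion, success
fraction 0.5, BP noise 5 mmHg.  All randomness derives from one seed via
`numpy.random.SeedSequence` substreams keyed on fixed (role, attribute,
group) tuples, so output is independent of evaluation order.

What the generator does **not** emulate: covariate correlation (the analysis
treats attributes marginally), longitudinal dosing/adherence, measurement
timing, multimodality or skew beyond truncation.  Passing tests therefore
show that the pipeline's arithmetic and the detector's recovery behaviour are
correct under the assumed marginal structure — not that real EHR cohorts
satisfy that structure.

## Problem sizes and determinism

The test and acceptance workloads use cohorts of n = 2000 (matching the
order of magnitude of the reference cohort's 2134 eligible patients), 20
seeds for recovery rates and 10 for null control; TVD sampling-noise checks
use n = 5000 and the uniform-binning check n = 10000.  Recovery is asserted
within ±0.04 (two bin widths at B = 50).  Reports are plain JSON with sorted
keys; SVG output strips the timestamp and fixes the hash salt so repeated
renders are byte-identical.

## Known limitations

* The three-way categorisation depends on τ and the purity threshold; both
  are package defaults formalising a judgement the original analysis made
  visually, and should be treated as tunable sensitivity parameters.
* A single breakpoint is assumed; attributes with multiple dominance flips
  are driven toward the "interleaved" category by the purity score.
* No inferential machinery (p-values, multiplicity correction, bootstrap
  intervals on breakpoints) is provided; verdicts are descriptive.
* Group means on a min–max scale are sensitive to the fixed extremes; the
  support rule inherits that sensitivity.
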