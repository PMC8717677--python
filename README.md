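# drugspectrum

Treatment-response phenotyping for antihypertensive drugs via *drug-related
attribute spectra*.

Given a cohort of patients starting a drug (the motivating case is metoprolol
monotherapy for hypertension), each patient is labelled **successful** when
the mean blood pressure over the five days after initiation satisfies
SBP < 140 mmHg *and* DBP < 90 mmHg, and **unsuccessful** otherwise.  Nineteen
pre-initiation clinical attributes (haematocrit, haemoglobin, renal markers,
lipids, electrolytes, glucose, age, sex and haemodynamics) are min–max
normalised onto [0, 1] with fixed per-attribute constants,

    z = (x − attr_min) / (attr_max − attr_min),

and each attribute's normalised values are histogrammed per outcome group
into an *attribute spectrum*.  The **difference spectrum** Δ subtracts the
unsuccessful group's bin frequencies from the successful group's.  An
attribute is classified **drug-related ("important")** when

* the two group distributions are *asymmetric* — total-variation distance
  ½ Σ|Δ| ≥ τ (default 0.10), and
* a *dominance breakpoint* exists — the interior bin edge `c*` maximising the
  empirical-CDF gap |F_s(c) − F_u(c)| (the two-sample Kolmogorov–Smirnov
  location) splits the axis so that each group dominates one side with
  purity ≥ 0.75.

A separate support rule flags attributes whose between-group mean difference
exceeds 0.05 in absolute value.  Because real hospital cohorts of this kind
are not redistributable, the package includes a first-class synthetic-cohort
generator whose defaults are calibrated to the published reference cohort's
group means, with a `two_block` family that plants a known breakpoint for
recovery experiments.

Intended users: biostatisticians and pharmaco-epidemiologists prototyping
response-stratification analyses on EHR-style tabular cohorts.

## Worked example

Simulate a cohort of 2000 patients in which HCT carries a dominance
crossover at 0.58 (successful group below it) and every other attribute
follows overlapping group distributions, then run the full pipeline:

```sh
drugspectrum simulate --config examples/config.yaml --out cohort_bp.csv
drugspectrum run cohort_bp.csv --out-dir results
```

which prints (abridged):

```
Attribute Asymmetric  Breakpoint  Estimate  MeanDiff  Important  |Diff|>thr
---------------------------------------------------------------------------
HCT       Yes         Yes         0.58       -0.5012  Yes        Yes
HB        Yes         No          -          -0.0657  No         Yes
PLT       Yes         No          -          +0.0284  No         No
Cr        Yes         No          -          +0.0609  No         Yes
...
```

HCT — the only attribute constructed with a dominance crossover — is the only
one classified important: its detected breakpoint (0.58) matches the planted
crossover exactly, and its large negative mean difference says successful
patients sit below it.  Attributes whose groups merely differ in mean (HB,
Cr, ...) are asymmetric and may pass the |Δmean| > 0.05 support rule, but
without a clean dominance split they are not flagged important.  `results/`
also receives the group and difference spectra as CSV, the heatmap figures,
the exclusion log of the cleaning funnel and a JSON report echoing all
thresholds.

Inspect the builtin normalisation table (recomputed normalised reference
intervals, with the three published bounds that cannot be reproduced from
their printed raw ranges flagged):

```sh
drugspectrum reference-table
```

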