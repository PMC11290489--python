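# Methods

## The measurement model

A suspension-bead-array screen reports one median fluorescence intensity
(MFI) per (sample, capture bead, detection antibody).  The synthetic
generator — the stand-in for the raw screen, which is not distributed —
models each record as

    log MFI = baseline(bead) + affinity(capture antibody)
              + log_effect · 1[complex read out] + ε,   ε ~ N(0, noise_sd²)

and `MFI = exp(·)`.  The choices behind this:

* **Log-normal noise.**  Bead-array intensities are strictly positive and
  their replicate noise is close to multiplicative (a roughly constant CV),
  so noise is Gaussian on the log scale.
* **Per-antibody affinity offsets** are drawn once per capture antibody and
  reused across all samples.  This is what makes *per-antibody* score
  populations (and per-antibody thresholds) meaningful, and it is why
  replicates of the same antibody are correlated: the antibody's background
  is a property of the reagent, not of the well.
* **Buffer wells** contain no lysate and are simulated as baseline-only
  records; their per-(capture, detection) medians define SNR denominators,
  so a buffer record's own SNR has median exactly 1.
* A complex is *read out* only when the sample truly contains an interacting
  receptor–RAMP pair **and** the capture–detection scheme can see it: tag
  capture with opposite-tag detection, RAMP-specific capture whose bead
  matches the sample's RAMP, or receptor-specific capture of the sample's
  receptor with RAMP-tag detection.

### Screen design emulated

`simulate_screen` reproduces the heterologous screen layout: every receptor
expressed alone (receptor + mock) and with each RAMP — `n_gpcrs × (1 +
|ramps|)` membrane samples — read over five epitope-based schemes and zero to
six receptor-specific capture antibodies per receptor, plus a mock-only
control and buffer wells.  `simulate_endogenous` emulates the wild-type
cell-line screens: receptor-specific capture beads with anti-RAMP detection,
biological triplicates in technical duplicate, and a minority of truly
interacting pairs.  `simulate_rcp_counts` produces per-image
rolling-circle-product counts (Poisson per channel, uniform nuclei counts,
and a no-primary-antibody blank series) for the proximity-assay statistics.

### Default parameters

| parameter | default | units / meaning | rationale |
|---|---|---|---|
| `interact_prob` | 0.5 | per-pair interaction probability | balanced classes give the calibration curves a well-defined crossing |
| `log_effect` | 2.0 | log-MFI shift of a read-out complex (≈ 7.4-fold) | 4 × `noise_sd`: strong but not trivial separation |
| `noise_sd` | 0.5 | SD of log-MFI noise in the heterologous screen | sample-to-sample variation (transfection + assay) dominates there |
| `ab_affinity_sd` | 0.5 | spread of per-antibody log offsets | polyclonal antibody backgrounds vary several-fold |
| `n_protein_abs_range` | (0, 6) | receptor-specific antibodies per receptor | matches a panel in which not every receptor has validated antibodies |
| endogenous `noise_sd` | 0.15 | replicate noise (technical CV ≈ 15%) | replicates of one lysate are far tighter than independent transfections |

The endogenous regime deliberately has `ab_affinity_sd ≫ noise_sd`: the
antibody-to-antibody background spread is shared across replicates, so the
replicate-mean robust-Z keeps variance ≈ 1 and the fixed 3.5 cutoff retains
its nominal meaning (see below).

## Score transformations

* **SNR** = MFI / median(buffer MFI of the same capture and detection
  antibody).  Missing buffer combinations are a hard error.
* **Quantile normalization** forces replicate columns onto the common
  reference distribution (row-mean of column-sorted values).  Ties receive
  the mean of the reference values across the tied ranks, which makes the
  operation idempotent.
* **Robust Z**: `(x − median(x)) / (1.4826 · MAD(x))`, the standard robust
  standardization whose 1.4826 constant makes the scale estimate consistent
  for the SD under normality.  Standardization is always per antibody
  population — the measurements of one capture–detection pair across
  samples — so reagents of different affinity become comparable.
* **Log scale.**  Pipeline stages feed `log(MFI)` / `log(SNR)` into the
  robust-Z step.  Because the noise model is multiplicative, the log scores
  are the ones with a Gaussian null; robust Z applied to *linear*-scale
  intensities has a substantially inflated right tail at extreme cutoffs
  (the exponential convexity turns a symmetric log deviation into a skewed
  linear one), which would detach the fixed 3.5 cutoff from its nominal
  tail probability.  Within one antibody's population the transform is
  monotone, so rankings — and calibrated-threshold calls — are unaffected;
  only the meaning of fixed cutoffs changes.

## Threshold selection

* **Literature-calibrated (epitope schemes).**  For each (RAMP, scheme), the
  labeled pairs' scores are swept over a candidate grid (sorted unique
  scores plus midpoints — between grid points nothing changes, so this grid
  is exhaustive).  Sensitivity is the fraction of labeled interactors with
  `score > t`; specificity the fraction of labeled non-interactors without.
  The threshold is the grid point minimizing |sens − spec|; ties break
  toward larger sens + spec, then toward the smaller threshold (step curves
  can touch over an interval, and the smallest such threshold is the least
  aggressive choice consistent with the crossing).
* **Density + MAD (protein capture).**  Each receptor-specific antibody is
  thresholded at the mode of a Gaussian KDE (Silverman bandwidth, 512-point
  grid spanning the data range) of its full score population plus
  6 × 1.4826 × MAD.  Because any one antibody is off-target for almost every
  sample, mode and MAD track the non-interacting bulk.  A zero MAD falls
  back to the sample SD; both zero is a degenerate-scale error.
* **Endogenous fixed cutoff.**  SNR → quantile normalization across the six
  replicate columns (within cell line by default; a switch pools cell
  lines) → robust Z of log scores per replicate across the antibody
  population → technical duplicates averaged within biological replicate →
  replicate-mean R.Z compared against 3.5, strictly.  Under the
  no-interaction null with replicate-shared antibody backgrounds, the
  replicate-level scores are ≈ N(0, 1), so the expected exceedance rate at
  3.5 is the normal tail Φ(−3.5) ≈ 2.3 × 10⁻⁴ — the property the
  null-calibration tests check against a Poisson band.

All hits use strict inequality: a score exactly at its threshold is not a
hit.

## Evidence classes and integration

Per (receptor, RAMP, capture family), with f = passing/evaluated schemes:
strong if f > 2/3, weak if f < 1/3, medium otherwise — a fraction exactly at
a third is medium (the rule is stated with strict inequalities at both
boundaries, so the boundary cases default to the middle class); absent iff
no scheme produced data, which can only happen for protein capture.  For
protein capture every antibody with data counts as one scheme.

The decision table (epitope × protein) is total over all 3 × 4
combinations: strong+strong, strong+medium, medium+strong ⇒ yes; weak+weak,
weak+medium, medium+weak ⇒ no; strong+weak, weak+strong, medium+medium ⇒
inconclusive; with protein data absent: strong ⇒ yes, weak ⇒ no, medium ⇒
inconclusive (the one combination not forced by the stated rules; assigned
by elimination, since a lone medium scheme family decides nothing).

Summary outputs: hits per (RAMP, scheme) as call-matrix column sums,
UpSet-style membership-pattern counts of the per-RAMP interactor sets
(patterns partition the receptor universe), evidence-class proportions per
expression quartile (linear/type-7 quantiles, boundary ties to the lower
bin), and the percentage of panel antibodies detecting at least one complex
per RAMP.

## Downstream statistics

* **Expression ratios.**  GPCR:RAMP nTPM ratio per (receptor, cell type)
  where both genes clear nTPM > 1 (strict); each (receptor, context) is one
  observation (a per-receptor-median alternative is a configuration switch);
  interactors vs non-interactors compared per RAMP with the two-sided
  Wilcoxon rank-sum test; inconclusive receptors excluded.
* **Binarization and clustering.**  Expressed ⇔ nTPM > 1; heat values are 0
  or log2(nTPM); hierarchical clustering of genes over contexts with
  Euclidean distance and complete linkage (the method names no
  linkage/metric; both are exposed as configuration).
* **Coupling enrichment.**  Beta-arrestin couplings binarized at
  log(Emax/EC50) > 0.  2×2 comparisons (family membership among
  primary/secondary couplers, arrestin subtypes) use the Fisher exact test
  with the conditional-MLE odds ratio; the number-of-primary-couplings
  comparison is an r×c exact conditional (Freeman–Halton) test, implemented
  by margin-constrained enumeration and reporting p only.  Comparisons with
  an empty margin are skipped with a warning.
* **Proximity assay.**  RCPs/cell = counts/nuclei per channel; the mean
  blank (no-primary-antibody) RCPs/cell is subtracted and negative nets
  clamp to 0 with a logged count; percent complexed = net overlap / total
  net RCPs across the three channels × 100.  Conditions are compared by
  one-way ANOVA followed by Dunnett many-to-one tests against the positive
  control (α = 0.05), via the standard multivariate-t procedure.

## Problem sizes used in validation

The validation suite runs entirely on synthetic data: screens of 15–60
receptors for end-to-end recovery (50 receptors, effect 4 × noise SD, full
noiseless truth set, fixed seed, ≥ 95% agreement on decided pairs and ≥ 0.95
per-scheme sensitivity/specificity at calibrated thresholds), a 215-receptor
sample-sheet check of the design arithmetic, an 8,000-antibody single-cell-
line null screen for tail calibration of the endogenous cutoff, 1,000-
instance randomized equivalence of threshold selection against exhaustive
enumeration, and 1,000-repetition null calibrations of the Dunnett-based
procedures.

## What the synthetic data do and do not show

The generator reproduces the screen's *design* (sample layout, scheme
structure, replicate structure, antibody panels, buffer wells) and a
realistic noise family, so passing tests demonstrate that the statistical
machinery is correct and calibrated: transformations compute what they
claim, thresholds land where the truth set puts them, the voting logic is
total and monotone, and error rates are nominal under the model.  They do
not demonstrate robustness to features real screens have and the model
lacks: plate-position and batch effects, bead aggregation, antibody
cross-reactivity, non-specific binding that correlates with expression
level, heavy-tailed outliers beyond log-normality, and truth sets that are
biased rather than merely noisy.  Headline counts of the real screen are
properties of the real data and are not reproduced here.

## Known limitations

* In-sample calibration: thresholds are calibrated on all labeled pairs and
  then applied to the same screen (no pair-level cross-validation is
  performed; a leave-pair-out switch exists for sensitivity analysis).
* The 6-MAD density threshold is deliberately stringent; at moderate effect
  sizes protein capture contributes mostly weak evidence and drives
  epitope-strong pairs to *inconclusive* rather than *yes*.  This is the
  intended conservative behavior of the rule, not a defect of the
  implementation.
* The r×c exact test enumerates tables and is limited to small totals
  (≤ 200); larger tables should use a chi-squared or Monte-Carlo approach.
* Quantile normalization assumes the replicate columns measure the same
  population; it is not a batch correction.
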