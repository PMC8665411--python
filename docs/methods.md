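# Methods

This note documents the statistical procedure implemented by `lfqdiff`,
the assumptions behind it, what the synthetic-data generator does and does
not emulate, and the choices made where the design was genuinely open.

## Pipeline

Input is a long-format table of peptide XIC intensities, one row per
(peptide, condition, biological replicate, technical replicate, fraction).
Stages run in a fixed order:

1. **Fraction summation.** XICs of one peptide are summed across off-line
   fractions on the linear scale (areas add); the sum is missing only when
   every fraction is missing.
2. **Technical-replicate merging.** Repeat injections of one sample are
   averaged on the linear scale; a value measured once passes through.
3. **Feature groups.** Non-proteotypic peptides are discarded. At protein
   level, one group per accession; at site level, each peptide contributes
   one observation per Gly-Gly position it carries and one group is made
   per (protein, position). A peptide is eligible for model fitting only
   if it is *shared* — observed at least once in each condition. Groups
   observed in a single condition are carried as condition-specific
   candidates. Detection counts per condition (number of biological
   replicates with at least one peptide observation) are taken before the
   shared filter, so condition-specific features keep honest counts.
4. **log2 transform.** Zero intensities are illegal by contract (missing
   values encode non-observation; a zero XIC is not a measurement).
5. **Normalization.** Per biological replicate *j*, over all quantified
   observations ("total signal"): `x' = (x − m_j)/s_j · s̄ + m̄` with
   `m_j` the median, `s_j` the scaled MAD (1.4826·MAD; IQR available via
   config), and `m̄`, `s̄` the across-replicate means used as re-anchors.
   After the transform all replicate medians and scales are equal. A
   D'Agostino–Pearson normality check per replicate is recorded in the
   normalization report; it is advisory only and gates nothing.
6. **Outlier removal.** Within each (feature, condition) cell,
   observations are centered on their peptide's mean across all
   replicates; Tukey's fences `[Q1 − k·IQR, Q3 + k·IQR]` (k = 1.5,
   quartiles by linear interpolation — the convention where Q1 of
   {1,2,3,4} is 1.75) decide removals. The removal unit is the **peptide**:
   the fences are applied to the peptides' mean centered residuals, and an
   outlying peptide loses all its observations in that cell. Cells with
   fewer than 4 units pass unfiltered.
7. **Model.** Per feature, ordinary least squares of
   `log2 x = μ + β_p + δ·1[c=b] + ε`; `δ` is the log2 fold change of
   condition b over condition a, tested two-sided against the t
   distribution with the residual degrees of freedom. Condition-specific
   features bypass the model and carry no p-value.
8. **FDR.** Benjamini–Hochberg step-up across all tested features; the
   family size counts only features with a p-value (specific and
   insufficient-data features are excluded).
9. **Candidates.** Fold ≥ threshold in the configured direction
   (inclusive), adjusted p ≤ alpha (inclusive), and detection in at least
   `min_detect_reps` replicates of either condition. Condition-specific
   features join when their presence pattern matches the direction
   (present only in b = increase, only in a = decrease) and they meet the
   detection filter in the condition where they exist.
10. **Integration.** Site-level candidate sets are collapsed to their
    distinct proteins (the site-to-protein mapping is kept for
    provenance); pairwise and full intersections are computed on protein
    ids, with lexicographic ordering for determinism. Heatmap exports
    annotate each candidate × experiment cell with the linear fold
    `2^|δ|`, the direction, and significance stars
    (\*\*\* ≤ 0.001, \*\* ≤ 0.01, \* ≤ 0.05).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `fold_threshold` | 2 | minimum linear fold change (inclusive) |
| `alpha` | 0.05 | maximum BH-adjusted p (inclusive) |
| `fence_k` | 1.5 | Tukey fence factor, log2 residual units |
| `min_detect_reps` | 3 | biological replicates of either condition with a detected peptide |
| `outlier_unit` | `peptide` | fence removal unit (`observation` optional) |
| `scale_estimator` | `mad` | robust scale of the normalizer (`iqr` optional) |
| `top_n` | none | optional cap on shared peptides per feature |
| `normalize` | true | median-and-scale normalization on/off |

## Design choices where the procedure was open

* **Model form.** "Adjusted on peptides and biological replicates" is
  realized as fixed peptide main effects with replicates entering as
  independent observations (the residual term). A replicate random effect
  or empirical-Bayes variance moderation (limma-style) is explicitly out
  of scope for v1; with the replicate counts involved (3–8 per condition)
  a random-effect variance would be poorly identified per feature.
* **Outlier unit.** Fencing individual observations of well-behaved
  normal noise trims the residual tails and understates the variance —
  measured on global-null simulations it inflates the raw p < 0.05 rate to
  8–11%. Removing whole peptides (within a condition) targets the actual
  failure mode — an aberrant peptide contaminates all its measurements via
  interference or mis-integration — and leaves null p-values approximately
  uniform. Peptide-level removal is therefore the default; the
  observation-level variant remains available as `outlier_unit`.
* **"Shared" peptides.** Interpreted as ≥ 1 observation in each
  condition, not presence in every replicate; a stricter reading would
  duplicate the separate ≥ 3-replicate detection filter.
* **Technical merging scale.** Linear: XICs are chromatographic areas, so
  repeat injections average as areas, not as log ratios.
* **Multiply-modified peptides.** A peptide carrying two or more Gly-Gly
  remnants contributes one observation to every site it covers; silently
  assigning it to a single site would drop evidence. Site positions are
  assumed unambiguous (no localization scoring).
* **No peptide cap.** All shared proteotypic peptides are used by default;
  `top_n` exists as a knob but is unlimited, since capping discards
  information without a variance benefit in this model.
* **Threshold boundaries.** Fold exactly 2 and adjusted p exactly 0.05 are
  included, matching the inclusive "≥ 2" / "≤ 0.05" convention used for
  the same cut-offs elsewhere in this workflow family.
* **Detection filter for specific features.** Applied in the condition
  where the feature exists (the only condition where it can be satisfied).

## Numerical notes

* Quartiles use linear interpolation; fence membership is inclusive, so a
  zero-IQR cell retains everything.
* A zero standard error with positive residual df yields p = 0 for a
  nonzero estimate and p = 1 otherwise; zero residual df yields a missing
  p (the estimate is still reported) and exclusion from the BH family.
* Normalization requires every replicate to have ≥ 2 observations and a
  nonzero scale; degenerate replicates raise instead of silently passing.
* Normalization is equivariant to location/scale changes of single
  replicate columns only up to the common re-anchoring affine map; all
  between-column statistics (fold changes, p-values) are invariant.
* Output TSVs format floats with 6 significant digits for byte-stable
  golden comparisons; full precision is available
  (`write_results(..., full_precision=True)`). Intensity tables round-trip
  at 17 significant digits.
* All randomness flows from a single seed per run; the generator consumes
  one RNG stream in a fixed block order (features → peptides → replicate
  effects → observation noise → outliers → missingness → fractions), so a
  seed pins the exact table.

## What the generator emulates — and what it does not

`simulate_experiment` produces log-normal peptide intensities with
feature baselines (default SD 2 log2 units), peptide ionization offsets
(SD 1 — between-peptide variance dominates real LFQ data), per-replicate
location shifts (SD 0.3), residual noise (SD 0.5), technical-injection
noise (SD 0.2), an injected log2 effect for a chosen fraction of features
(default 1% — substrate screens of this kind report candidate rates below
~1.5%), condition-specific features, observation-level outlier
contamination, and missingness (completely-at-random by default, with an
optional intensity-dependent logistic mode). Fractionated designs split
each intensity over at most two randomly chosen fractions — a peptide
elutes in few adjacent high-pH fractions — with linear-scale proportions
summing to one, so fraction summation is exactly conservative.

Not emulated: retention times, charge states, spectra,
identification-level error, shared (non-proteotypic) peptides, correlated
missingness between peptides of one protein, and interference-driven
heavy-tailed noise. Passing tests therefore demonstrate the statistical
correctness and calibration of the pipeline under its own model
assumptions, not robustness to every artifact of real LC-MS/MS data.

The built-in designs mirror the three study layouts: whole proteome
(3 vs 6 biological replicates, six fractions each, protein level), diGly
ubiquitylome (3 vs 3, two injections per sample, site level), pan-UB
ubiquitylome (4 vs 8, protein level).

## Problem sizes used by the checks

The acceptance checks run at desk scale by choice: null calibration on 500
features (KS test) and 20 replicate simulations (false-discovery
proportion); parameter recovery pooled over 10 simulations of 2000
features at a 1% changed fraction (≈ 200 changed features — a single
simulation's mean bias is Monte-Carlo dominated, and larger changed
fractions genuinely bias median normalization by ≈ 1.4 × the changed
fraction in log2 units); exact recovery on a noiseless 100-feature
simulation with normalization disabled, since median/scale normalization
is not fold-preserving once effects are injected and exactness to 1e-10
is a property of the estimation core.

## Known limitations

* Fixed-effects OLS treats replicates as independent observations; any
  replicate-level covariance beyond the normalized location shift is
  unmodeled.
* Median/scale normalization assumes most features are unchanged; fold
  estimates acquire a bias of roughly 1.4 × (changed fraction) log2 units
  when that assumption is violated.
* Condition-specific features carry no significance statement at all —
  their selection rests entirely on the detection filter.
* No imputation: missing intensities are never filled in, and features
  losing a whole condition to missingness migrate to the specific branch.
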