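# Methods

## Scope and model

The package reproduces, at desk scale, a two-arm analysis for finding and
validating membrane targets for fluorescence molecular endoscopy of
esophageal squamous neoplasia: (A) confounder-corrected differential
expression with permutation-based FDR control and rule-based target
selection; (B) ex vivo validation statistics — IHC H-scores with
nonparametric group comparison, and fluorescence biopsy quantification
(MFI, ROC with cut-off, pixel-level tracer-vs-target overlap). Patient data
are replaced by seeded generators calibrated to the published summary
statistics, so every stage is testable offline.

## Confounder correction (FGmRNA-style profiles)

The published FGmRNA method identifies non-genetic transcriptional
components on an independent compendium of ~77,000 arrays and uses them as
covariates. That covariate inventory is not distributed, so this package
re-creates the *scheme* on the input matrix itself:

1. **Decomposition.** The gene-centered matrix (per-gene mean removed; no
   per-gene variance scaling, so effect sizes stay in expression units) is
   decomposed by SVD. Scores are scaled to unit sample variance; loadings
   absorb the singular values, so `loadings @ scores.T` reconstructs the
   centered matrix. Default `k = min(n_samples − 1, 50)`.
2. **Flagging.** Each component's gene loadings are Pearson-correlated with
   the per-gene mean tumor copy-number offset; components with p ≥ α
   (default α = 0.01) are flagged non-genetic. Constant copy number flags
   everything non-genetic with a warning.
3. **Residualization.** Each gene is regressed (OLS) on the non-genetic
   component scores; residuals are orthogonal to every removed score vector
   (checked to 1e-8 relative) and per-gene residual variance never exceeds
   the raw variance.

**Known limitation — projection attenuation.** Because the components are
estimated from the same samples they correct, regressing out m components
attenuates any fixed class contrast by `E[m/(n−1)]` (the expected squared
projection of the contrast onto m data-derived directions of the
(n−1)-dimensional sample space): ~20% at the defaults (m ≈ 49, n = 238).
The tests assert the contrast equals `spike × (1 − m/(n−1))` within 3 SE
rather than "unchanged". Rankings and Welch statistics improve regardless,
because the removed components carry far more variance than signal; the
original method avoids the attenuation by estimating covariates on
independent data. At very small n (k ≈ n−1) the residual degenerates to the
few retained components — choose k ≪ n for small matrices.

## Class comparison and MVP-FDR

Welch's t (unequal variances, Welch–Satterthwaite df, two-sided p from the
Student t distribution) is computed per gene, vectorized over genes and
permutations. Degenerate convention: both variances zero with equal means
gives t = 0, p = 1; with unequal means ±∞, p = 0.

The multivariate permutation test is the step-down order-statistic
construction: candidate thresholds are the sorted observed p-values; for
each candidate c, class labels are permuted B times (default B = 1000;
exhaustive enumeration when the design has fewer than 500 distinct
assignments) and the FDP bound at c is `Q(c)/max(1, R(c))`, where R(c)
counts observed p ≤ c and Q(c) is the ⌈confidence·B⌉-th order statistic of
the null counts. The largest qualifying c is selected; an empty significant
set is a valid outcome. Under the global null the realized FDP exceeds the
1% target in ≈1% of runs (verified on 200 replicates). Enlarging the FDR
target never shrinks the set; permuting gene order permutes outputs
identically.

Ranking keeps upregulated genes only (tumor mean > normal mean), ordered by
ascending p, ties broken by descending |t| then gene id. Two-sided p-values
are used throughout; the upregulation filter is applied after significance.

## Target prioritization

Candidate iff rank ≤ top_n AND membrane AND carcinogenesis AND (esophageal
OR GI overexpression). Membrane localization is a hard clause by default
(every retained target in the motivating analysis was membrane-annotated);
`require_membrane=False` relaxes it. Genes absent from the annotation table
count as all-false (logged). Wet-lab exclusions (e.g. no IHC antibody) are
an optional `exclude_reason` column applied after selection.

## IHC analytics

H-score = 100·(weak + 2·moderate + 3·strong) over cell fractions, range
exactly [0, 300]. The integer bands 0–100/101–200/201–300 are generalized
to real scores as half-open intervals closed at the upper edge (≤100
negative/low, ≤200 intermediate, >200 high), since fractions need not give
integers. Group comparison uses Kruskal–Wallis (midranks, tie-corrected,
chi-square reference) even for two groups, with significance at p < 0.01;
all-identical inputs return H = 0, p = 1 by convention.

## Fluorescence quantification

* **MFI** is the mean over tissue-mask pixels; `include_background=True`
  reproduces whole-frame means.
* **Group tests**: two-tailed Mann–Whitney U, exact enumeration when
  n₁·n₂ ≤ 400 and tie-free, otherwise the tie-corrected normal
  approximation.
* **ROC**: AUC is the rank-based concordance `P(MFI⁺ > MFI⁻) + ½P(tie)`,
  asserted equal (1e-9) to the trapezoidal area of the threshold curve on
  every call. A biopsy is called positive when MFI > cutoff, so ties count
  as negative calls and the minimum threshold gives (sens, spec) = (1, 0).
  The cut-off rule is Youden's J = sens + spec − 1, ties resolved toward
  the smallest qualifying threshold (the published cut-off 2355 is accepted
  as a fixed value wherever a cutoff argument is taken).
* **Tracer positivity** defaults to a per-biopsy Otsu threshold on tissue
  pixels (fixed-value and percentile rules available; the rule and
  threshold are recorded in the output). A constant image yields an
  all-negative mask with a warning.
* **Overlap**: sensitivity = |tracer⁺∩target⁺|/|target⁺|, specificity =
  |tracer⁻∩target⁻∩tissue|/|target⁻∩tissue|; an empty denominator is
  reported as NaN and excluded from cohort medians, with n reflecting the
  exclusion. Biopsies are treated as independent; patient ids are carried
  as metadata only.

## Synthetic data: what it emulates, and what it does not

* **Compendium**: expression = confounder loadings × scores + spike + noise,
  with loadings ~ N(0, confounder_sd²), scores ~ N(0, 1) per sample, so a
  gene's expected extra variance is the sum of its squared loadings. The
  spike adds `spike_effect` to spiked genes in tumor samples, matched by a
  `cna_gain` offset in the copy-number matrix. Defaults emulate the study's
  cohort structure: 118 tumor vs 120 normal samples, 500 genes, 20 spiked at
  3× the noise SD, 5 confounders of SD 2. Confounders are class-independent
  by default; `confounder_class_bias` induces correlation to demonstrate why
  correction matters. No probe-level or normalization artifacts are modeled.
* **IHC cohorts**: per sample a category is drawn (defaults: cases
  5/30, 12/30, 13/30 over negative-low/intermediate/high; controls all
  negative/low, matching the published 25/30 vs 0/27 split), an H-score
  uniform within the band, and staining fractions solved to reproduce that
  H-score exactly (feasible-interval sampling over the simplex).
* **Biopsies**: MFI ~ Normal(μ, σ) per group, truncated at 0 by redraw,
  with the published group parameters as defaults. Note the truncation
  shifts means upward — by ≈ σ·φ(μ/σ)/Φ(μ/σ) ≈ 300 units for the ESCC
  group (μ/σ = 1.62) — so calibration tests compare sample moments against
  the truncated-normal moments, not the nominal μ. Images are abstract
  pixels (no physical scale): an elliptical tissue mask, a contiguous
  target blob grown by smoothed-noise priority to exactly the configured
  positive fraction, intensity levels (background, optional 2-pixel bright
  rim emulating edge pooling of tracer, target signal at 3× background)
  solved so the tissue mean equals the drawn MFI, plus Gaussian pixel noise
  (SD 50 units — small against backgrounds of hundreds, so the tissue mean
  stays within 1% of the drawn value).
* **What passing tests do not show**: on these clean bimodal images Otsu
  binarization recovers the target area almost perfectly (overlap medians
  ≈ 1), whereas the real ex vivo slices show low tracer sensitivity due to
  tracer penetration, incubation time and tissue viability — effects the
  generator deliberately does not model. The published slice medians
  (23.02%/85.43%) are therefore not reproduction targets.

## Numerical and design choices

* All randomness flows from one `numpy.random.Generator` per call; no
  global state. Identical seed + config give bit-identical outputs, and
  end-to-end reports serialize floats at 10 significant digits so seeded
  reruns are byte-identical.
* Problem sizes in the long-run checks: 1000 replicates for the MFI
  simulation means, 200 replicates for the FDR-control and H-score cohort
  checks, 20 seeds for spike recovery — chosen to put Monte-Carlo error
  well below the asserted tolerances (3 SE) at desk scale.
* Whether the original ranked-gene count used one- or two-sided tests is
  not documented; two-sided is assumed. How the 2355 cut-off was chosen is
  likewise undocumented; Youden is provided as the default rule while all
  cut-off statistics also accept a fixed value.
* Copy-number noise SD is fixed at 0.05 (gene-level offsets are estimates,
  not calls); the flagging test only needs tumor-mean offsets to separate
  from zero.
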