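# fme — target discovery and ex vivo validation analytics for fluorescence molecular endoscopy

Esophageal squamous cell carcinoma (ESCC) and its precursor, squamous
high-grade dysplasia (HGD), are easy to miss with white-light endoscopy.
Fluorescence molecular endoscopy (FME) can highlight lesions if a good
membrane target exists. This package implements, as a tested and reusable
pipeline, the two analysis arms used to find and validate such a target
(GLUT1, imaged with the NIR glucose analogue 2-DG 800CW):

**Discovery** — from a tumor/normal expression compendium:

1. *Confounder correction* (`fme.fgmrna`). Expression is decomposed into
   principal components; each component is flagged *genetic* or
   *non-genetic* by correlating its gene loadings with the per-gene mean
   tumor copy-number offset; each gene is regressed on the non-genetic
   component scores. The residuals ("FGmRNA profiles") retain the
   downstream effect of somatic copy-number alterations (SCNAs) while
   shedding shared non-genetic variation.
2. *Class comparison* (`fme.diffexpr`). Per-gene Welch t-test,
   `t = (x̄₁ − x̄₂)/√(s₁²/n₁ + s₂²/n₂)` with Welch–Satterthwaite df, and a
   multivariate permutation (MVP) test: for each candidate p-value
   threshold *c*, labels are permuted B times and the bound on the false
   discovery proportion is `Q(c)/max(1, R(c))`, with `R(c)` the observed
   discoveries and `Q(c)` the ⌈confidence·B⌉-th order statistic of null
   counts. The default settings control FDP ≤ 1% with 99% confidence.
3. *Prioritization* (`fme.prioritize`). Top-ranked upregulated genes are
   filtered by the imaging-target rule: membrane-localized AND linked to
   carcinogenesis AND overexpressed in esophageal or GI cancer.

**Validation** — from tissue and biopsy measurements:

4. *IHC* (`fme.ihc`). H-score = 100·(1·weak + 2·moderate + 3·strong) on a
   0–300 scale, banded into negative/low (≤100), intermediate (≤200), high
   (>200); group comparison by Kruskal–Wallis.
5. *Fluorescence* (`fme.fluor`). Per-biopsy mean fluorescence intensity
   (MFI) over the tissue mask; Mann–Whitney group comparisons; ROC/AUC
   (rank-based, equal to the trapezoidal area) with Youden or fixed cut-off;
   and pixel-level tracer-vs-target overlap on serial slices
   (sensitivity = |tracer⁺∩target⁺|/|target⁺|,
   specificity = |tracer⁻∩target⁻|/|target⁻| within tissue).

A seeded synthetic-data module (`fme.synthetic`) generates every input the
pipeline needs — an SCNA-spiked expression compendium with low-rank
confounders, IHC cohorts with a configured staining-category mix, and
synthetic biopsies whose group MFI distributions follow the published
statistics (normal 1323 ± 589.7, n=5; LGD 2027 ± 1190, n=7; HGD 4596 ± 2135,
n=13; ESCC 4309 ± 2657, n=17) — so the whole pipeline is testable offline.

## Worked example

```python
from fme import synthetic, fgmrna, diffexpr, fluor, ihc

# discovery on a simulated compendium (118 tumor / 120 normal, 500 genes,
# 20 spiked genes at 3x the noise SD, 5 confounders)
sim = synthetic.simulate_compendium(synthetic.CompendiumConfig(seed=7))
profiles, comp = fgmrna.correct(sim.expression, sim.copy_number)
stats_df, mvp, ranks = diffexpr.class_comparison(profiles, seed=7)

# validation on simulated IHC + biopsy cohorts at the published parameters
cohort = synthetic.simulate_ihc_cohort(synthetic.IHCCohortConfig(seed=7))
kw = ihc.analyze_cohort(cohort)["kruskal_wallis"]
records = synthetic.simulate_biopsy_set(synthetic.published_biopsy_config(seed=7))
out = fluor.analyze_cohort(records, cutoff=2355.0)
```

Output (seed 7):

```
components removed: 49 of 50
significant genes: 21 p threshold: 2.96e-06
spiked genes in top 20 ranks: 20
KW H = 28.67, p = 8.6e-08
AUC = 0.9722; sens = 90.0%, spec = 91.7% at cutoff 2355
overlap medians: sens 1.000 spec 1.000
```

All 20 spiked genes occupy the top 20 ranks after correction; the MVP test
declares 21 genes at FDR 1%/CI 99%; the case/control H-score cohorts differ
at p < 0.001; and on this particular seed the simulated biopsy cohort gives
AUC 0.97 with 90% sensitivity at the fixed MFI cut-off of 2355 (single-seed
values scatter around the ~0.87 / ~84% long-run means of the calibrated
simulation). Overlap medians are 1.0 on clean synthetic images — see
`docs/methods.md` for why real slices behave differently.

The same stages are available from the shell:

```sh
fme simulate compendium --out sim/ --seed 7
fme fgmrna --expr sim/expression.tsv --cna sim/copy_number.tsv \
    --labels sim/labels.csv --out profiles.tsv
fme diffexpr --profiles profiles.tsv --labels sim/labels.csv --seed 7 --out ranks.tsv
fme run-discovery --config run.yaml        # or run-validation
```

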