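# metabograd

Inference pipeline for untargeted plasma metabolomics studies of pulmonary
hypertension: cross-batch preprocessing, discovery/replication differential
testing with confounder adjustment and comparator-group specificity tiers,
single-marker ROC evaluation, quantification of metabolic reversal after
pulmonary endarterectomy (PEA), and multi-site arteriovenous gradient
analysis with pathway enrichment and relevance networks.

It is written for analysts working with vendor-summarised semi-quantitative
metabolite panels (samples × metabolites intensity tables) from cohorts of
chronic thromboembolic pulmonary hypertension (CTEPH) patients, healthy
controls (HC), disease comparators (DC), chronic thromboembolic disease
without PH (CTED) and idiopathic/heritable PAH (IPAH/HPAH). Because such
patient-level data are rarely shareable, the package ships a first-class
synthetic-cohort generator with planted ground truth, so every stage of the
pipeline is exercised — and its error rates measured — against a known
answer key.

## The statistical cascade

For each metabolite *j* with healthy-control-referenced z-scores
(z = (y − μ̂_HC)/σ̂_HC after per-metabolite Box–Cox):

1. **Preprocessing** — missing cells imputed with the metabolite's minimum
   detected level; only non-xenobiotic metabolites detected in ≥ 95 % of
   samples retained; Box–Cox power λ_j chosen by profile likelihood on a
   grid λ ∈ [−2, 2]; quantile normalisation maps every sample's value
   distribution onto the mean order statistics to merge batches.
2. **Discovery/replication screen** — two-sided Mann–Whitney U in each
   cohort; a metabolite passes iff p < α/m in *both* cohorts with a
   consistent sign of the case–control difference. The AUC comes free:
   AUC = U/(n₁n₂).
3. **Confounder adjustment** — per-metabolite OLS
   z_j ~ group + age + sex + ethnicity + BMI + preserved-renal
   (creatinine < 75 µmol·L⁻¹) + preserved-liver (bilirubin < 21 µmol·L⁻¹)
   + drug classes; survivors require p_group < 0.05.
4. **Specificity tiers** — nested comparisons against DC, CTED and
   IPAH/HPAH classify each metabolite from `vs_HC_only` up to
   `vs_all_including_IPAH`.
5. **Surgery response** — unpaired pre- vs post-PEA screen (Bonferroni),
   paired Wilcoxon signed-rank validation, and the percent correction
   100·(med(z_pre) − med(z_post))/med(z_pre); hits whose direction
   disagrees between designs are flagged as probable false positives.
6. **Gradients** — paired Wilcoxon on within-subject differences along the
   flow direction SVC → PA → ART, Benjamini–Hochberg FDR within each site
   pair; Fisher's-exact subpathway enrichment over the detected background;
   relevance network linking metabolites with Spearman ρ > 0.9; Spearman
   correlations with clinical severity (mRAP, cardiac output, 6-min walk).

## Worked example

```bash
python examples/03_discovery_replication.py
```

```
Bonferroni bound at m=307: p < 1.63e-04
52 metabolites replicate across both cohorts
43 remain significant after confounder adjustment
median |disease effect| / |age effect|: 360x
recovery vs planted truth: 52/64 found, 0 false positives
```

Reading: at a detected panel of 307 metabolites the family-wise bound is
0.05/307; 52 metabolites clear it in both the discovery (108 CTEPH vs 58 HC)
and replication (92 vs 63) cohorts with concordant direction, and 43 of
them survive confounder adjustment. Against the generator's answer key the
cascade found 52 of 64 planted effects with no false positives — the
misses are the smallest planted perturbations (≈ 0.33–0.5 sd), which the
double-Bonferroni rule is deliberately too conservative to call.

The other examples cover the preprocessing chain, ROC marker evaluation
(`AUC 0.90 (0.86–0.94), sens 89% / spec 82%` for a 2-sd marker), the
two-stage surgery screen with percent-correction estimates, the tri-site
gradient analysis and the end-to-end pipeline
(`metabograd run --seed 1 --out dir/`, also available programmatically as
`run_pipeline`), which writes every table plus a manifest that makes the
run byte-for-byte reproducible.

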