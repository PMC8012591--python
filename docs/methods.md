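# Methods

## Scope and data model

The package analyses vendor-summarised untargeted plasma metabolomics
panels: a samples × metabolites matrix of non-negative semi-quantitative
intensities with missing values, a sample metadata table (group, cohort,
batch, pre/post-surgery pairing, anatomical site, covariates, clinical
severity variables) and a two-level pathway annotation
(subpathway → superpathway, with identity-confidence and xenobiotic
flags). Matrices carry a `scale_tag` recording their position on the
processing chain raw → imputed → boxcox → zscore → quantile_normalised;
operations check the tag, so out-of-order processing fails loudly rather
than silently producing nonsense.

## Preprocessing chain

* **Imputation.** Missingness in these panels is left-censoring at a
  per-metabolite limit of detection, so missing cells are imputed with the
  metabolite's minimum detected level. Metabolites with no detected value
  cannot be imputed and are dropped with a warning.
* **Detection filter.** Only non-xenobiotic metabolites detected in
  ≥ 95 % of samples (inclusive boundary) are retained. The pre-imputation
  detection mask is carried on the matrix so the filter gives identical
  results before or after imputation.
* **Box–Cox.** y = ((x+c)^λ − 1)/λ (ln(x+c) at λ = 0), λ per metabolite by
  maximum profile likelihood over the grid −2 to 2 in steps of 0.1; the
  shift c is 0 unless non-positive values exist, then 10⁻⁶ + |min|. The
  grid fit is computed vectorised over all metabolites and agrees with a
  dense scipy profile-likelihood scan (tested). Imputation precedes the
  transform so the transform sees a complete positive matrix.
* **z-scoring.** Per metabolite, z = (y − mean_ref)/sd_ref with the
  healthy-control group as reference; the reference subset then has mean 0
  and sd 1 exactly. In designs without healthy controls (the tri-site arm)
  the reference is all samples of the run — gradients are within-subject
  differences, so the choice only sets the reporting scale.
* **Quantile normalisation.** Each sample's values are replaced rank-wise
  by the mean order statistics over all samples; ties receive the mean of
  the reference values their ranks span (the convention that preserves the
  sample mean). Applied after z-scoring by default (order configurable);
  idempotent, and leaves every sample with an identical sorted value
  vector.

## Differential cascade

Group comparisons use the two-sided Mann–Whitney U test (rank tests because
power transforms do not remove all skew; results are then invariant to any
strictly monotone per-metabolite transform, which is tested as a property).
The p-value is exact when n₁·n₂ ≤ 400: via the exact null distribution
when the pooled values have no ties, and by full enumeration of the
⟨n₁+n₂ choose n₁⟩ group assignments when ties are present and the count is
≤ 3·10⁵; otherwise the tie-corrected normal approximation is used. The
two-sided exact p is the symmetric-tail mass P(|U′ − n₁n₂/2| ≥ |U − n₁n₂/2|).

The replication rule — Bonferroni α/m in discovery AND replication with a
shared direction of the mean difference — controls the family-wise error
far below α (the double screen is conservative; measured ≤ 5 % over 50
global-null studies at m = 300).

Confounder adjustment is per-metabolite OLS on the z-scores with the group
indicator, age, sex, ethnicity, BMI, binary preserved-renal
(creatinine < 75 µmol·L⁻¹) and preserved-liver (bilirubin < 21 µmol·L⁻¹)
indicators, and one indicator per drug class present in the metadata.
Healthy controls without assay values are assumed to have preserved
function. Missing covariates are handled complete-case with a logged
count; constant design columns are dropped; metabolites with fewer than 10
complete cases are skipped. The binary function indicators (rather than
continuous creatinine/bilirubin) follow the explicit clinical cut-offs;
this is a deliberate design choice.

Specificity tiers are nested: the healthy-control criterion (replicated
screen + adjusted p < 0.05) is the entry condition; DC, then CTED, then
IPAH/HPAH adjusted comparisons (p < 0.05 each) promote a metabolite one
tier at a time, so tier counts are monotone by construction.

## ROC evaluation

One curve per marker and comparator, one point per distinct threshold,
orientation auto-flipped so AUC ≥ 0.5 (flip recorded). The trapezoidal AUC
equals U/(n₁n₂) to machine precision (tested against a brute-force pair
count). The "best" cut-off maximises Youden's J = sens + spec − 1, ties
broken toward higher sensitivity — the standard single-marker choice,
made explicit because no criterion is canonical. The 95 % CI uses the
DeLong placement variance (deterministic, truncated to [0, 1]; empirical
coverage 95 % ± 3 under the null, tested at n = 200 per group); the
p-value against AUC = 0.5 is the Mann–Whitney p on the same data, since
the two statistics are the same object.

## Surgery-response screen

Stage 1 compares independent pre- and post-surgery groups per metabolite
(Mann–Whitney, Bonferroni over the tested panel). Stage 2 runs the paired
Wilcoxon signed-rank test on subjects sampled at both timepoints,
restricted to stage-1 hits, with a nominal p < 0.05 flag and a
Benjamini–Hochberg FDR < 0.05 flag computed over the stage-1 hits (the
multiple-test family for the paired analysis is a configurable choice; BH
over the validated set is the default). Zero differences are dropped
(classic Wilcoxon convention, count logged); the p-value is exact for
≤ 25 informative pairs without tied absolute differences, tie-corrected
normal otherwise.

Percent correction is 100·(med(z_pre) − med(z_post))/med(z_pre) on the
healthy-control z-scale, so 100 % is a full return to healthy levels.
Medians rather than means resist the skew these panels retain; the
statistic is reported clamped to [−100, 200] with the raw value logged,
and flagged undefined when |med(z_pre)| < 0.1 (no meaningful baseline
perturbation to correct). Hits whose direction of change differs between
the unpaired and paired designs are flagged inconsistent — the signature
of a false positive of the unpaired screen.

## Gradient analysis

Site pairs follow the flow direction SVC → PA → ART; gradients are
downstream − upstream, so the SVC_PA gradient is PA minus SVC and the
closing ART_SVC difference is SVC minus ART (the three mean differences
over the same complete-case subjects sum to zero exactly). Per metabolite
and pair, a paired Wilcoxon on within-subject differences; FDR is
controlled with Benjamini–Hochberg within each site pair across
metabolites (three families, matching per-gradient reporting); the effect
is the median paired difference in z-units. Pairs with fewer than 5
complete subjects are skipped.

Pathway enrichment is a two-sided Fisher's exact test per (site pair,
pathway) of significant × in-pathway over all detected metabolites, with
pathways under 4 detected members excluded; p-values agree with a
hypergeometric two-tail oracle (tested for backgrounds up to 200). The
relevance network connects significant-gradient metabolites with Spearman
ρ strictly above 0.9 on the signed correlation (an absolute-value option
exists); connected components are labelled. Clinical correlations are
Spearman ρ between metabolites and rank-normalised severity variables
(rank-based inverse normal — Spearman is invariant to it, so it only
standardises reporting scales).

## Synthetic cohorts and what they do (not) show

The generator plants every parameter the pipeline is asked to recover and
records it in a truth ledger. Intensities are log-normal: effects are
additive on the natural-log scale in units of each metabolite's log-sd
(multiplicative on intensities — the heavy-tailed positive structure that
motivates Box–Cox). Defaults mirror the main-study conditions:

* cohort sizes 58/63 HC, 108/92 CTEPH (discovery/replication), 132 DC,
  63 CTED, 433 IPAH; 64/82 unpaired and 43 paired surgery subjects; 86
  tri-site subjects (68 CTEPH + 18 IPAH);
* m = 375 metabolites in ~40 subpathways within 8 superpathways, with 6 %
  xenobiotics and 8 % poorly detected species so that ≈ 324 survive the
  detection filter;
* planted disease effects on 17 % of the panel, magnitudes +0.84–2.0 sd
  (upregulated) and −0.33–1.53 sd (downregulated); 80 % of effects shared
  with IPAH, few with DC/CTED — reproducing the observation that the PH
  comparator is metabolically similar and only a handful of metabolites
  are disease-specific;
* covariate interference calibrated by ratio: disease ≈ 75× the per-sd age
  effect and ≈ 2.35× the sex effect, on ~30 % of metabolites;
* batch shifts N(0, 0.2 sd) across 3 batches; left-censoring at a
  per-metabolite detection-limit quantile (0.5 %, or 15 % for the poorly
  detected);
* surgery corrections on 60 % of affected metabolites with fractions
  0.15–1.0, plus one metabolite planted with opposite shifts in the
  unpaired and paired designs (the false-positive scenario the
  direction-consistency flag exists for);
* site gradients of 0.2–0.45 sd on 55 % of the panel (the prevalence scale
  the three-site study reports), a subject random effect of 0.8 sd shared
  across a subject's three samples with 0.35 sd site-level noise, and a
  latent severity variable coupling affected metabolites (ρ ≈ 0.35) to
  mRAP, cardiac output and walk distance;
* eight "twin" pairs of structurally related species (isomers,
  co-regulated lipids) correlating at ρ ≈ 0.97 — the real-data feature
  that gives relevance networks their edges.

What passing recovery tests shows: the cascade's operating
characteristics — family-wise error ≤ 5 % under the null, ≥ 95 %
sensitivity at 1.5 sd effects with ≤ 1 false positive per study,
percent-correction bias within 10 points, ≥ 90 % gradient sensitivity at
0.2–0.45 sd — under the generative model above. What it does not show:
robustness to features the generator omits — chromatographic drift, adduct
and isotope artefacts, missingness that is not left-censoring, non-normal
covariate interactions, or annotation errors. Conclusions about real
cohorts inherit those caveats.

## Numerical choices and degenerate inputs

All-tied group comparisons return p = 1, AUC = 0.5. Wilcoxon with no
informative pairs returns p = 1. Zero-variance metabolites are dropped at
z-scoring with a warning; all-missing metabolites at imputation. BH
adjustment enforces monotonicity and adjusted ≥ raw. Enrichment excludes
pathways with fewer than `min_size` = 4 detected members. Empty
significant sets propagate as empty tables and empty networks without
error. Every simulation and generator accepts one integer seed;
identical config + seed reproduces all outputs byte-for-byte, which the
run manifest (config, versions, output hashes) makes checkable.

## Problem sizes used by the validation studies

Calibration and recovery studies run 50 replicate studies each at m = 300
metabolites with the cohort sizes above (recovery uses ~100 cases / 60
controls per cohort and fixed 1.5 sd effects); the paired-test uniformity
check uses 1000 simulated 40-pair studies. These sizes give the
binomial/KS assertions comfortable resolution while keeping the full suite
around a minute.

## Known limitations

Quantile normalisation is the only batch-correction offered (no
empirical-Bayes shrinkage). The unpaired surgery comparison reports no
covariate balancing (no propensity matching). Survival modelling,
metabolite identification and raw-spectra processing are out of scope.
The exact-p enumeration cap (3·10⁵ assignments) means heavily tied
mid-sized comparisons fall back to the tie-corrected normal approximation.
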