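# Methods

This note documents the statistical model behind `methbiotype`, the
defaults and why they were chosen, what the synthetic cohorts emulate, the
numerical conventions, and the known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Pipeline model and assumptions

**Inputs.** A normalized beta-value matrix (samples × CpG probes, values
in [0, 1]; normalization such as BMIQ is assumed to have happened
upstream), a probe annotation (gene symbol, region class), and a clinical
table with 34 declared symptom/function features plus declared covariates
(age, BMI, five blood-cell fractions, three ancestry PCs, smoking,
alcohol use, number of deployments) and a binary diagnosis. Missing beta
values are not supported; impute or drop upstream.

**Probe → region reduction.** Probes with sd < `sd_min` (0.05), mean
outside [`mean_lo`, `mean_hi`] = [0.01, 0.99], or without a gene symbol
are removed, then genes keeping fewer than two probes are dropped
("confident gene" rule). Within each confident gene a graph is built with
edges where pairwise Pearson r strictly exceeds `r_collapse` (0.8);
connected components are averaged into regions. Collapsing is scoped per
gene because the downstream units are genes; a `collapse_scope="global"`
flag exists for the alternative reading. Singleton components pass
through as one-probe regions so that no confident gene silently
disappears. When a recall (retest) matrix is supplied, regions whose
original-vs-recall correlation over the stable individuals falls below
`r_recall` (0.65) are removed; at least three stable samples are
required, and regions with undefined correlation are dropped.

**Association screen.** A region is clinically informative when its
maximum |Pearson r| over the 34 features strictly exceeds `r_clin` (0.2)
while its maximum |r| over every declared confounder stays at or below
`r_conf` (0.2; the confounder bound is not numerically specified by the
operating points the method is usually quoted with, so the symmetric 0.2
is a configurable choice). The screen — including the confounder
exclusion — is repeated `n_iter` (5000) times leaving `leave_out` (5)
samples out, and regions are ranked by pass frequency with ties broken by
full-sample max clinical |r| then region id; the top `top_k` (100)
regions proceed. One master seed spawns a substream per iteration, so
enlarging `n_iter` never reshuffles earlier iterations. Constant regions
or features contribute correlation 0.

**Composites.** The gene block is centered but not scaled (shared beta
units); the clinical block is z-scored (heterogeneous instruments). PCA
keeps 4 gene PCs and 6 clinical PCs — fixed counts, chosen to keep the
subject-to-feature ratio of a ~160–200-sample cohort near the
recommended ≥ 20 (a warning fires below that ratio). CCA on the PC
scores is computed by the classical QR + SVD algorithm; coefficients are
scaled so training variates have unit variance ("unstandardized"
canonical coefficients). The sequential Wilks' Λ statistic with
Bartlett's χ² approximation gates the number of supported pairs at
`wilks_alpha` = 1e-4; failing pairs are flagged but kept, since the
latent plane is two-dimensional by construction. CCA signs are arbitrary,
so each pair is flipped to correlate positively with a severity anchor
(the CAPS-like total) when available — this makes the first axis point
toward severity.

**Biotyping.** Two-class LDA with equal priors separates controls from
cases in the latent (x, y) plane: normal = Σ_pooled⁻¹(μ_control −
μ_case), boundary through the midpoint of the class means. The normal is
stored unit-norm (any positive rescaling preserves labels). With this
orientation the control mean scores positive and the control-distinct
case cluster negative, so cases with score < 0 are labeled G2 and the
rest G1 — a score of exactly 0 goes to G1 ("otherwise"). Because PCA,
CCA and LDA are all linear, the score collapses to a per-region weight
vector w = PCA_gene · CCA_gene · n_LDA applied to centered region values;
the package asserts the two paths agree to 1e-10. A `flip_sign` flag
exists because published axis conventions are occasionally mirrored.
Singular pooled covariances are ridge-regularized with a logged epsilon.
Cross-cohort application re-uses the discovery centering (no per-cohort
re-centering): that is the interpretation under which new cases can be
assigned from their weighted sums alone, and it requires the cohorts to
share the probe panel.

**Clinical contrasts.** Feature-by-feature OLS `feature ~ biotype + BMI +
age` with two-sided p-values and Benjamini–Hochberg FDR across features;
collinear covariates are dropped with a warning, constant features are
flagged degenerate with p = 1. Ternary coordinates locate each feature
relative to the three core symptom subcategories as normalized absolute
correlations.

**Differential methylation.** Per probe, OLS of beta on [intercept,
group indicator, covariates]; residual variances are moderated by the
standard empirical-Bayes hierarchical model: (d0, s0²) estimated by
method of moments on log s² (with the trigamma inverse solved by Newton
iterations), posterior variance s̃² = (d0·s0² + d·s²)/(d0 + d), moderated
t with d0 + d degrees of freedom. When the observed spread of log s² does
not exceed sampling, d0 = ∞ (complete shrinkage); when estimation fails
outright, the ordinary t is used with a warning, and `d0_override`
exposes both limits for verification. Betas are modeled directly because
the effect-size threshold is a beta difference; Δβ is the raw
case-minus-control mean (and median) difference, reported alongside the
adjusted statistic. A probe is a DMP when p < 0.01 and |Δβ| > 0.02; a
gene is a DMG when ≥ 1 member probe is a DMP, its direction that of the
member DMP with the largest |Δβ| (a "majority" mode was considered and
rejected as less interpretable when probes disagree in magnitude).
Enrichment is a one-sided hypergeometric test per gene set with a
direction score (n_hyper − n_hypo)/√n_overlap standing in for a
proprietary activation z-score — a functional substitute, not a
replication. Pathway dissimilarity is 1 − |Pᵢ∩Pⱼ|/max(|Pᵢ|,|Pⱼ|),
grouped by complete linkage (scipy's nearest-neighbor chain; exact merge
ties follow its deterministic order).

**Panel selection.** Candidates are relaxed DMPs (p < 0.1, |median Δβ| >
0.02, adjusted for cell composition and age) whose median difference has
a consistent non-zero sign in every validation cohort. The search draws
`subset_size` (10) probes uniformly without replacement `n_runs`
(100,000 at study scale) times, trains a linear SVM (C = 1, hinge loss,
features z-scored with training parameters, no class weighting) on the
training cohort, and retains a subset when the *unweighted mean* of the
per-validation-cohort AUCs exceeds `auc_keep` (0.8); probe frequency is
computed over retained subsets, ties broken by univariate training AUC
then id. The forward-AUC trajectory refits the panel at k = 1..K; the
default cutoff is the smallest k within `forward_tol` (0.005) of the
trajectory maximum and is deliberately overridable — panel size is a
judgment call. Collinearity pruning greedily drops the lower-ranked probe
of any pair with |r| > `prune_r` (0.8, mirroring the region-collapse
threshold). Biotype-aware refinement — a step whose exact published
procedure is not specified anywhere we could follow — is implemented as
greedy forward selection maximizing the mean of the per-biotype
validation AUCs (G1 vs all controls, G2 vs all controls), returning the
smallest greedy prefix within `forward_tol` of the best prefix
objective; that construction also guarantees the refined panel's
objective is within the tolerance of the full panel's. Evaluation
reports trapezoidal ROC AUC plus sensitivity/specificity at the Youden
point (argmax of sensitivity + specificity − 1), with per-biotype
contrasts keeping all controls.

## 2. The synthetic cohort generator

Real cohorts of this kind are access-restricted, so the package ships a
generator whose outputs carry exactly the statistical structure each
pipeline stage assumes. Defaults are desk-scale: 200 samples (100
control / 50 G1 / 50 G2), 1,500 genes with 1–6 probes each (~5,500
probes including 150 intergenic), mean beta shifts ±0.06 on 40 signal
genes per biotype.

**Beta model.** Per probe, a logit-normal draw around a per-gene baseline
(clinically coupled genes U[0.35, 0.65], null genes U[0.10, 0.90], probe
offsets N(0, 0.3) on the logit scale), with the total probe noise sd
0.25 on the logit scale (≈ 0.05–0.06 beta-scale sd for mid-range probes,
typical of variable array CpGs and just above the pipeline's own sd
filter) split into a shared per-(sample, gene) component and an
independent probe component so that within-gene correlation is 0.9.
Biotype shifts are added on the beta scale after squashing (so planted
mean differences are exactly the configured Δβ) and values are clipped
to [0.001, 0.999].

**Biotype structure.** The two programs are deliberately asymmetric,
which is both what the real phenomenon looks like and what makes the
method identifiable:

* G2 (control-distinct): +0.06 on its 40 genes, *severity-graded* — the
  per-sample shift scales with the individual's centered psychological
  factor (`severity_coupling` = 0.25) — and an opposite-direction shift
  of 0.5 × the G1 program on G1's genes (`cross_coupling_g2`).
* G1 (control-like): flat −0.06 on its own 40 genes and only a mild
  opposite trace (0.2, `cross_coupling_g1`) on the G2 program.

Two consequences follow. First, pooling all cases against controls
partially cancels both programs (the washout: the pooled contrast calls
strictly fewer DMGs than the G2 contrast). Second, on the clinically
selected regions — which are dominated by the severity-graded G2
program — G1 sits near the controls, which is the geometry the LDA
boundary needs. A symmetric coupling is provably unrecoverable: LDA on a
control-vs-case labeling is equivalent to regression on the class
indicator, which assigns both case clusters the same fitted projection,
so G1 and G2 land at identical discriminant values.

**Clinical model.** 34 features load (0.6–0.95, times
`clinical_loading`) on two latent factors with unit within-group sd:
"Psychological" with group means (0, 3, 4.5) — mirroring the by-design
severity gap between screened controls and diagnosed cases, with the
distinct biotype more severe — and "Physical and Dissociative" with
means (0, 0.5, 0.5): cases report more physical burden than controls but
the biotypes are mixed in that dimension. Quality-of-life features load
negatively. Feature noise sd is 0.6; cross-loadings ≤ 0.15. CAPS-like
and PCL-like totals are affine in the psychological factor.

**Physical methylation program.** 60 genes track a biological factor
that correlates 0.55 (`phys_methylation_fidelity`) with the reported
physical factor at logit loading 0.25. This gives the second canonical
pair a genuine gene–clinical correlate — exactly what the second
composite is in the real analysis — and the imperfect fidelity keeps its
canonical correlation below the severity pair's so the composite order
is stable. Without this program the second pair has nothing real to
find and latches onto the residual case/control contrast, distorting the
latent plane.

**Covariates and confounded genes.** Age, BMI, Dirichlet cell fractions,
ancestry PCs, smoking, alcohol and deployments are drawn independently
of the labels; age, neutrophil fraction and ancestry PC1 each shift a
disjoint subset of null genes (8%/10%/5% of genes at 0.15/0.4/0.2 logit
units per covariate sd), giving the confounder exclusion real work.

**Population structure vs cohort sampling.** A separate `structure_seed`
(default 0) fixes the gene/probe layout, baselines and all program gene
sets; the cohort `seed` draws the individuals. Two cohorts differing
only in `seed` are independent samples from one population — the setting
cross-cohort model transfer assumes. Identical config + seed reproduces
outputs bit-for-bit.

**Recall pairs.** The retest matrix mixes each probe's noise with a
fresh draw at autocorrelation `recall_corr` (0.95) while keeping fixed
effects; regions with group structure are therefore slightly *more*
reproducible than `recall_corr`, as real biology is. Genes flagged
unstable (`unstable_region_fraction`) are replaced by junk measurements
(baseline plus fresh noise, no planted biology), so their test-retest
correlation is ~0 and the stability filter removes them.

**What the generator does not emulate** — and hence what passing tests
do *not* establish about real data: raw IDAT intensities and probe
type I/II chemistry, batch/chip effects, cell-composition deconvolution
error, SNP-affected or cross-reactive probes, non-linear
methylation–age trajectories, missing values, and diagnostic exclusion
rules (real cohort Ns drift between analyses; the generator does not
model that). Effect sizes are planted, so recovery rates measure the
pipeline's correctness at the stated conditions, not expected power in
any real cohort.

## 3. Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1]; zero-variance columns contribute
  correlation 0 (screen) or drop the region (recall filter).
* CCA requires full-rank blocks and errors with a suggestion to reduce
  PCs; LDA ridge-regularizes a singular pooled covariance with a logged
  epsilon; a biotype score of exactly 0 is G1.
* The moderated-t prior fit falls back to the ordinary t when the
  variance dispersion is degenerate; d0 = ∞ is handled exactly (normal
  reference distribution).
* Filters use ddof = 1 standard deviations and inclusive mean bounds;
  the region-collapse edge rule is strict (r > threshold), so raising
  the threshold can only split regions (region count is monotone).
* All resampling uses `numpy.random.SeedSequence` substreams; rankings
  carry explicit deterministic tie-breaks (documented per function).
* Serialized models are plain JSON with explicit matrix shapes; every
  writer has a reader that round-trips it.

## 4. Problem sizes used by the tests and the acceptance script

The shipped experiments run at desk scale, chosen as the package's own
reference conditions: discovery cohorts of 200 samples × ~5,500 probes
with 500 leave-five-out screen iterations; null calibration on ~1,700
independent filtered probes at n = 60; the panel search at 1,000 runs
over 60 candidates across three cohorts. The full-scale operating points
(5,000 iterations, 100,000 runs, ~17,000 probes) are plain config
values — `PipelineConfig` and `PanelSearchConfig` default to them — and
scale linearly in time.

## 5. Known limitations

* The confounder screen uses marginal correlations; a confounder acting
  only jointly with another variable can slip through.
* The latent plane is fixed at two composites; cohorts with more planted
  factors would need `n_cca_pairs` raised and the Wilks gate consulted.
* With ~100 selected regions and ~200 subjects, CCA retains some
  in-sample optimism; canonical correlations reported on the discovery
  cohort are upper estimates, and regions selected by chance can tilt
  the latent axes. The cross-cohort transfer test is the meaningful
  check against this.
* The biotype-refinement objective is this package's explicit
  construction for an otherwise under-specified step; alternative
  objectives (e.g. worst-biotype AUC) are one-line changes.
* `compare_clinical_by_biotype` assumes roughly continuous features; for
  heavily discrete instruments an ordinal model would be preferable.
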