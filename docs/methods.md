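# Methods

This note documents the models implemented in `neuroreserve`, the choices
made where the published analysis left details open, and what the synthetic
validation does and does not establish.

## Scientific setting

Presymptomatic carriers of autosomal-dominant frontotemporal-dementia
mutations (*GRN*, *C9orf72*, *MAPT*) show measurable grey-matter loss years
before symptom onset. Two candidate modifiers of that loss are cognitive
reserve, proxied by years of formal education, and the common *TMEM106B*
rs1990622 C/T polymorphism. The analysis asks whether carrier status (GS),
education and T-allele count interact on a grey-matter composite, in a
multicentre family cohort where subjects are clustered both by pedigree and
by recruiting site.

## Grey-matter composite (gLPCA)

Regional volumes are first expressed as percent of total intracranial volume
(TIV), removing head-size differences, then column z-scored (sample sd,
n−1). Classical PCA of such data is dominated by whatever happens to have
the largest shared variance; grey-matter parcels, however, carry known
structure — strong left-right homologue correlation and spatial contiguity.
Graph-Laplacian PCA folds that structure in: with a skeleton graph over the
p = 27 measures and its combinatorial Laplacian `L = D − W`, the loadings
minimise the reconstruction error plus `α·tr(Q'LQ)`, which penalises
loadings that differ across connected measures. The solution is the
eigendecomposition of the normalised composite operator
`G_β = (1−β)(I − X'X/λ_data) + β·L/λ_graph`; the penalty weight implied by
the mixing parameter is `α = β·λ_data/((1−β)·λ_graph)`.

Choices:

* **Skeleton graph.** The original study's graph is in supplementary
  material we do not ship; the packaged template is a declared anatomical
  approximation: unit edges between all 13 left-right homologue pairs,
  within-hemisphere lobe adjacencies, subcortical adjacencies, one
  subcortical-to-cortical link per structure, and cerebellum-thalamus
  links (63 edges, connected). A data-driven alternative thresholds
  absolute Pearson correlations at `tau`. Any report should state the graph
  used; both constructions are exported as edge-list text.
* **Standardization.** Measures span three orders of magnitude (accumbens
  ~0.04% of TIV, frontal lobe ~6%); z-scoring makes the graph penalty
  commensurable across measures. Whether the original analysis scaled its
  inputs is not stated.
* **Mixing weight.** β = 0.5 by default, with a configurable sweep
  (`glpca.beta_sweep`) because the original β is not stated; the carrier
  effect's sign is stable across the sweep in the shipped tests.
* **Sign orientation.** Each loading column is flipped so its coefficient
  sum is ≥ 0; higher PC1 then reads as more grey matter, matching the
  interpretation of the published education/atrophy figures. Exact zero-sum
  ties fall back to a first-nonzero-positive rule; eigenvalue ties at the
  component cut (gap < 1e−10) trigger a warning and keep deterministic
  index order.
* **Scores.** PC1 scores are the raw projections `Xq₁` and are not
  rescaled; their scale depends on p and the data. Coefficients fitted on
  PC1 are therefore on the composite's own scale. Parameter recovery (below)
  is done on the generator's latent outcome, whose scale the truth
  coefficients are defined on.

## Mixed-effects interaction model

The composite is modelled with fixed effects GS, education, T-allele count,
all two-way products, the three-way product, age and sex (female = 1), and
two **crossed** random intercepts (pedigree, site) — crossed because the
model must not assume families attend a single site even though the
generator happens to assign one site per family.

* **Genotype coding.** T-allele count (CC=0, CT=1, TT=2). A single
  published coefficient for the genotype implies numeric coding, and with
  the published signs only the allele-count coding makes the carrier
  education slope steepest in TT with the dose ordering CC < CT < TT.
* **Centring.** Education and T-allele count enter centred at fixed
  constants (13.8 years; 1.268 = 2 × 0.634 pooled T frequency), and the
  constants travel with every fit so slopes are reported in raw units.
  Uncentred coding leaves GS nearly collinear with GS×Edu and GS×T, pushing
  the GS standard error an order of magnitude above the published 0.084 —
  the published SE ladder is only reproducible with main effects evaluated
  at a typical subject. Age is left in raw years.
* **Estimation.** Maximum likelihood on the marginal covariance
  `V = σ²I + σ²_ped Z_p Z_p' + σ²_site Z_s Z_s'`, with fixed effects
  profiled out by GLS and the three variances optimised by L-BFGS-B
  (deterministic start: random-intercept variances 0.1, residual at the OLS
  residual variance; variances bounded at 0). ML rather than REML matches
  reporting Wald z for every fixed effect; REML is available via a flag.
  The implementation is a direct dense-Cholesky fitter (p = 10 fixed
  effects, n in the hundreds, so a dense solve is exact and fast); the test
  suite cross-checks it against statsmodels' variance-components MixedLM
  (equal estimates where that optimizer converges, and a log-likelihood
  never below it) and against closed-form OLS when both variance components
  are generated at zero.
* **Inference.** Wald z = estimate/SE with normal two-sided p-values,
  matching a Z-value/P-value output table. Variance-component SEs are
  reported from the observed information of the profiled likelihood
  (central differences), NaN at the boundary; they are descriptive only.
* **Education slopes.** For genotype t and group gs, the slope of the
  composite in education is `β2 + β4·gs + (β6 + β7·gs)·(t − t_centre)`.
  The dose-monotonicity report evaluates t = 0, 1, 2 and classifies the
  ordering (increasing / decreasing / constant / non-monotonic).

## Synthetic cohort generator

The generator emulates the analysed cohort's structure: 77 families (size
1 + Poisson(2), mean 3), one gene and one recruiting site per family
(gene mix 33/29/15 GRN/C9orf72/MAPT over 13 sites), per-subject carrier
status Bernoulli(0.5) (autosomal-dominant risk), Hardy–Weinberg rs1990622
genotypes at T frequency 0.634, education ~ N(13.8, 3.2²) truncated to
[5, 25] and rounded to half-years, age ~ N(47.2, 13²) truncated to
[19, 86], 64% female, and independent MRI/genotype missingness at the
published enrolment rates (22/294 and 41/272).

The latent composite is the mixed model itself evaluated at configurable
truth parameters; the defaults are the published fixed-effect estimates and
random-intercept variances (pedigree 0.085, site 0.004). Two quantities are
not published and are set by declared convention:

* the intercept (0), and
* the residual variance, **0.227**, chosen by least-squares matching of the
  model's analytic fixed-effect standard errors (at the default cohort
  design) to the nine published SEs; all nine then agree within ~25%,
  so simulated replicates reproduce the published precision as well as the
  point estimates.

Region volumes scale allometrically with a log-normal TIV (reference
1.45 × 10⁶ mm³, sex offset e^0.05), so percent-of-TIV normalization exactly
removes head size: each region is `μ_j (1 + 0.01·w_j·g + η_j)` around
plausible per-region means, with default loading weights w = 3 for frontal,
parietal and temporal lobes and 1 elsewhere (these lobes are reported as
the composite's main contributors), fractional region noise sd 0.03, and
noise correlation 0.8 between left-right homologues (0 elsewhere).

What the generator does **not** emulate: within-pedigree genotype
transmission (genotypes are independent per subject, consistent with the
published independence of genotype from carrier status), realistic atrophy
topography, longitudinal change, or age-at-onset processes. Passing
recovery tests therefore show that the estimation machinery is unbiased
under the declared generative model — not that the pipeline would reproduce
the original fit on real data, which are not deposited.

## Parameter recovery and calibration

The recovery experiment simulates 50 replicate cohorts at the analysed
scale — missingness off, expected 231 subjects in 77 families across 13
sites, one seed per replicate — refits the ML model on the latent composite
of each, and compares mean estimates with the generating values; the shipped
acceptance test requires the carrier, education and three-way coefficients
and the pedigree variance to land within 3 Monte-Carlo SEs of truth.
Type-I calibration refits 100 null-effect cohorts (all β = 0, variance
components at defaults) and requires the pooled Wald |z| > 1.96 rate across
the nine non-intercept terms to stay within 3σ binomial bounds of 5%
([2.8%, 7.2%] at 900 draws). The OLS-equivalence check uses a cohort
generated with both variance components at zero, where the ML fit collapses
to the boundary and GLS reduces to OLS exactly.

Problem sizes throughout (50 recovery replicates, 100 calibration
replicates, ~231-subject cohorts, n = 2 000 for the homologue-correlation
and large-n variance checks) are the package's declared experiment scales;
they give Monte-Carlo SEs an order of magnitude below the effects under
test.

## Known limitations

* The template skeleton graph is an anatomical stand-in for the original
  (unavailable) supplementary graph; composite loadings depend on it.
* ML variance components carry the usual small-sample downward bias; at the
  default scale the pedigree-variance bias (~0.006 of 0.085) is within the
  recovery tolerance, but users fitting smaller cohorts should prefer the
  REML flag when variance components are of direct interest.
* Wald normal p-values are anti-conservative for the site component's few
  (13) clusters; this mirrors the reported analysis rather than improving
  on it.
* The neuropsychological ANCOVA z-scores of the original cohort table are
  out of scope (their covariate set is unspecified), as are per-gene
  stratified imaging analyses and any MRI preprocessing: the pipeline
  consumes precomputed regional volumes.
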