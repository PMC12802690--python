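# Methods

This note documents the statistical models implemented in `cortexmeth`,
their assumptions, the parameters that matter, the synthetic data used to
validate them, and the numerical choices made where the design was open.

## Per-site linear modelling

Each site's methylation proportion β ∈ [0, 1] is regressed on developmental
age (post-conception weeks prenatally, years postnatally) with ordinary
least squares, controlling for sex and experimental batch (treatment-coded
indicators). Missing values are handled as complete cases per site; sites
sharing a missingness pattern share one matrix factorisation. The age
coefficient's two-sided p comes from the t distribution at the residual
degrees of freedom, computed in log10 space so tails far below double
precision (p ≪ 1e-308) remain ordered and printable; the float `p` column
underflows to 0 beyond ~1e-323 while `log10_p` stays exact. A site is a
dDMP when p < 9×10⁻⁸, the experiment-wide threshold for EPIC-array
association studies. Effects are reported as percentage points per week
(proportion slope × 100).

Two-sided p-values are used throughout (standard EWAS practice); "t test"
comparisons between groups are Welch (unequal variance). The genome-wide
hypo/hyper direction test is a one-tailed exact binomial with p₀ = 0.5,
summed in log space over the tail; per-feature direction tests instead use
p₀ equal to the hypermethylated proportion among all dDMPs, with the tail
taken in the direction of departure.

The age × cell-fraction interaction model (age + fraction + age:fraction +
covariates) uses fixed effects only; per-fraction slopes are refit on each
fraction's samples so reported stratified effects are ordinary OLS slopes.
The cell-type mixed model adds a donor random intercept (REML estimates;
significance via a likelihood-ratio test between maximum-likelihood fits of
nested models). When the random-effect variance collapses to zero or the
fit fails, the site falls back to OLS with an OLS likelihood-ratio test and
is flagged (`fallback_ols`).

## Region calling

Candidate regions are maximal chains of dDMPs in which each *consecutive*
pair lies within 500 bp (so a chain may span more than 500 bp in total);
chains of ≥3 dDMPs are tested. The combined statistic is inverse-variance
meta-analysis under Σ = diag(se)·R·diag(se), with R the Pearson correlation
of per-site OLS residuals after full covariate adjustment and a 1e-6 ridge
on its diagonal (failure to factorise after the ridge is an error). With
R = I this reduces exactly to fixed-effect meta-analysis; with perfectly
correlated sites the combined SE approaches a single site's SE (no
precision gain). Direction consistency within a region is not required;
mixed-sign regions are reported with a flag. Bonferroni correction is over
the number of candidates, and regions with adjusted p < 0.05 are dDMRs.
Sub-region enumeration (testing every contiguous sub-window) is deliberately
not implemented; candidates are the maximal chains only.

## Pre-trajectory filters

Before GP fitting, (i) leave-one-out Z-score outliers (|Z| > 5, with the
leave-one-out SD floored at 1e-6 so identical values never divide by zero)
are set missing per site — the site is kept, matching the per-site language
of the filter; (ii) non-variable sites, whose middle-80% range — implemented
as the 10th-to-90th percentile span with linear interpolation — is strictly
below 0.05; and (iii) constant sites, with every sample strictly above 0.90
or strictly below 0.10, are excluded. All boundaries are strict
inequalities. Note that with symmetric contamination a gross outlier can
partially mask another (the leave-one-out SD is inflated by the remaining
outlier); this is inherent to the statistic, not a defect.

## Gaussian-process trajectory classification

Each site's mean-centred values are modelled as a zero-mean GP over age in
raw pcw units (no x standardisation, so the fitted Matérn lengthscale is
directly the "timescale" that the period conversion assumes). Three nested
models share bias and noise terms:

* constant: K = σ_b²J + σ_n²I
* linear: K = σ_b²J + σ_v²xx′ + σ_n²I (uncentred xx′ plus bias — a Bayesian
  line with free intercept after centring y)
* nonlinear: K = σ_b²J + σ_f²·Matérn5/2(|Δx|/ℓ) + σ_n²I

The log marginal likelihood L = −½yᵀK⁻¹y − ½log|K| − (n/2)log2π is computed
by Cholesky with a jitter ladder (0, 1e-10, 1e-8, 1e-6; −∞ beyond) and
maximised over log-hyperparameters by bounded L-BFGS with analytic
gradients: 5 restarts (one moment-based initialisation plus seeded
log-uniform draws), and the linear/Matérn fits additionally warm-started at
the constant model's optimum with the signal variance at its floor, so
nested likelihood ratios are non-negative up to optimiser tolerance (the
optimiser's start point is retained whenever a run terminates worse than it
began). Bounds: variances ∈ [1e-8, 10] on the proportion² scale, ℓ ∈
[0.5, 200] pcw. The linear-slope variance σ_v² gets a lower floor of 1e-12:
it multiplies xx′, whose entries reach ~500 pcw², so a 1e-8 floor would
leave the constant model unreachable by ~0.1 likelihood units and break the
nesting guarantee.

**Class assignment.** Constant vs linear is the argmax of L (ties within
1e-6 to the simpler model). The nonlinear class requires L_nl to exceed
*both* simpler optima by ≥2 likelihood units. This margin is deliberate:
type-II maximum likelihood over the Matérn's two extra hyperparameters
gains O(0–2) likelihood units on pure-noise sites by chasing empirical
autocorrelation at short lengthscales, so a bare argmax overcalls
nonlinearity on roughly half of null sites; the margin equals the LLR
threshold already used for refinement. High-confidence nonlinear sites
additionally need timescale ℓ ≥ 10 pcw (both bounds inclusive). The period
of one full oscillation is 2π√(3/5)·ℓ, so ℓ = 1 oscillates every ≈5 pcw.

**Known bias.** For planted sinusoids the ML lengthscale implies a period
about 1.9–2.3× the true sine period: the Matérn autocorrelation has no
negative lobes, and observation noise absorbs the zero-lag curvature that
would pin the exact period, so ML-II prefers the smoother fit.
Classification as nonlinear is unaffected; fitted periods should be read as
upper-bound smoothness scales, not literal oscillation periods.

## Co-methylation modules

Over the (typically nonlinear) site subset: signed adjacency
a_ij = ((1+cor)/2)^12 (Pearson, proportion scale), topological overlap
TOM_ij = (Σ_{u≠i,j} a_iu·a_uj + a_ij)/(min(k_i,k_j)+1−a_ij), average-linkage
hierarchical clustering of 1−TOM and a static height cut. By default the
cut height is chosen from the dendrogram itself: candidate heights between
successive merges are scanned and the one yielding the most clusters of at
least `min_module_size` (default 30) wins, ties going to the highest cut.
A fixed static height (the classic 0.995) can be passed explicitly, but on
strongly clustered data between-module TOM is far from zero and merge
heights fall well below 1, which makes any single fixed height fragile —
the scan is the package's replacement for dynamic tree cutting, which is
out of scope. Clusters below the minimum size are "unassigned" (the
grey-module equivalent) and excluded from eigengenes and hubs. Eigengenes
are the first PC of the standardised member matrix, sign-oriented to make
the mean member kME positive; hub sites maximise kME with deterministic
site-id tie-breaks. Cross-cohort comparison projects query samples into the
reference cohort's PC space using reference centring, scaling and loadings.

## Enrichment statistics

Feature/chromosome enrichment: per-category 2×2 tables (in/out of category
× dmp/non-dmp), Pearson chi-squared without continuity correction, log odds
ratios with a Haldane 0.5 correction when any cell is zero. Open-chromatin
enrichment: one joint logistic regression of dDMP status on the membership
indicators of *all* cell-type peak sets, so each coefficient controls for
every other cell type; identical or rank-deficient membership columns are
an error naming the sets, and complete separation falls back to a signed
infinite-effect sentinel with a Fisher-exact p. Gene-set enrichment is
gene-level logistic regression of "contains ≥1 dDMP" on set membership
controlling for gene size (number of annotated sites; multi-gene probes
count for every listed gene); the tiered variant restricts dDMP status to
the top-k most significant dDMPs and removes the remaining dDMPs from the
table entirely, keeping the non-dDMP background identical across bins.
"Corrected p" is Bonferroni throughout. Wald p-values for logistic effects
are two-sided.

## Deconvolution

Reference construction follows "any"-mode probe selection: per cell type,
one-vs-rest t statistics rank all sites and the top `num_probes` (default
100) by |t| — regardless of direction — are taken, with deterministic
site-id tie-breaks; the reference entry is the within-type mean. Bulk
proportions minimise ‖y − Xw‖₂ subject to w ≥ 0 (active-set NNLS; no
sum-to-one constraint — Σw is reported as a diagnostic). The CETYGO-style
score is the RMSE between the bulk profile and its reconstruction over the
reference sites: zero for exact mixtures, approximately the noise SD for
noisy ones, and strictly larger when the panel omits a cell type actually
present.

## Synthetic data

The generator emulates the study conditions: 91 donors by default, ages
uniform on 6–23 pcw, sex Bernoulli(0.5), 2–4 balanced batches. Site
trajectories are constant, linear (slopes drawn from ±{0.5, 1, 2, 4}
pp/week, the order of the strongest reported developmental effects) or
nonlinear (sigmoid / Gaussian bump / sine with amplitudes 0.1–0.25 and
inflections in mid-gestation), plus sex (0.5 pp) and batch (1 pp SD)
offsets. Noise is additive Gaussian on the proportion scale (default SD
0.03) with clipping to [0.001, 0.999] — not a beta distribution — because
the downstream models are linear-Gaussian and this keeps oracle math exact:
with zero noise every curve equals its specification. Class allocation is
deterministic (largest remainder), and `is_dmp` truth uses a design-time
power calculation for the per-site regression. Annotation places sites on
two synthetic chromosomes as a mixture of tight runs (gaps ≤150 bp, so
≥3-site region candidates exist) and isolated sites; peak membership is
Bernoulli with the odds multiplied by a configurable factor for true-DMP
sites, so the planted log-odds is exactly log(factor), realised as one
minimal interval per member site so interval overlap reproduces membership
exactly. Mixtures are Dirichlet-weighted combinations of reference profiles
plus noise.

What the generator does *not* emulate: beta-distributed (heteroscedastic)
measurement error, probe-level artefacts (cross-hybridisation, SNPs),
spatial correlation of noise along the genome, realistic linkage between
annotation categories, or cell-composition drift inside bulk trajectories.
Passing tests therefore demonstrate correctness of the estimators under
their own assumptions and calibrated error control under Gaussian noise,
not robustness to array-specific artefacts.

## Problem sizes and runtime

Validation uses desk-scale problems chosen to keep the full suite around
three minutes: the GP benchmark is 300 sites × 90 samples (100 per class,
linear slope 1 pp/week, sigmoid amplitude 0.2 / width 3 pcw, noise SD
0.03); the null family-wise-error study of region calling runs 200
replicates of 8 clustered sites × 30 samples; type-I calibration of the
per-site model uses 1,000 permuted-age null sites; deconvolution recovery
uses 100 Dirichlet mixtures over a 4-type panel. Larger inputs are
generated programmatically rather than stored.

## Known limitations

* The GP fitted period overstates true oscillation periods ~2× (above).
* The static-cut module detector does not merge highly correlated modules
  and has no notion of intramodular connectivity beyond kME.
* The mixed model fits one site at a time and is the slowest per-site path;
  it is intended for targeted follow-up rather than array-wide scans.
* p-values below ~1e-323 print as 0 in the float column; use `log10_p`.
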