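# Methods

This note documents the models, numerical choices and limitations of
`netstage` — what each stage computes, which knobs matter, and what the
synthetic cohorts do and do not emulate.

## Seed definition

Per modality, the subjects × voxels matrix is residualised against age,
gender, education and APOE ε4 (OLS with intercept; rank-deficient
designs are rejected naming the collinear columns).  The observed
statistic is the pooled-variance two-sample t (one-sided, CN > dementia)
on the residuals; the null permutes group labels over the residualised
subjects (a Freedman–Lane-style scheme: nuisance effects are removed
once, then exchangeability is assumed on the residuals).

**TFCE.**  The enhanced value of voxel v is the Riemann sum
`Σ_h extent(cluster_h(v))^E · h^H · dh` over heights `h = dh, 2dh, … ≤
max`, with clusters by face (6-)connectivity and supra-threshold
membership `stat ≥ h`.  Defaults `E = 0.5`, `H = 2`, `dh = max/100` are
the published FSL defaults; the method itself only fixes E and H
conceptually.  Negative values never contribute (one-sided use).
Family-wise error uses the max-TFCE permutation null, so
`p ≥ 1/(n_perm+1)` and an isolated test at α = 0.05 needs
`n_perm ≥ 19`.

**Seeds.**  The two thresholded t maps are summed; within each expected
region's spherical search neighbourhood (default radius 12 mm, supplied
by the caller — on real data this encodes the anatomical prior used to
pick network key regions) the maximum of the summed map becomes the seed
centre, and the seed is the set of voxels whose centres lie within 4 mm.
A region with no surviving voxel is reported absent, never fabricated.
Coordinates are world mm via the NIfTI affine; voxel indices 0-based.

## Seed PLS

Columns of the seed vector Y and the voxel matrix X are centred and
scaled to unit Euclidean norm, so `R = YᵀX` holds exact Pearson
correlations ("centred and normalised" admits several conventions; unit
norm is fixed here because it makes R interpretable and the rank-1 path
analytic).  Constant voxel columns map to r = 0 with a logged count.
For a single seed the SVD is the closed form `u = Rᵀ/‖R‖`, `s = ‖R‖`,
which the implementation reproduces to machine precision through the
general SVD path (sign fixed by a non-negative seed salience).  The
permutation test permutes the subject order of Y relative to X with the
singular value as statistic (the method description names no statistic;
the singular value is the natural energy measure).  Bootstrap ratios
resample subjects with replacement, sign-align every bootstrap salience
to the original (flip when its inner product with u is negative — the
standard guard against reflection inflating the SE) and divide u by the
elementwise bootstrap SD.  Degenerate resamples with constant seed
values are redrawn and counted.

Network scores are `L_X = X·u` per seed and modality; left/right
homologous seeds (HIP, ANG, INS, PPC, DLPFC) are averaged **on the raw
projections, before z-scoring** — z-of-average keeps a single
interpretable scale, and the alternative order changes only a scalar
factor per column.  z-scoring uses the sample SD over the reference
group (all subjects by default; a CN-only reference is available as the
robustness variant).

## Staging

Diagnosis from scores (helper only; a provided diagnosis column always
takes precedence): CN iff MMSE ≥ 24 and CDR 0; MCI iff MMSE ≥ 24 and
CDR 0.5; probable dementia iff MMSE ≤ 26 and CDR ≥ 0.5.  The overlap
(MMSE 24–26 with CDR 0.5) resolves to MCI because the dementia label
additionally requires clinical criteria a score rule cannot reproduce;
unmatched combinations return "unclassifiable" rather than a default.

CSF strata use strict inequalities (Aβ < 192 pg/mL → amyloid positive;
else p-tau > 23 pg/mL → tau positive; else negative), with amyloid
positives analysed as one group regardless of tau.

Ordering is a total order: stage (CN → MCI → dementia; the "merged"
strategy pools MCI and dementia), then MMSE descending within CN,
CDR-SOB ascending within the later stages, then age ascending, then id
(the final tie-break makes the order fully deterministic).  Binning
partitions the order into `K = ceil(n/bin_size)` contiguous bins with
sizes differing by at most one, remainder spread over the leading bins —
the source protocol assumed divisibility by 10 and left the remainder
case open.

## Sparse varying-coefficient model

With subjects assigned to bins `t_k` (k = 1..K), the model is
`y_i = Σ_j β_j(t_(i)) x_ij + ε_i` with `β_j(t) = Σ_m γ_jm B_m(t)` in a
clamped cubic B-spline basis (default M = 6 basis functions; open-uniform
knots over [1, K]; partition of unity holds exactly).  Response and
predictors are z-scored within pathology group (sample SD), so no
intercept is fitted.  The objective is

    (1/2n) Σ_i [y_i − Σ_j β_j(t_i) x_ij]² + λ · Pen

with `Pen = Σ_j √(γ_jᵀ Ω γ_j)` (group lasso) or `Σ_j γ_jᵀ Ω γ_j`
(ridge), where `Ω = BᵀB/K` is the bin-sum quadrature of `∫β_j²` — the
natural discretisation given that the model is only ever evaluated at
the bins.  The printed form of the source objective is quadratic in β,
but the described estimator performs variable selection, which a
quadratic penalty cannot do; the group norm is therefore the default and
the pure quadratic ships as the "ridge" variant used for the robustness
comparison.

**Solver.**  Substituting `g_j = Ω^{1/2} γ_j` gives a standard group
lasso.  It is solved by block coordinate descent over working sets with
KKT screening: each block update is the *exact* minimiser of
`(1/2)gᵀAg − bᵀg + λ‖g‖` obtained from the eigendecomposition of the
group Gram A and Newton iteration on the secular equation
`Σ_i β_i²/(d_i t + λ)² = 1` (monotone from a provable lower bound);
zero groups are touched only through the screening pass
`‖Z_jᵀr/n‖ ≤ λ`.  Every update is an exact minimisation, so the
objective is monotone non-increasing.  Convergence requires a relative
objective decrease below `tol = 1e-6` *and* the KKT conditions: no dual
violation on zero groups and stationarity residual ≤ 1e-5 on active
groups (CV path fits relax the stationarity tolerance to 1e-3, since
they only feed the held-out error).  `λ_max`, the smallest λ zeroing
everything, comes from the same dual bound.

**λ selection.**  The grid is 50 log-spaced points from `λ_max` down to
`10⁻³·λ_max`, truncated where the training R² exceeds 0.999 (the glmnet
deviance-ratio convention): far below the noise scale the residual is
pure shrinkage bias and spurious groups start absorbing it, which is a
degenerate regime for model selection and a no-op on noisy data.
Fivefold CV is stratified by bin with warm starts along the descending
path.  `cv_lambda` returns the error-minimising λ by default (ties to
the larger λ); the repetition protocol uses the **one-standard-error
rule**.  The reason is structural: repetitions share one dataset and
differ only in fold assignment, so a chance predictor–noise correlation
lowers the held-out error in *every* fold and the error-minimising λ
admits such predictors in essentially every repetition — the >90/100
consistency rule cannot screen them.  The 1-SE rule is the standard
remedy and restores the intended behaviour (planted predictors kept,
null predictors excluded); `lambda_rule="min"` is available.

**Repetitions and specificity.**  100 repetitions differ only in the CV
fold seed (`base_seed + r`); predictors selected in more than 90
repetitions are kept.  Reported curves are the mean over all
repetitions with a band of ±2·SE, where SE is the *standard deviation*
of the per-repetition curves — repetitions are not independent data
draws, so dividing by √100 would understate the estimator variability
the band is meant to display.  Specificity permutes the response across
participants and reruns the whole protocol per permuted dataset; with no
real signal the selection frequencies should look random.  Nuisance
predictors (gender, education, APOE ε4, ICV, scan site) enter the model
exactly like network scores, as penalised varying-coefficient groups;
site is effect-coded.

## Synthetic cohorts

The generator emulates the study conditions: a 3 (stage) × 3 (pathology)
design with `n_per_cell` subjects per cell; a 24³ voxel grid at 4 mm
with seven networks planted as isotropic Gaussian blobs (σ = 6 mm, unit
peak) at 12 loci — bilateral HIP, ANG, INS, DLPFC, PPC and midline PCC,
mPFC, pairwise ≥ 20 mm apart so 4 mm seeds are disjoint.  Subject maps
are `baseline + Σ_j l_ij·pattern_j + site offset + iid noise` with
loadings `l_ij ~ N(μ_stage, loading_sd²)`, stage means 0.5/0.0/−0.5
(CN/MCI/AD) by default — a monotone decline of network integrity of
about one loading-SD across the full range, qualitatively matching the
observed group differences; voxel noise SD 0.5 (≈ half the planted peak
contrast); three scan sites with additive voxel offsets of SD 0.1 so
nuisance regression has something to remove.  CSF values are drawn
strictly inside/outside the cutoffs (e.g. amyloid positive uniform on
100–180 pg/mL) so reclassification is exact by construction.  Memory is
generated per pathology group from the within-group z-scored loadings
with per-bin true coefficients (default: HIP structural declining
0.8 → 0.2, all else null) plus N(0, 0.5²) noise — roughly half the
response variance is signal, a deliberately favourable but not
degenerate brain–behaviour coupling.

What the generator does **not** emulate: anatomy, registration error,
partial-volume effects, spatially correlated noise, longitudinal change,
missing data, or realistic inter-network correlation beyond the shared
stage structure.  Passing tests therefore demonstrate the correctness
and calibration of the machinery under known truth — not effect sizes,
power, or robustness properties of any real cohort.

## Problem sizes used in the test suite

Statistical checks run at sizes chosen to keep Monte-Carlo error small
relative to their tolerance bands: calibration of the permutation tests
uses 250–500 null replicates at 199 permutations each; the
coefficient-recovery check uses one pathology group of n = 300 over 30
bins with 100 repetitions on a 15-point λ grid; specificity uses 20
permuted datasets × 20 repetitions; seed-definition counts use 30
subjects per group with 200–1000 permutations.

## Known limitations

- The permutation contrast assumes exchangeability of residualised
  subjects; variance smoothing and cluster-mass alternatives are out of
  scope, as is exact replication of FSL binaries.
- Only the leading latent variable per seed is carried forward;
  multi-seed (block) PLS is out of scope.
- No pointwise inference on coefficient curves (the ±2·SE band is a
  stability summary, not a confidence band).
- The diagnosis helper cannot reproduce clinical judgement in the
  MMSE 24–26 / CDR 0.5 overlap and defers to a provided diagnosis
  column.
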