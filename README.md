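# netstage

Individual-level brain covariance networks and their stage-varying
association with memory across the Alzheimer's disease continuum.

## The problem

Grey-matter atrophy and glucose hypometabolism in Alzheimer's disease do
not affect isolated voxels: they follow large-scale covariance networks
anchored at regions such as the hippocampus and the default-mode hubs.
How strongly an *individual* expresses such a network — and how strongly
that expression relates to memory — plausibly changes along the disease
course and differs between people with and without amyloid/tau
pathology.  `netstage` implements the full analysis path for this
question on cross-sectional cohorts:

1. **Seed definition** — nuisance-adjusted permutation group contrast
   (CN > dementia) per modality, TFCE enhancement with family-wise-error
   control via the max-statistic null, summation of the thresholded t
   maps, and 4 mm spherical seeds at the regional peaks.
2. **Seed PLS** — for each seed and modality, the correlation vector
   between the seed signal `Y` and all brain voxels `X` (columns centred
   and scaled to unit norm) is `R = Yᵀ·X`; its SVD `R = v·s·uᵀ` yields
   the network salience `u` (for a single seed, `u = Rᵀ/‖R‖`,
   `s = ‖R‖`).  Latent variables are tested with 1000 permutations,
   voxel reliability with bootstrap ratios (500 resamples), and
   individual network scores are the projections `L_X = X·u`, averaged
   over left/right homologues and z-scored — 14 scores per participant
   (7 regions × 2 modalities).
3. **Staging** — CSF stratification (amyloid positive at
   Aβ₁₋₄₂ < 192 pg/mL, tau positive at p-tau₁₈₁ > 23 pg/mL, A+T−/A+T+
   merged), deterministic severity ordering (CN by MMSE descending,
   MCI/dementia by CDR-SOB ascending, ties by age then id) and
   near-even binning (10 subjects/bin).
4. **Group statistics** — permutation one-way ANOVA (5000 permutations)
   on nuisance-residualised scores, pairwise permutation t-tests with
   Bonferroni–Holm correction.
5. **SVC modelling** — the sparse varying-coefficient regression

   `y_i(t_k) = Σ_j β_j(t_k)·x_ij + ε_i(t_k)`

   with each `β_j(t)` expanded in a cubic B-spline basis and estimated by
   minimising `(1/2n)·Σ_i [y_i − Σ_j β_j(t_i)x_ij]² + λ·Σ_j √(γ_jᵀΩγ_j)`
   (group lasso over spline-coefficient groups; a ridge variant uses the
   quadratic penalty `Σ_j γ_jᵀΩγ_j`).  λ is tuned by fivefold CV, the fit
   is repeated 100 times over CV randomisations, predictors selected in
   >90 repetitions are kept, and specificity is checked on
   response-permuted datasets.

A first-class synthetic-cohort generator (`netstage.simulate`) plants
known covariance networks and a known stage-varying memory coefficient,
so every stage is testable end to end without any data download.

## Worked example

`examples/05_svc_trajectories.py` generates a cohort whose
amyloid-pathology group (n = 300, 30 bins) has a hippocampal structural
coefficient declining from 0.8 to 0.2, fits the SVC protocol with 25
repetitions, and prints:

```
30 bins, 19 predictors, 25 repetitions

selection frequencies (nonzero only):
HIP_GMV    25

kept (frequency > 22/25): ['HIP_GMV']

recovered HIP_GMV coefficient curve vs planted truth:
 bin  recovered  truth
   1       0.71   0.80
   7       0.64   0.68
  13       0.47   0.55
  19       0.46   0.43
  25       0.45   0.30
curve-truth correlation: 0.917
```

Only the planted predictor survives the consistency rule; its recovered
coefficient curve declines across the severity bins as planted — the
early-stage dominance of hippocampal network integrity on memory.  The
other examples cover cohort simulation, seed definition, network
scoring, group comparisons and the one-command pipeline
(`netstage run-all --demo`).

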