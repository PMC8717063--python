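# Methods

## Task design model

A session is six runs — two feature-based JA (fJA), two spatial JA
(sJA), two solo control — in a seeded counterbalanced order.  Each run
holds 32 contiguous trials of 12.5 s (phases: fixation 2.5 s, role
assignment 2.5 s, cue–response 2.5 s, fixation 2.5 s, verify 2.5 s)
without inter-trial jitter, so trial *k* starts at `lead_in + 12.5 k`
seconds.  Role sequences in JA runs are pseudo-random permutations with
an exact 16/16 initiator/responder split per participant; partner roles
are complementary by construction (fIJA↔fRJA, sIJA↔sRJA, controls map to
themselves).  Control runs alternate blocks of the feature and spatial
solo tasks; the default is eight blocks of four trials, fCTRL first,
which preserves the 16/16 split while honoring the alternating
structure (the block size is configurable).

32 trials × 12.5 s = 400 s of task occupies 160 of the 175 volumes
acquired at TR 2.5 s; the remainder is split into a 10 s lead-in and
trailing rest.  The exact padding is a free parameter of the generator
(the analyses are insensitive to it as long as all events fit in the
run).

## Forward model

Per voxel and run:

    y(t) = Σ_i a_i · h(t; onset_i, 5 s) + verify term + drift + noise

where `h` is the 5 s boxcar at the role-phase onset convolved with the
canonical double-gamma HRF (delays 6/16 s, unit dispersions, undershoot
ratio 1/6, unit peak; peak latency ≈ 5 s).  Trial amplitudes are
`a = amp_mean + amp_sd · e` with standard-normal `e` per voxel and
trial.  In JA runs, voxels of the task-coupling mask share a common
component between partners: `e = √c·s + √(1−c)·ε` with `s` identical for
both members, so the inter-partner amplitude correlation equals
`coupling_task = c`.  The verify phase contributes a fixed-amplitude
response (default 0.5), giving the no-interest regressor something real
to absorb.

Noise is stationary AR(1) (default φ = 0.3, marginal sd 1.0, 30-sample
burn-in).  In JA runs, residual-mask voxels mix in a shared smooth
latent — Gaussian noise low-pass filtered at 0.1 Hz (4th-order
Butterworth, zero-phase), standardized, carrying a fraction
`coupling_residual` of the background variance — emulating coherent
"resting-state-like" fluctuation between partners.  Drift is a sum of
up to three slow cosines with random per-voxel coefficients; component
periods are constrained to ≥ 160 s so the injected drift always lies
inside the 128 s high-pass stop band regardless of run length.
Control runs receive no shared component of either kind.

All randomness flows from one seed through `SeedSequence([seed,
run_index, stream])` splitting, making every run bit-reproducible and
the two participants' streams independently addressable.

Defaults (`amp_sd = 0.5`, `noise_sd = 1.0`, `verify_amp = 0.5`,
`drift_amp = 1.0`) put single-trial amplitude estimates at a
signal-to-noise where trial betas correlate ≈ 0.9 with the generating
amplitudes — comfortably detectable at the cohort level yet far from
noise-free, which is the regime the analyses are designed for.

What the generator does *not* emulate: spatial autocorrelation of noise,
motion and physiological artifacts, scanner drift nonstationarity,
hemodynamic variability across voxels/subjects, and behavioral errors.
Passing tests therefore certify the statistical machinery (estimation,
enumeration, calibration, recovery), not robustness to real-data
artifacts.

## First-level GLM

Designs come in two flavors: a session-wise condition design (six
interest regressors spanning the runs, one verify covariate, one
intercept per run) and a per-run trial-wise design (32 trial regressors
+ verify + intercept).  Events are 5 s boxcars at the role-phase onset,
convolved with the HRF on a 10× oversampled grid and sampled at the
volume acquisition times; a design with an all-zero interest column is
rejected.

High-pass filtering residualizes data *and* design against the
orthonormal DCT-II basis with periods ≥ 128 s (constant + ⌊2·N·TR/128⌋
cosines; 7 columns for N = 175, TR = 2.5).  Filtering-as-projection is
algebraically identical to appending the DCT block as nuisance
regressors (tested).  Columns annihilated by the filter (intercepts)
are dropped from estimation, which is why a trial-wise run yields
exactly 33 estimable betas.

Serial correlation: a single AR(1) coefficient is estimated by
restricted maximum likelihood, pooling voxels that pass an omnibus
F-test of the interest regressors at p < 0.001 in a first-pass OLS fit
(falling back to the top-F voxels when fewer than 20 pass; the pool is
subsampled to a few hundred voxels, which is far more than needed for a
single scalar).  The REML criterion uses the design augmented with the
DCT block so the filter's degrees of freedom enter exactly, and
profiles a common noise variance across pooled voxels.  Whitening is
the exact Cholesky factor of the inverse AR(1) correlation matrix
(first row scaled, then lagged differences), applied per run; whitened
OLS equals explicit GLS (tested against the dense inverse).  Runs are
fit independently with per-run intercepts, matching the per-run logic
of the beta-series reordering; the condition design concatenates runs
but filters and whitens per run.  Setting `whiten="none"` skips
estimation and whitening entirely — the residual analysis requires the
autocorrelation structure to be preserved.  Zero-variance voxels get
zero betas and are flagged and excluded from pooling.  No global
scaling anywhere.

## Inter-brain correlation

Beta series: trial betas of the four JA runs in canonical order (fJA
runs in session order, then sJA runs), no-interest beta dropped,
4 × 32 = 128 entries per voxel.  "Same coordinates" means identical
voxel indices on the shared grid — no homotopic flipping.  Beta series
are not re-standardized per run by default (betas are already per-trial
amplitudes); an optional per-run z-scoring flag exists.

Pseudo pairs: each real pair contributes its role-sequence-A member and
its B member; every A(i)–B(j) combination with i ≠ j is a pseudo pair,
enumerated deterministically (i-major).  Complementarity of role labels
is enforced so trial order aligns across pseudo members.  The full
enumeration (not a subsample) is used.

Correlation maps: voxelwise Pearson r, Fisher z = atanh(r) with
|r| clipped at 1 − 1e-7.  Residual series are demeaned per run,
correlated per run, and the z values averaged within condition type (JA
or control); per-run correlation avoids spurious covariance from run
boundaries that concatenation would create.  The Fisher transform is
applied to both analysis types (a flag can disable it).  The cohort
path computes all P² member combinations with batched per-voxel matrix
products; it is tested to agree with the reference per-pair routine to
float32 precision.

## Group inference

Contrast maps feed a voxelwise one-sample t (df = n−1); real-vs-pseudo
z-maps feed a Welch t with Satterthwaite degrees of freedom (the two
groups have very different sizes and variances; pseudo-pair maps are
also not strictly independent since participants recur across pseudo
pairs — the test treats them as independent, as the resampling design
intends, and the permutation correction operates on the same statistic).

Cluster correction: voxels with one-sided p below the height threshold
(default 0.001; per-voxel t quantile at the map's df) form 26-connected
clusters.  The family-wise corrected p of a cluster is the fraction of
permutations — sign flips for one-sample, group-label shuffles for
two-sample, the observed labeling always included — whose *maximum*
cluster size is at least the observed size; the smallest attainable p
is 1/n_perm, and fewer than 10 distinct permutations is refused.
Permutation is the default method: it is exact under exchangeability
and behaves on tiny grids, where random-field theory's smoothness
estimates are unreliable.  An RFT mode (Gaussian-field expected
cluster-size approximation with smoothness estimated from standardized
unit-map gradients) is provided for users wanting the parametric
convention; it is validated only for sanity (p ∈ [0,1], monotone in
cluster size), not against the permutation answer.

Conjunctions use the minimum-statistic-over-thresholded-maps rule: a
voxel passes iff every component map individually exceeds its height
threshold.  The predefined contrast table covers the four
task-vs-control contrasts, the four spatial/feature differentials, the
role contrast (initiator > responder across both tasks), and the main
effect of JA (1,1,1,1,−2,−2 over fIJA, fRJA, sIJA, sRJA, fCTRL, sCTRL);
spatial- and feature-specific JA are conjunctions of the corresponding
four rows.

## Pipeline and reproducibility

`PipelineConfig` is a flat, strictly validated mapping (unknown keys
rejected); a master seed feeds every stochastic stage through
deterministic sub-seed derivation, so a config fully determines all
outputs — manifests record SHA-256 hashes of every artifact, and
re-running an identical config reproduces identical hashes.  Maps are
stored as float32 NIfTI; internal computation uses float64 except the
large-cohort simulation/fitting path, which runs in float32 for memory
and speed (the float32/float64 agreement is covered by the
equivalence tests).  Reports are written as CSV plus Markdown.

## Problem sizes used in the validation suite

Unit tests run on scaled-down geometry (8–12³ grids, 8–16 trials/run,
48–96 volumes).  The calibration checks use 2000 simulated voxels for
the Welch type-I rate and 200 null cohorts (12³ grid, 22 maps, 200
permutations) for the family-wise cluster rate.  Ground-truth recovery
runs full-scale cohorts — 22 pairs, 24³ voxel grid at 3 mm, 175 volumes,
coupling 0.6/0.5 in disjoint 50-voxel masks — over 10 seeds in the test
suite and 3 seeds in the acceptance script, with 200 permutations per
cluster test; these sizes give stable rates while keeping a full
validation run in the minutes range on a single core.

## Known limitations

- The residual-coupling latent also leaks into trial-beta noise (a
  shared smooth background inevitably correlates partners' beta
  estimates), so strong residual coupling can produce a secondary
  beta-series cluster in the residual mask.  This is a property of the
  forward model, not an analysis error; the recovery criterion is that
  each analysis finds its own mask.
- The pseudo-pair dependence structure (each participant appears in
  2(P−1) pseudo pairs) is replicated, not corrected for; exact
  dependence-respecting inference is out of scope.
- RFT mode is an approximation intended for large smooth grids and is
  not validated against permutation p-values.
- The generator's noise is spatially white; cluster-extent calibration
  on real (spatially smooth) data would differ.
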