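# Methods

## Scope and data model

`spineprint` operates on parcelled two-run resting-state fMRI: per subject
and run, an `N × T` matrix of region time series with sampling interval TR.
Region order is fixed by a `ParcellationScheme` and is identical across all
matrices, vectors and maps. Two schemes are built in:

* **Spinal**: 14 cross-section regions per cervical level, in the canonical
  order `dh_L, dh_R, iz_L, iz_R, vh_L, vh_R, sl_L, sl_R, cst_L, cst_R,
  fc_L, fc_R, fg_L, fg_R` (gray-matter block then white-matter block, left
  before right), levels rostral→caudal. Three, five and seven levels give
  42, 70 and 98 regions. The within-level label order is a package
  convention — figure-style "alternating left/right" descriptions are
  ambiguous at label granularity, so one deterministic order is declared
  canonical and used everywhere.
* **Brain**: 100 cortical regions sorted by the seven resting-state
  networks (VIS, SM, DA, VA, L, FP, DMN), left hemisphere before right
  within each network, plus 19 subcortical regions (SUB) last → 119.

Image-domain preprocessing (motion correction, segmentation, registration)
is out of scope; the package starts from time series (optionally toy
voxel-level blocks with region labels).

## Denoising

**Physiological regressors.** Cardiac phase ramps linearly from 0 to 2π
between consecutive heartbeat peaks (samples outside the peak span reuse
the nearest interval periodically). Respiratory phase is Glover-style:
magnitude = empirical cumulative fraction of the amplitude histogram × π,
sign from the smoothed temporal derivative, range (−π, π]. The RETROICOR
design expands both phases in sines/cosines up to chosen orders plus
sum/difference interaction terms; the column count is
`2·c + 2·r + 4·i²`, so the standard orders (4, 4, 2) give 32 regressors.
Interaction terms are defined as `sin/cos(m_c·φ_c ± m_r·φ_r)` — the
alternative (elementwise products of the basis columns) yields a different
count and is not used. A CSF regressor averages the `ceil(f·V)` most
temporally variable CSF voxels (default f = 0.10).

**Cleaning as one projection.** The 0.01–0.13 Hz band-pass is realized as a
projection: a DCT-II basis restricted to frequencies *outside* the pass
band (atom k has frequency `k/(2·T·TR)`) is concatenated with the confound
columns and an intercept, and the joint least-squares fit is removed in a
single step. This guarantees (i) residuals exactly orthogonal to every
confound column, (ii) idempotence, and (iii) that the filter cannot
reintroduce variance removed by the confound regression (the known artifact
of sequential filtering and regression). Rank-deficient confound matrices
are handled by the minimum-norm solution. Out-of-band attenuation is exact
for signals in the stop-band span; a finite-length tone whose frequency
falls between DCT grid points retains a small leakage component inside the
pass band (order 10⁻³ of its power at T ≈ 240) — this is a property of any
projection filter on a finite window, not of the implementation. Slice-wise
regression is expressed by calling the cleaner once per slice-block of
channels.

**tSNR** is temporal mean over temporal standard deviation (sample, n−1),
per voxel; zero-variance voxels yield ±inf with a warning.

**Robust parcellation.** Region value at time t = mean of that region's
voxel values after excluding values below the 5th or above the 95th
percentile of the cross-voxel distribution *at that time point* (the
percentile band is inclusive, so ties at the boundary are kept). Regions
with fewer than 5 voxels use the plain mean, since 5–95% trimming is
vacuous below that size. An alternative reading — trimming extreme time
points per voxel before averaging — exists; the per-time-point cross-voxel
form is the one implemented.

## Fingerprinting

FC is the Pearson correlation matrix of region series (diagonal exactly 1);
the feature vector is its upper triangle in row-major order (i < j), a
convention shared by FC vectors, ICC maps and the PCA sweep. No Fisher
z-transform is applied before the identifiability correlation (a flag
exists, off by default).

The identifiability matrix is `I[i, j] = corr(c_i(1), c_j(2))`. `Iothers`
averages *all* `Ns(Ns−1)` off-diagonal entries without symmetrization.
Identification is row-wise only: subject i is identified at level K iff at
most K−1 off-diagonal entries of row i are ≥ `I[i, i]`; a tie with the
diagonal counts as failure (deterministic, conservative, probability zero
for continuous data). Idiff is reported on the raw correlation scale;
chance level is `100/Ns` percent, rounded to one decimal in summaries only.
Cohen's d uses sample (n−1) variances of the diagonal and off-diagonal
entries.

**PCA sweep.** The `2·Ns` FC vectors are stacked as columns of an
`M × 2·Ns` matrix; each edge (row) is centered across columns; SVD gives
the principal components over columns; for each m the columns are
reconstructed from the top-m components plus the mean and Idiff is
recomputed. Centering per edge and adding the mean back makes the
`m = 2·Ns` entry reproduce the raw Idiff exactly (asserted to 1e−8), which
pins down the orientation of the decomposition; the sweep's argmax prefers
the smaller m on ties.

## Reliability

Per edge, a one-way random-effects ANOVA with subjects as groups and the
k = 2 runs as repeats:
`MSR = k·Σ(x̄_i − x̄)²/(Ns−1)`, `MSW = Σ_ij (x_ij − x̄_i)²/(Ns·(k−1))`,
`ICC(1,1) = (MSR − MSW)/(MSR + (k−1)·MSW)`. Edges with zero total variance
are NaN and excluded from percentiles. Thresholding uses the
linear-interpolation quantile of the finite upper-triangle values (each
edge once); sub-threshold edges are zeroed. Nodal strength is the row
aggregate of the filtered map — `sum` by default (NaN as 0), `mean`
(NaN excluded) as an option, since both conventions appear in the
literature; reports name the mode used. For level-replicated spinal
schemes, the within-level 14 × 14 diagonal blocks are averaged elementwise
(NaN-aware) across levels and datasets; cross-level edges are deliberately
excluded from that average.

## Cross-regression

Each target region's series is regressed on *all* predictor regions' series
over the shared time axis, with mean-centering in place of an intercept and
the minimum-norm least-squares solution (`Y = X·β + ε` read as per-target
multiple regression — the only dimensionally consistent form). Residuals
(`N_target × T`) are exactly orthogonal to the centered predictors and
satisfy the Pythagorean variance split per region. Fitting is per run; runs
are not pooled. A ridge option exists for T close to the predictor count
but is off by default. Residual fingerprints feed the residual series
through the standard FC → identifiability pipeline.

## Synthetic cohorts

Subject-run series are T draws from a zero-mean multivariate normal with
correlation
`Σ(i, r) = (1−α−γ)·C_group + α·C_subj(i) + γ·C_run(i, r)` plus iid
observation noise (`noise_sd`). Component matrices are rank-q factor-model
correlations (`normalize(W·Wᵀ + 10⁻³·I)`, W `n × q` standard normal,
q = `latent_rank`, default 10 — low rank gives FC structure of realistic
strength; q ≫ n would drive all correlations to zero). The convex mixture
is projected to the correlation cone by eigenvalue clipping at 10⁻⁶ and
diagonal renormalization (cheap and adequate at these sizes). All draws
descend from spawned child generators of one seed, so cohorts are
bit-for-bit reproducible.

* `α` (subject weight) is the fingerprint strength: at α = 0 the
  identification accuracy equals the 100/Ns chance level by exchangeability;
  at α = 0.9 with low γ and noise it reaches 100%.
* `γ` (run weight) models session/state variability.
* Defaults (Ns = 15, N = 98, T = 230, TR = 2.31 s, α = 0.4, γ = 0.2,
  noise 0.5) mirror a single-site two-run cervical-cord protocol covering
  C2–C8; the generator also accepts the 42/70-region and 119-region brain
  configurations.

Driven pairs set `Y(i, r) = A_i·X(i, r) + noise` with `A_i` a sparse
subject-specific mixing matrix fixed across runs, so Y's identifiable
structure is inherited entirely from X; regressing X out of Y should
collapse Y's fingerprint while the reverse regression leaves X's largely
intact. What the generator does **not** emulate: hemodynamic convolution,
temporal autocorrelation (no AR noise by default), motion artifacts, scanner
drifts, or spatial voxel structure. Passing tests therefore demonstrate the
estimators' statistical behaviour under the assumed covariance model, not
robustness to those real-data features.

## Problem sizes in the test suite

The statistical acceptance checks run at the emulated study scale
(15 × 98 × 230): 200 replicates for the chance-level check at α = 0
(Monte-Carlo SE ≈ 0.5 accuracy points), 20 replicates of the
strong-fingerprint regime, 100 replicates per point of the α-grid
{0, 0.2, 0.4, 0.6, 0.8} for the Spearman monotonicity of mean Idiff and
mean edge ICC, and 50 replicates of the driven-pair directionality contrast
(10 subjects, 40 source regions, 10 target regions). Unit tests use smaller
cohorts chosen so every oracle comparison is exact.

## Numerical conventions and edge cases

* Pearson correlations computed with population-scale z-scores; results
  clipped to [−1, 1]; constant series raise with the offending region or
  subject named.
* Quantiles: numpy linear interpolation between order statistics.
* Degenerate inputs: all-NaN ICC maps, zero pooled variance in Cohen's d,
  fewer than 2 subjects, overcomplete nuisance bases, and T ≤ predictors in
  cross-regression all raise informative errors rather than returning
  silent NaN.
* Reports serialize floats through JSON's repr round-trip; TSVs use
  17-significant-digit scientific notation and are re-read with round-trip
  float parsing, so file round-trips are bitwise exact.

## Known limitations

* The robust-mean and PCA-orientation choices above are single readings of
  conventions that vary across the literature; both alternatives are
  documented, neither is silently mixed in.
* ICC variants other than (1,1), confidence intervals on ICC, dynamic FC,
  partial correlation and lagged/causal cross-models are out of scope.
* The chance level reported for a cohort is always 100/Ns.
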