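# Methods

This note records the statistical models, default parameters and numerical
choices implemented in `molfc`, and the known limitations of the synthetic
cohort generator.

## Atlas preparation (`molfc.atlas`)

A molecular density atlas enters the analysis as a nonnegative 3D map.
Preparation applies, in order:

1. **Resampling** to the functional grid by trilinear interpolation
   (nilearn `resample_img`; nearest-neighbour for the reference mask and
   other label images), zero fill outside the source support. Matching
   geometry short-circuits to the identity.
2. **Reference-region masking**: voxels of the tracer's quantification
   region (e.g. cerebellum, occipital lobe, white matter) are set to zero
   and recorded; they are excluded from all later rescaling statistics,
   not merely zeroed.
3. **Min–max rescaling** to [0, 1] over non-reference voxels.

Masks: with `coverage` the set of voxels with nonzero temporal variance in
every subject's scan, the atlas-specific mask for atlas *a* is
`coverage ∩ (a > 0) ∩ GM` and the single atlas-independent mask is
`coverage ∩ GM`. Pathway masks are unions of named parcellation regions
(12 mesocorticolimbic and 3 nigrostriatal afferent regions by default).
Tissue volume is `sum(probability) × voxel volume`; total intracranial
volume is the sum over GM, WM and CSF.

## Denoising (`molfc.denoise`)

For each 4D scan, per voxel in the validity mask:

1. **aCompCor**: each tissue mask (WM, CSF) is eroded by one voxel
   (6-connectivity); the voxel × time matrix is demeaned per voxel and
   decomposed by SVD; the first five right singular vectors, scaled to
   unit variance, are the component time series. Requesting more
   components than the matrix rank is an error.
2. **Confound regression**: one simultaneous OLS of every voxel's time
   series on [intercept, linear trend, 5 WM + 5 CSF aCompCor components,
   6 motion parameters, 6 backward-difference motion derivatives]
   (22 confounds + 2 internal regressors). A single simultaneous model is
   used so that later steps cannot reintroduce removed variance.
3. **Band-pass 0.008–0.1 Hz**, zero-phase. The default design zeroes all
   DFT bins outside the band: exactly unit gain in band, exact zero out
   of band, no phase distortion, idempotent. A forward–backward
   Butterworth (`design="butter"`, order 4) is available; it trades the
   exact passband for smooth roll-off. The filter rejects bands that do
   not fit below the Nyquist frequency.
4. **Despiking**: residuals from a running median (window 11) are
   compared against their median absolute deviation (× 1.4826); samples
   within k·MAD (default k = 4) pass unchanged, samples beyond are mapped
   through `scale·tanh(residual/scale)` so that every output sample lies
   within k·MAD of the running median.
5. A final **linear-detrend projection** removes the small slope that
   filtering/despiking can reintroduce, then each voxel's original mean
   is restored. The output therefore preserves voxel means and carries
   exactly zero fitted linear trend.

## Dual regression (`molfc.react`)

Stage 1 (spatial): at each timepoint *t*, OLS of the in-mask voxel values
on [intercept, demeaned template]. Because there is a single regressor,
the coefficient is computed in closed form,
`a·(y_t − ȳ_t)/(a·a)` with `a` the demeaned template. The coefficient
series across time is the subject's molecular time series.

Stage 2 (temporal): the stage-1 series is z-scored (population SD) and
each voxel's time course is regressed on [intercept, series]; the series
coefficient is the voxel's FC value. Maps are stored as 0 outside the
analysis mask.

Each template is fitted in its **own independent model** (simple
regression in both stages), mirroring the published pipeline, rather than
one multivariate model over all templates. Pathway-restricted variants run
stage 1 inside `pathway ∩ atlas-specific` and stage 2 on the whole
grey-matter mask.

## Cognition (`molfc.cognition`)

Seven measures (logical memory immediate/delayed recall, letter fluency,
similarities, Stroop time-interference, digit span forwards/backwards) are
standardized against the same site's cognitively unimpaired (CU) group
(sample SD, n−1); missing raw scores propagate. The composite score is
the mean of the available z-scores with Stroop time sign-flipped (a
completion time: higher is worse) and is missing for participants with
three or fewer available measures. Fewer than two CU reference values, or
zero CU spread, at a site is an error rather than a silent NaN.

## Group statistics (`molfc.stats`)

Voxel-wise OLS with cell-means group coding (CU, MCI, dementia
indicators), mean-centred continuous covariates (age, education, TIV) and
first-level-reference dummy coding for categorical covariates (sex,
site). Group differences use the all-groups-equal F contrast (successive
differences of group columns); single-row contrasts give t maps. Voxels
non-finite in any subject are excluded.

**Cluster-extent FWE by Freedman–Lane permutation**: the design is split
into effect (`M = X C⁺`) and nuisance (`Z = X(I − C⁺C)`, numerically null
columns dropped by SVD) partitions; the data are residualized against Z,
subject rows of the residuals are permuted, the nuisance fit is added
back, and the full-model statistic map is recomputed. Clusters form above
the parametric quantile of the forming threshold (default p = 0.001)
under 18-connectivity (faces + edges). Each observed cluster's FWE
p-value is `(1 + #{permutation max extent ≥ k}) / (1 + n_perm)`. Peaks
are reported in world coordinates when an affine is supplied; ties break
toward the lowest linear voxel index.

Scalar tests delegate to scipy behind a validating interface: Pearson χ²
without continuity correction (`chi2_contingency(correction=False)`),
one-way ANOVA (`f_oneway`), Kruskal–Wallis with tie correction
(`kruskal`), Shapiro–Wilk. Degenerate tables (zero marginals, zero
expected counts) are errors.

## Synthetic cohort generator (`molfc.synthetic`)

The generating model is the one the dual regression estimates:

```
BOLD(v, t) = Σ_k W_k(v)·s_k(t) + nuisance + motion drift + trend
             + spikes + white noise + baseline
```

* **Geometry**: a deterministic slab layout — the brain excludes a
  one-voxel border; the bottom slices are WM, the top CSF, the middle GM;
  every tissue survives one-voxel erosion. Grids must be ≥ 12 voxels per
  axis.
* **Templates** `W_k`: smooth (6 mm FWHM) random fields supported on GM,
  sequentially orthogonalized over the GM support, shifted nonnegative,
  reference slab masked, rescaled to [0, 1]. Group effects add a constant
  δ inside a sphere intersected with the template support.
* **Series** `s_k`: zero-mean unit-SD Gaussian series confined to
  0.01–0.08 Hz (inside the 0.008–0.1 Hz analysis band), mutually
  orthogonalized (QR). Orthogonalization of both fields and series makes
  the independent per-template simple regression the correct estimator of
  the mixing; without it, chance correlations between random templates
  (~1/√n on these grids) bias the estimates irrespective of noise.
* **Amplitude unit**: all corruption amplitudes are multiples of the mean
  per-template signal SD over the support, so SNR statements hold per
  molecular system regardless of the number of templates.
* **Nuisance**: rank-5 per tissue; shared broadband basis series per
  tissue, independent N(0, 1) spatial loading patterns per component at
  2× signal SD in WM/CSF and 0.3× leakage into GM. Distinct, prominent
  spatial patterns are required for the planted subspace to be
  identifiable by a 5-component aCompCor; weaker or collinear loadings
  place most components below the eroded-mask PCA noise floor.
* **Other corruptions**: motion random walks with a spatially random
  BOLD coupling, random linear trends, global ±8×SD spikes at 2 % of
  timepoints (large enough to give the despiker a detectable target),
  white noise at 1× SD, baseline 100.
* **Reproducibility**: every generative component draws from its own
  `default_rng([config.seed, subject_seed, component_tag])` substream, so
  switching one component off leaves all other realizations unchanged —
  this is what makes exact nuisance-isolation experiments valid.
* **Cohort**: site assignment by configured shares, demographics, TIV
  (log-normal around 1450 ml), biomarker status (patients likelier
  positive; the last site unmeasured), and raw cognitive scores built
  from site-specific CU scales with group shifts in CU-SD units, plus
  per-cell missingness and a few subjects reduced to three measures to
  exercise the composite rule.

### Generator limitations

* Geometry is a rectangular slab phantom: no cortical folding, no
  partial-volume mixing, no spatial autocorrelation in the noise.
* Motion affects the signal only through an additive drift term; no
  realignment-style interpolation artefacts are simulated.
* Tissue nuisance is exactly low-rank and strictly tissue-confined aside
  from the configured GM leakage; physiological noise in real data is
  neither.
* Cognitive scores are Gaussian with linear group shifts; floor/ceiling
  effects and item-level structure are not modelled.

## Validation experiments (`molfc.validation`)

Small-grid experiments scale the full-resolution cluster-forming
threshold (p = 0.001 on a ~1.7 × 10⁵-voxel grey-matter brain) in two
ways, matched to what each experiment measures:

* **Null calibration** uses the count-preserving analog
  (`scaled_forming_p`, ≈ 0.1 on a 12³ grid — equal expected
  suprathreshold voxel count). At stringent thresholds on tiny grids the
  integer cluster-extent null collapses onto one or two values and the
  test becomes arbitrarily conservative; preserving the suprathreshold
  count preserves the richness of the extent distribution. Measured
  family-wise error: pooled 0.045 over 6 × 200 null repetitions.
* **Detection** keeps a stringent small-grid threshold (p = 0.01):
  cluster-extent inference localizes a compact implanted effect only when
  the forming threshold suppresses the noise background — at the
  count-preserving analog the permutation max-extent null grows past the
  implanted cluster and detection correctly fails.

Noisy-recovery experiments run at the stated conditions (white noise at
1× signal SD, T = 125, band-pass denoising). With the full corruption
chain the 22-regressor confound regression removes ~8–18 % of the
band-limited signal variance by chance temporal overlap (22 estimated
directions in 125 samples) — an inherent property of confound regression
at this scan length; full-chain numbers are reported separately by
`scripts/acceptance.py` as `fullchain_*`.

The surviving-nuisance metric passes the exact injected nuisance
realization through the same fitted linear denoising operators and
reports its power relative to the denoised output; projecting the output
onto the broadband nuisance basis instead has a chance-overlap floor of
several percent (10 random directions against ~58 in-band dimensions)
even under perfect removal.

## Numerical choices

* All OLS fits use `numpy.linalg.lstsq` or closed forms; no iterative
  solvers.
* The FFT band-pass is preferred as the default because a
  forward–backward IIR at these cutoffs cannot keep total in-band power
  within a few percent of the input (Parseval), which the validation
  experiments require.
* Population (ddof = 0) SDs for time-series z-scoring; sample (ddof = 1)
  SDs for cognitive standardization, matching the respective conventions.
* Permutation p-values use the `(1 + b)/(1 + m)` estimator, which is
  valid (never zero) and slightly conservative.
* Derived RNG seeds stay below 2³¹; all experiment entry points take a
  single integer seed.
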