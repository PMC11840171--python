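# molfc — receptor-enriched functional connectivity

`molfc` estimates **molecular-template functional connectivity** from
resting-state fMRI: PET/SPECT receptor and transporter density atlases are
used as spatial regressors to extract, per subject, the BOLD fluctuations
weighted by each neurotransmitter system's distribution, and those time
series are then used as temporal regressors to map each system's functional
connectivity (FC) across the brain — the REACT two-stage dual regression.
The package implements the full analysis used to study dopaminergic and
cholinergic FC across the Alzheimer's disease continuum (cognitively
unimpaired → MCI → dementia):

1. **Atlas preparation** — resampling onto the functional grid, masking of
   each tracer's reference region, min–max rescaling to [0, 1], and
   construction of the atlas-specific (coverage ∩ atlas ∩ grey matter) and
   atlas-independent (coverage ∩ grey matter) analysis masks, plus binary
   masks for the mesocorticolimbic (MCL) and nigrostriatal (NST)
   dopaminergic pathways.
2. **Denoising** — aCompCor (first five principal components of eroded
   white-matter and CSF signals), simultaneous regression of 22 confounds
   (10 aCompCor + 6 motion + 6 motion derivatives) with intercept and
   linear trend, zero-phase 0.008–0.1 Hz band-pass, and despiking toward a
   running median.
3. **Dual regression** — one independent two-stage model per molecular
   template; pathway-restricted variants re-run stage 1 inside a pathway
   mask while stage 2 covers the whole grey matter.
4. **Cognition** — seven measures standardized against each site's
   cognitively unimpaired group, averaged into a composite score that is
   left missing for participants with three or fewer measures.
5. **Group statistics** — voxel-wise GLMs (group indicators plus age,
   education, sex, total intracranial volume and site), cluster-extent
   family-wise-error correction by Freedman–Lane permutation, and the
   scalar demographic tests (χ², ANOVA, Kruskal–Wallis, Shapiro–Wilk).
6. **Synthetic cohort generator** — multi-site cohorts with known template
   loadings, band-limited molecular time series, low-rank tissue nuisance,
   motion drift, trends, spikes, biomarker status and cognitive scores, so
   every estimator in the package can be validated against ground truth.

## Worked example

Simulate one subject at unit signal-to-noise, denoise, and extract the
three molecular FC maps:

```python
import numpy as np

from molfc import (SimulationConfig, acompcor, build_confounds, build_masks,
                   denoise_pipeline, make_atlas, react, rescale_unit,
                   simulate_subject, tissue_layout)

config = SimulationConfig(seed=11)                    # 20^3 grid, T=125
atlases = [rescale_unit(make_atlas(config, k)) for k in range(3)]
layout = tissue_layout(config.grid_shape)

scan, motion, truth = simulate_subject(config, atlases, "CU", seed=0)

wm = acompcor(scan, layout["wm"], 5)
csf = acompcor(scan, layout["csf"], 5)
confounds = build_confounds(motion.to_numpy(), wm, csf, config.tr)
denoised = denoise_pipeline(scan, config.affine, confounds)

masks = build_masks([scan], atlases, layout["gm"], affine=config.affine)
fc_maps = react(denoised, atlases, masks)

for k, fc in enumerate(fc_maps):
    m = masks.atlas_independent
    r = np.corrcoef(fc.betas[m], truth.loadings[k][m])[0, 1]
    print(f"{fc.atlas}: FC map vs. true loadings r = {r:.3f}")
```

Output:

```
D1: FC map vs. true loadings r = 0.937
D2: FC map vs. true loadings r = 0.902
DAT: FC map vs. true loadings r = 0.931
```

The same analysis runs end to end from the command line, driven by a YAML
config:

```bash
cat > config.yaml <<EOF
out_dir: run1
simulate:
  n_per_group: [4, 4, 4]
  grid_shape: [14, 14, 14]
  n_timepoints: 60
  n_templates: 2
  sites: [S1]
  site_shares: [1.0]
glm:
  forming_p: 0.01
  n_perm: 100
EOF
molfc run --config config.yaml
```

```
... molfc INFO simulate: 0.6s
... molfc INFO prep: 0.2s
... molfc INFO denoise: 0.9s
... molfc INFO react: 0.1s
... molfc INFO glm: 0.1s
pipeline outputs in run1
```

The run directory contains the simulated cohort (`data/`), denoised scans
(`denoised/`), per-subject FC maps and molecular time series (`fc/`), the
scored cohort table (`cohort_scored.tsv`), and per-template group F maps
with cluster tables (`glm/`). An unchanged rerun skips completed stages via
config-hash sentinels in `run_log/`.

## Validation and reproduction

The statistical core is validated against ground truth and independent
oracles; `molfc.validation` holds the experiments, and the test suite
asserts them:

* the five χ² statistics of the source cohort's contingency tables are
  reproduced to two decimals (sex 1.39, AChEI 63.04, site 20.64,
  Aβ 23.04, p-tau 8.94);
* dual regression is exact (≈1e-15) on noiseless template × series
  products and matches brute-force least squares to 1e-8;
* at unit SNR and T = 125, molecular time series recover truth at
  r > 0.95 and FC maps at r > 0.9;
* the permutation cluster test's empirical family-wise error on 200 null
  cohorts lies within [0.02, 0.09] at nominal 0.05, and an implanted
  group-difference cluster is detected as exactly one significant cluster
  (Dice > 0.99 against truth) with none on a null cohort;
* planted low-rank tissue nuisance survives denoising at < 0.1 % of the
  output variance; the band-pass retains in-band tones at ≥ 0.9 amplitude
  and suppresses out-of-band tones to ≤ 0.1.

Reproduce all quantities from scratch (about half a minute):

```bash
python scripts/acceptance.py --seed 1 --out results.json
```

Run the full test suite:

```bash
python -m pytest -q tests/          # unit + property + acceptance tests
```

## Layout

```
src/molfc/
  atlas.py       atlas normalization, analysis masks, tissue volumes
  denoise.py     aCompCor, confound regression, band-pass, despike
  react.py       two-stage dual regression (whole-brain and pathway)
  cognition.py   site-referenced z-scores, composite score
  stats.py       voxel-wise GLM, Freedman–Lane cluster FWE, scalar tests
  synthetic.py   ground-truth cohort generator
  validation.py  calibration/recovery experiments used by tests & scripts
  pipeline.py    YAML-driven end-to-end driver with stage skipping
  cli.py         `molfc` command-line interface
docs/methods.md  models, parameters and numerical choices
```
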