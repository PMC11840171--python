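"""Self-contained validation experiments with known ground truth.

Each function here runs one end-to-end experiment against the synthetic
generator — parameter recovery of the dual regression, family-wise error
calibration of the permutation cluster test, detection of an implanted
group-difference cluster, removal of planted nuisance — and returns plain
numbers. The same experiments back the test suite and the reproduction
script, so reported quantities are always recomputed from scratch.

Small-grid experiments scale the full-resolution cluster-forming
threshold (p = 0.001 on a ~1.7e5-voxel grey-matter brain) to the toy
grids in two different ways, matched to what each experiment measures.
The null-calibration experiment uses the count-preserving analog
``scaled_forming_p`` (equal expected suprathreshold voxel count, p = 0.1
on a 12^3 grid), because family-wise error control degenerates into
over-conservatism when the integer cluster-extent null collapses onto
one or two values. The detection experiment keeps a stringent threshold
(p = 0.01) because cluster-extent inference only localizes a compact
implanted effect when the forming threshold suppresses the noise
background, exactly as at full resolution.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .atlas import build_masks, rescale_unit
from .denoise import (DenoisedScan, acompcor, bandpass_filter,
                      build_confounds, denoise_pipeline)
from .react import stage1_timeseries, stage2_fcmap
from .stats import (DesignMatrix, build_design, cluster_inference,
                    fit_voxelwise_glm, group_f_contrast)
from .synthetic import (EffectSpec, SimulationConfig, make_atlas,
                        simulate_subject, tissue_layout)

SMALL_GRID_FORMING_P = 0.01

#: reference point for threshold scaling: p = 0.001 on a full-resolution
#: grey-matter brain of ~1.7e5 voxels (2 mm isotropic).
FULL_BRAIN_FORMING_P = 0.001
FULL_BRAIN_N_VOXELS = 173_000


def scaled_forming_p(n_voxels: int) -> float:
    """Forming threshold with the full-brain expected suprathreshold count.

    Preserves ``FULL_BRAIN_FORMING_P × FULL_BRAIN_N_VOXELS`` expected
    suprathreshold voxels on a grid of ``n_voxels`` voxels, capped at 0.5.
    """
    return min(0.5, FULL_BRAIN_FORMING_P * FULL_BRAIN_N_VOXELS / n_voxels)


def _denoised(scan: np.ndarray, config: SimulationConfig,
              bandpass_only: bool = False) -> DenoisedScan:
    layout = tissue_layout(config.grid_shape)
    mask = np.var(scan, axis=3) > 0
    if bandpass_only:
        Y = scan[mask].T
        mu = Y.mean(axis=0, keepdims=True)
        out = np.zeros_like(scan)
        out[mask] = (bandpass_filter(Y - mu, config.tr) + mu).T
        return DenoisedScan(data=out, affine=config.affine, tr=config.tr,
                            valid_mask=mask)
    wm = acompcor(scan, layout["wm"], 5)
    csf = acompcor(scan, layout["csf"], 5)
    rng = np.random.default_rng([config.seed, 99])
    motion = np.cumsum(rng.normal(0, 0.02, (config.n_timepoints, 6)), axis=0)
    conf = build_confounds(motion, wm, csf, config.tr)
    return denoise_pipeline(scan, config.affine, conf)


def recovery_experiment(seed: int, noise_sd: float = 1.0,
                        full_chain: bool = False,
                        config: SimulationConfig | None = None
                        ) -> dict[str, float]:
    """Recover template series and FC maps from one noisy subject.

    By default the scan carries only white measurement noise at
    ``noise_sd`` × per-template signal SD and is band-pass filtered before
    the dual regression; ``full_chain`` turns on the rank-5 tissue
    nuisance, motion drift, trend and spikes and runs the complete
    denoising pipeline. Returns the minimum over templates of the
    series-truth and map-loading correlations.
    """
    if config is None:
        config = SimulationConfig(seed=seed)
    if not full_chain:
        config = replace(config, nuisance_rank=0, motion_amp=0.0,
                         trend_amp=0.0, spike_rate=0.0, noise_sd=noise_sd)
    atlases = [make_atlas(config, k) for k in range(config.n_templates)]
    rescaled = [rescale_unit(a) for a in atlases]
    layout = tissue_layout(config.grid_shape)
    scan, motion, gt = simulate_subject(config, atlases, "CU", seed=0,
                                        subject="sub")
    if full_chain:
        wm = acompcor(scan, layout["wm"], 5)
        csf = acompcor(scan, layout["csf"], 5)
        conf = build_confounds(motion.to_numpy(), wm, csf, config.tr)
        ds = denoise_pipeline(scan, config.affine, conf)
    else:
        ds = _denoised(scan, config, bandpass_only=True)
    masks = build_masks([scan], rescaled, layout["gm"], affine=config.affine)
    series_r, map_r = [], []
    for k, a in enumerate(rescaled):
        s1 = stage1_timeseries(ds, a, masks.atlas_specific[a.name])
        series_r.append(abs(np.corrcoef(s1.values, gt.series[:, k])[0, 1]))
        fc = stage2_fcmap(ds, s1.zscored(), masks.atlas_independent)
        mk = masks.atlas_independent
        map_r.append(abs(np.corrcoef(fc.betas[mk],
                                     gt.loadings[k][mk])[0, 1]))
    return {"series_r_min": float(min(series_r)),
            "fcmap_r_min": float(min(map_r)),
            "series_r_mean": float(np.mean(series_r)),
            "fcmap_r_mean": float(np.mean(map_r))}


def noiseless_exactness_experiment(seed: int) -> dict[str, float]:
    """Dual regression on pure template × series products, no noise.

    For each template the scan is exactly ``W_k(v) · s_k(t)`` plus a
    constant baseline. Stage 1 on the template's support must return the
    series exactly and stage 2 must return the loadings exactly (up to
    machine rounding); the mixture of all templates must still recover
    loadings at r > 0.999 through the independent per-template models.
    """
    config = SimulationConfig(seed=seed, noise_sd=0.0, nuisance_rank=0,
                              motion_amp=0.0, trend_amp=0.0, spike_rate=0.0)
    atlases = [rescale_unit(make_atlas(config, k))
               for k in range(config.n_templates)]
    rng = np.random.default_rng([seed, 21])
    from .synthetic import band_limited_series
    s = band_limited_series(rng, config.n_templates, config.n_timepoints,
                            config.tr, orthogonalize=True)
    series_err, map_err = 0.0, 0.0
    for k, a in enumerate(atlases):
        scan = a.values[..., None] * s[:, k] + config.baseline
        mask = a.values > 0
        ds = DenoisedScan(data=scan, affine=config.affine, tr=config.tr,
                          valid_mask=mask)
        s1 = stage1_timeseries(ds, a, mask)
        series_err = max(series_err, float(np.max(np.abs(s1.values
                                                         - s[:, k]))))
        fc = stage2_fcmap(ds, s1.zscored(), mask)
        # stage 2 regresses on the z-scored series, so betas carry the
        # series SD as a factor: beta_v = W_v · sd(s_k)
        scale = float(s[:, k].std(ddof=0))
        map_err = max(map_err, float(np.max(
            np.abs(fc.betas[mask] - a.values[mask] * scale))))
    mix = recovery_experiment(seed, noise_sd=0.0)
    return {"series_max_abs_err": series_err,
            "map_max_abs_err": map_err,
            "mixture_series_r_min": mix["series_r_min"],
            "mixture_fcmap_r_min": mix["fcmap_r_min"]}


def null_design(n: int) -> tuple[DesignMatrix, np.ndarray]:
    """Three-group design for null simulations (sizes as equal as possible)."""
    sizes = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
    groups = np.repeat([0, 1, 2], sizes)
    X = np.zeros((n, 3))
    X[np.arange(n), groups] = 1.0
    design = DesignMatrix(values=X, columns=["group_CU", "group_MCI",
                                             "group_dementia"])
    return design, group_f_contrast(design)


def fwer_calibration(seed: int, n_reps: int = 200, n_subjects: int = 20,
                     grid: tuple[int, int, int] = (12, 12, 12),
                     n_perm: int = 200,
                     forming_p: float | None = None,
                     alpha: float = 0.05) -> dict[str, float]:
    """Empirical family-wise error of the cluster test on pure noise.

    Each repetition draws Gaussian maps for ``n_subjects`` subjects, runs
    the F-contrast cluster inference, and counts a family-wise error when
    any cluster reaches ``alpha``. The empirical rate should bracket the
    nominal level. The forming threshold defaults to the count-preserving
    ``scaled_forming_p`` of the grid (see module docstring).
    """
    if forming_p is None:
        forming_p = scaled_forming_p(int(np.prod(grid)))
    design, contrast = null_design(n_subjects)
    rng = np.random.default_rng(seed)
    rejections = 0
    for rep in range(n_reps):
        maps = rng.standard_normal((n_subjects, *grid))
        table = cluster_inference(maps, design, contrast,
                                  forming_p=forming_p, n_perm=n_perm,
                                  seed=int(rng.integers(2 ** 31)))
        if len(table) and (table["fwe_p"] < alpha).any():
            rejections += 1
    return {"fwer": rejections / n_reps, "n_reps": n_reps}


def _cohort_fc_stack(config: SimulationConfig,
                     effect_specs: list[EffectSpec]) -> dict:
    """Simulate a cohort in memory and compute its template-0 FC maps."""
    import pandas as pd

    atlases = [make_atlas(config, k) for k in range(config.n_templates)]
    rescaled = [rescale_unit(a) for a in atlases]
    layout = tissue_layout(config.grid_shape)
    groups = [g for g, n in zip(["CU", "MCI", "dementia"],
                                config.n_per_group) for _ in range(n)]
    rng = np.random.default_rng([config.seed, 5])
    scans, fc, truths = [], [], []
    for i, group in enumerate(groups):
        scan, motion, gt = simulate_subject(
            config, atlases, group, seed=i, effect_specs=effect_specs,
            subject=f"sub-{i:03d}")
        scans.append(scan)
        truths.append(gt)
    masks = build_masks(scans, rescaled, layout["gm"], affine=config.affine)
    for i, scan in enumerate(scans):
        wm = acompcor(scan, layout["wm"], 5)
        csf = acompcor(scan, layout["csf"], 5)
        motion = np.cumsum(rng.normal(0, 0.02,
                                      (config.n_timepoints, 6)), axis=0)
        conf = build_confounds(motion, wm, csf, config.tr)
        ds = denoise_pipeline(scan, config.affine, conf)
        a = rescaled[0]
        s1 = stage1_timeseries(ds, a, masks.atlas_specific[a.name])
        fc.append(stage2_fcmap(ds, s1.zscored(),
                               masks.atlas_independent).betas)
    n = len(groups)
    cohort = pd.DataFrame({
        "group": groups,
        "age": rng.normal(70, 8, n),
        "education": rng.normal(12, 3, n),
        "sex": rng.choice(["M", "F"], n),
        "tiv": rng.normal(1450, 150, n),
        "site": rng.choice(["S1", "S2"], n),
    })
    design = build_design(cohort)
    return {"stack": np.stack(fc), "design": design,
            "mask": masks.atlas_independent, "config": config,
            "truths": truths, "effect_specs": effect_specs}


def planted_cluster_experiment(seed: int, delta: float = -0.8,
                               n_per_group: int = 10,
                               grid: tuple[int, int, int] = (14, 14, 14),
                               n_timepoints: int = 60,
                               n_perm: int = 500,
                               forming_p: float = SMALL_GRID_FORMING_P
                               ) -> dict[str, float]:
    """Detect one implanted group-difference cluster (or none when δ=0).

    Returns the number of FWE-significant clusters and, when one exists,
    its Dice overlap with the true effect cluster.
    """
    config = SimulationConfig(
        n_per_group=(n_per_group,) * 3, grid_shape=grid,
        n_timepoints=n_timepoints, n_templates=1, seed=seed)
    center = tuple(int(s // 2) for s in grid)
    radius = max(2.0, min(grid) / 5.0)
    effect = [EffectSpec(template_index=0, center=center, radius=radius,
                         deltas={"CU": 0.0, "MCI": delta / 2.0,
                                 "dementia": delta})]
    run = _cohort_fc_stack(config, effect)
    contrast = group_f_contrast(run["design"])
    table = cluster_inference(run["stack"], run["design"], contrast,
                              forming_p=forming_p, n_perm=n_perm, seed=seed,
                              mask=run["mask"])
    sig = table[table["fwe_p"] < 0.05] if len(table) else table
    out = {"n_significant": float(len(sig)), "dice": 0.0}
    if len(sig) == 0:
        return out
    # true cluster: voxels whose loading was shifted, inside the mask
    gt = run["truths"][0]
    grids = np.indices(grid)
    spec = effect[0]
    d2 = sum((grids[i] - spec.center[i]) ** 2 for i in range(3))
    true_cluster = (d2 <= spec.radius ** 2) & (gt.loadings[0] > 0) & \
        run["mask"]
    # recompute the significant cluster's voxels from the stat map
    stat = fit_voxelwise_glm(run["stack"], run["design"], contrast,
                             mask=run["mask"])
    from scipy import ndimage

    from .stats import CONNECTIVITY_18, _threshold
    thr = _threshold(stat, forming_p)
    labels, _ = ndimage.label((stat.values > thr) & stat.mask,
                              structure=CONNECTIVITY_18)
    best_dice = 0.0
    for _, row in sig.iterrows():
        peak = tuple(int(v) for v in (row["x"], row["y"], row["z"]))
        lab = labels[peak]
        detected = labels == lab
        inter = (detected & true_cluster).sum()
        dice = 2.0 * inter / (detected.sum() + true_cluster.sum())
        best_dice = max(best_dice, float(dice))
    out["dice"] = best_dice
    return out


def nuisance_removal_experiment(seed: int) -> dict[str, float]:
    """Fraction of denoised GM variance carried by surviving true nuisance.

    Simulates a subject with the planted rank-5 tissue nuisance, isolates
    the exact injected nuisance component (scan minus the nuisance-free
    rerun of the same seed), pushes it through the same linear denoising
    operators fitted on the full scan (confound regression with the
    scan-estimated aCompCor components, then the band-pass), and reports
    its residual power relative to the denoised data's total power.
    """
    from .denoise import regress_confounds

    config = SimulationConfig(seed=seed)
    atlases = [make_atlas(config, k) for k in range(config.n_templates)]
    layout = tissue_layout(config.grid_shape)
    scan, motion, gt = simulate_subject(config, atlases, "CU", seed=0)
    clean_cfg = replace(config, nuisance_rank=0)
    clean, _, _ = simulate_subject(clean_cfg, atlases, "CU", seed=0)
    nuis = scan - clean                      # exact injected realization

    wm = acompcor(scan, layout["wm"], 5)
    csf = acompcor(scan, layout["csf"], 5)
    conf = build_confounds(motion.to_numpy(), wm, csf, config.tr)
    gm = layout["gm"]
    surviving = bandpass_filter(
        regress_confounds(nuis[gm].T, conf.values), config.tr)
    denoised = bandpass_filter(
        regress_confounds(scan[gm].T, conf.values), config.tr)
    frac = float(np.sum(surviving ** 2) / np.sum(denoised ** 2))
    return {"nuisance_variance_fraction": frac}


def cognition_experiment(seed: int,
                         n_per_group: tuple[int, int, int] = (60, 30, 30)
                         ) -> dict[str, float]:
    """Standardization and composite-rule checks on a synthetic cohort.

    Returns the largest deviation of any site's CU group from mean 0 /
    sample SD 1 after site-referenced z-scoring, and the number of rows
    violating the composite-availability rule (composite present iff at
    least four measures are available).
    """
    import pandas as pd

    from .cognition import MEASURES, MIN_MEASURES_FOR_CS, add_composite, \
        zscore_by_site
    from .synthetic import _cognitive_scores

    config = SimulationConfig(n_per_group=n_per_group, seed=seed)
    rng = np.random.default_rng([seed, 11])
    groups = np.repeat(["CU", "MCI", "dementia"], n_per_group)
    shares = np.asarray(config.site_shares, dtype=float)
    sites = rng.choice(config.sites, size=len(groups),
                       p=shares / shares.sum())
    raw = _cognitive_scores(rng, config, sites, groups)
    cohort = pd.concat(
        [pd.DataFrame({"group": groups, "site": sites}), raw], axis=1)
    scored = add_composite(zscore_by_site(cohort))

    dev = 0.0
    for site, rows in scored.groupby("site"):
        cu = rows[rows["group"] == "CU"]
        for m in MEASURES:
            z = cu[f"z_{m}"].dropna()
            dev = max(dev, abs(float(z.mean())),
                      abs(float(z.std(ddof=1)) - 1.0))
    n_avail = scored[[f"z_{m}" for m in MEASURES]].notna().sum(axis=1)
    should_have_cs = n_avail >= MIN_MEASURES_FOR_CS
    violations = int((should_have_cs != scored["cs"].notna()).sum())
    violations += int((n_avail != scored["cs_n_measures"]).sum())
    return {"cu_standardization_dev": dev,
            "composite_rule_violations": float(violations),
            "n_subjects": float(len(scored)),
            "n_missing_cs": float(scored["cs"].isna().sum())}


def filter_gain_experiment(tr: float = 2.6, T: int = 125,
                           in_freq: float = 0.05, out_freq: float = 0.18
                           ) -> dict[str, float]:
    """Amplitude gain of the band-pass at an in-band and out-of-band tone."""
    t = np.arange(T) * tr
    gains = {}
    for label, f in (("inband_gain", in_freq), ("outband_gain", out_freq)):
        x = np.sin(2 * np.pi * f * t)
        y = bandpass_filter(x[:, None], tr)[:, 0]
        amp_in = (x.max() - x.min()) / 2.0
        amp_out = (y.max() - y.min()) / 2.0
        gains[label] = float(amp_out / amp_in)
    return gains
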