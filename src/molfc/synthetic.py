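"""Synthetic multi-site cohort generator with known ground truth.

Every downstream stage (atlas preparation, denoising, dual regression,
cognition, group statistics) is exercised against data whose generating
model is the one the dual regression estimates:

    BOLD(v, t) = Σ_k W_k(v) · s_k(t) + nuisance(v, t) + motion drift
                 + linear trend + spikes + white noise

where W_k is the k-th molecular template rescaled to [0, 1] plus a
group-specific loading shift δ inside designated effect clusters, and s_k
are zero-mean band-limited (0.01–0.08 Hz) Gaussian time series that
survive the denoising band-pass. Tissue nuisance is a low-rank subspace
loading on WM/CSF voxels (strongly) and GM voxels (weakly), which is what
aCompCor is built to estimate and remove.

The cohort table carries demographics, site labels, TIV, biomarker status
and seven raw cognitive scores whose group means are shifted (in CU-SD
units) according to the configured cognitive effects.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import (MCL_REGIONS, NST_REGIONS, ParcellationImage,
                    ReceptorAtlas, mask_reference_region, rescale_unit)
from .cognition import MEASURES

DEFAULT_ATLAS_NAMES = ["D1", "D2", "DAT", "VAChT", "M1", "a4b2"]
GROUPS = ["CU", "MCI", "dementia"]


@dataclass
class EffectSpec:
    """A spherical FC effect: per-group loading shift on one template."""

    template_index: int
    center: tuple[int, int, int]
    radius: float
    deltas: dict[str, float]       # group label -> loading shift


@dataclass
class SimulationConfig:
    n_per_group: tuple[int, int, int] = (10, 10, 10)   # CU, MCI, dementia
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size: float = 2.0                            # mm, isotropic
    n_timepoints: int = 125
    tr: float = 2.6                                    # seconds
    n_templates: int = 3
    template_smoothness: float = 6.0                   # mm FWHM
    noise_sd: float = 1.0           # × in-brain signal SD (relative units)
    nuisance_rank: int = 5          # components per tissue
    nuisance_amp: float = 2.0       # × signal SD, in WM/CSF
    nuisance_gm_amp: float = 0.3    # × signal SD, leakage into GM
    motion_amp: float = 0.2         # × signal SD, motion-correlated drift
    trend_amp: float = 0.3          # × signal SD over the scan
    baseline: float = 100.0         # mean BOLD offset in-brain
    spike_rate: float = 0.02        # fraction of timepoints spiked
    spike_amp: float = 8.0          # × signal SD
    effect_specs: list[EffectSpec] = field(default_factory=list)
    cognitive_effects: dict[str, float] = field(
        default_factory=lambda: {"CU": 0.0, "MCI": -1.0, "dementia": -2.0})
    missing_rate: float = 0.02      # per-cell cognitive missingness
    few_measures_rate: float = 0.02  # subjects left with only 3 measures
    sites: tuple[str, ...] = ("S1", "S2", "S3")
    site_shares: tuple[float, ...] = (0.35, 0.40, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_group):
            raise ValueError("group sizes must be positive")
        if self.n_templates < 1:
            raise ValueError("need at least one template")
        if not 0.0 <= self.spike_rate < 1.0:
            raise ValueError("spike_rate must lie in [0, 1)")
        if self.n_timepoints <= 0 or self.tr <= 0:
            raise ValueError("timepoints and TR must be positive")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = -np.asarray(self.grid_shape) * self.voxel_size / 2.0
        return aff


@dataclass
class GroundTruthSubject:
    """Per-subject generating quantities stored in the manifest."""

    subject: str
    group: str
    loadings: np.ndarray           # K × X × Y × Z
    series: np.ndarray             # T × K, zero-mean
    applied_deltas: dict[int, float]  # template index -> delta in cluster


def default_effect_specs(config: SimulationConfig) -> list[EffectSpec]:
    """One spherical loading-shift cluster on template 0, patients lower."""
    c = tuple(int(s // 2) for s in config.grid_shape)
    r = max(2.0, min(config.grid_shape) / 6.0)
    return [EffectSpec(template_index=0, center=c, radius=r,
                       deltas={"CU": 0.0, "MCI": -0.3, "dementia": -0.6})]


# --- geometry --------------------------------------------------------------

def tissue_layout(grid_shape: tuple[int, int, int]
                  ) -> dict[str, np.ndarray]:
    """Deterministic brain geometry: WM and CSF slabs sandwich the GM.

    The brain excludes a one-voxel border; within it, the bottom three
    z-slices are WM, the top three are CSF and the middle is GM — thick
    enough that a one-voxel erosion of each tissue mask stays nonempty.
    """
    nx, ny, nz = grid_shape
    if min(grid_shape) < 12:
        raise ValueError("grid must be at least 12 voxels per axis")
    brain = np.zeros(grid_shape, dtype=bool)
    brain[1:nx - 1, 1:ny - 1, 1:nz - 1] = True
    zidx = np.arange(nz)[None, None, :]
    wm = brain & (zidx <= 3)
    csf = brain & (zidx >= nz - 5)
    gm = brain & ~wm & ~csf
    return {"brain": brain, "gm": gm, "wm": wm, "csf": csf}


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int, int],
                  fwhm_mm: float, voxel_mm: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter
    field = rng.standard_normal(shape)
    sigma_vox = fwhm_mm / voxel_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if sigma_vox > 0:
        field = gaussian_filter(field, sigma=sigma_vox)
    return field


def make_atlas(config: SimulationConfig, template_index: int,
               reference_slab: int = 2) -> ReceptorAtlas:
    """A smooth nonnegative random density field with a reference region.

    Density is supported on the grey matter, as for real receptor and
    transporter maps; WM and CSF carry no specific binding. Successive
    template fields are orthogonalized over the GM support so the
    independent-model dual regression is the correct estimator of the
    mixing it is asked to undo. The reference region is the lowest
    ``reference_slab`` z-slices of the brain (zeroed and excluded from
    rescaling). Deterministic given the config seed and template index.
    """
    layout = tissue_layout(config.grid_shape)
    if reference_slab >= config.grid_shape[2]:
        raise ValueError("reference region covers the whole grid")
    gm = layout["gm"]

    def gm_field(index: int) -> np.ndarray:
        rng = np.random.default_rng([config.seed, 1000 + index])
        f = _smooth_field(rng, config.grid_shape,
                          config.template_smoothness, config.voxel_size)
        v = f[gm]
        return (v - v.mean()) / v.std()

    basis: list[np.ndarray] = []
    field = None
    for j in range(template_index + 1):
        f = gm_field(j)
        for b in basis:
            f = f - (f @ b) / (b @ b) * b
        basis.append(f)
        field = f
    values = np.zeros(config.grid_shape)
    values[gm] = field - field.min()   # nonnegative
    name = DEFAULT_ATLAS_NAMES[template_index % len(DEFAULT_ATLAS_NAMES)]
    ref = np.zeros(config.grid_shape, dtype=bool)
    ref[:, :, :reference_slab + 1] = True
    ref &= layout["brain"]
    atlas = ReceptorAtlas(values=values, affine=config.affine, name=name)
    return mask_reference_region(atlas, ref, region_name="lower_slab")


def template_loadings(config: SimulationConfig,
                      atlases: list[ReceptorAtlas], group: str,
                      effect_specs: list[EffectSpec]
                      ) -> tuple[np.ndarray, dict[int, float]]:
    """Rescaled atlas loadings with the group's δ added inside clusters."""
    W = np.stack([rescale_unit(a).values for a in atlases])
    applied: dict[int, float] = {}
    grids = np.indices(config.grid_shape)
    for spec in effect_specs:
        delta = spec.deltas.get(group, 0.0)
        applied[spec.template_index] = delta
        if delta == 0.0:
            continue
        d2 = sum((grids[i] - spec.center[i]) ** 2 for i in range(3))
        sphere = d2 <= spec.radius ** 2
        support = W[spec.template_index] > 0
        W[spec.template_index][sphere & support] += delta
    return W, applied


def band_limited_series(rng: np.random.Generator, n: int, T: int, tr: float,
                        band: tuple[float, float] = (0.01, 0.08),
                        orthogonalize: bool = False) -> np.ndarray:
    """n zero-mean unit-SD Gaussian series confined to a frequency band.

    With ``orthogonalize`` the series are made mutually orthogonal
    (Gram–Schmidt), so a per-template simple regression is the correct
    estimator of the mixing they generate.
    """
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise ValueError("band contains no resolvable frequencies")
    spec = np.fft.rfft(rng.standard_normal((T, n)), axis=0)
    spec[~keep] = 0.0
    s = np.fft.irfft(spec, n=T, axis=0)
    s -= s.mean(axis=0, keepdims=True)
    if orthogonalize and n > 1:
        q, _ = np.linalg.qr(s)
        sign = np.sign(np.einsum("tk,tk->k", q, s))
        s = q * np.where(sign == 0, 1.0, sign)
        s -= s.mean(axis=0, keepdims=True)
    sd = s.std(axis=0, ddof=0)
    return s / np.where(sd > 0, sd, 1.0)


# --- subject-level simulation ----------------------------------------------

def simulate_subject(config: SimulationConfig,
                     atlases: list[ReceptorAtlas], group: str, seed: int,
                     effect_specs: list[EffectSpec] | None = None,
                     subject: str = "sub"
                     ) -> tuple[np.ndarray, pd.DataFrame, GroundTruthSubject]:
    """Generate one subject's 4D scan, motion table and ground truth."""
    for a in atlases:
        if a.values.shape != tuple(config.grid_shape):
            raise ValueError("atlas grid does not match simulation grid")
    if effect_specs is None:
        effect_specs = default_effect_specs(config)
    layout = tissue_layout(config.grid_shape)
    brain = layout["brain"]
    T, K = config.n_timepoints, len(atlases)
    # one independent substream per generative component, so switching a
    # component off leaves every other realization unchanged
    def sub(tag: int) -> np.random.Generator:
        return np.random.default_rng([config.seed, seed, tag])

    rng_series, rng_nuis, rng_motion = sub(0), sub(1), sub(2)
    rng_trend, rng_spike, rng_noise = sub(3), sub(4), sub(5)

    W, applied = template_loadings(config, atlases, group, effect_specs)
    s = band_limited_series(rng_series, K, T, config.tr,
                            orthogonalize=True)        # T × K
    signal = np.tensordot(W, s, axes=([0], [1]))        # X×Y×Z×T
    support = np.any(W != 0, axis=0)
    # noise/nuisance unit: the mean per-template signal SD over the
    # support (SD of W_k·s_k), so an SNR of 1 means each molecular
    # system's own signal matches the noise regardless of K
    if support.any():
        sig_sd = float(np.sqrt(np.mean(
            [np.mean(W[k][support] ** 2) for k in range(K)])))
    else:
        sig_sd = 1.0
    sig_sd = sig_sd or 1.0

    scan = signal.copy()
    # low-rank tissue nuisance, estimable from WM/CSF by aCompCor
    if config.nuisance_rank > 0:
        for tissue in ("wm", "csf"):
            tmask = layout[tissue]
            basis = band_limited_series(rng_nuis, config.nuisance_rank, T,
                                        config.tr, band=(0.0, 1.0))
            load_t = rng_nuis.normal(
                0.0, 1.0, (tmask.sum(), config.nuisance_rank))
            scan[tmask] += (load_t @ basis.T) * config.nuisance_amp * sig_sd
            gmask = layout["gm"]
            load_g = rng_nuis.normal(0.0, 1.0,
                                (gmask.sum(), config.nuisance_rank))
            scan[gmask] += (load_g @ basis.T) * \
                config.nuisance_gm_amp * sig_sd

    # motion: slow random walks; a correlated spatial drift enters the BOLD
    steps = rng_motion.normal(0.0, 0.02, (T, 6))
    motion = np.cumsum(steps, axis=0)
    if config.motion_amp > 0:
        coupling = rng_motion.normal(0.0, 1.0, (int(brain.sum()), 6))
        m = (motion - motion.mean(axis=0)) / \
            np.where(motion.std(axis=0) > 0, motion.std(axis=0), 1.0)
        scan[brain] += (coupling @ m.T) * config.motion_amp * sig_sd / 6.0

    if config.trend_amp > 0:
        slopes = rng_trend.normal(0.0, 1.0, int(brain.sum()))
        t_lin = np.linspace(-0.5, 0.5, T)
        scan[brain] += np.outer(slopes, t_lin) * config.trend_amp * sig_sd

    if config.spike_rate > 0:
        spike_t = rng_spike.random(T) < config.spike_rate
        if spike_t.any():
            signs = rng_spike.choice([-1.0, 1.0], int(brain.sum()))
            bump = np.outer(signs, spike_t.astype(float))
            scan[brain] += bump * config.spike_amp * sig_sd

    if config.noise_sd > 0:
        scan[brain] += rng_noise.normal(
            0.0, config.noise_sd * sig_sd, (int(brain.sum()), T))

    if config.baseline != 0:
        scan[brain] += config.baseline

    motion_df = pd.DataFrame(
        motion, columns=["tx", "ty", "tz", "rx", "ry", "rz"])
    gt = GroundTruthSubject(subject=subject, group=group, loadings=W,
                            series=s, applied_deltas=applied)
    return scan, motion_df, gt


# --- cohort-level simulation -----------------------------------------------

def make_parcellation(config: SimulationConfig) -> ParcellationImage:
    """Partition the GM into contiguous labelled chunks, one per region.

    Region names cover the two dopaminergic pathway lists plus generic
    cortical fillers; every pathway name resolves to exactly one label.
    """
    layout = tissue_layout(config.grid_shape)
    names = MCL_REGIONS + NST_REGIONS + ["cortical_filler_1",
                                         "cortical_filler_2"]
    gm_idx = np.flatnonzero(layout["gm"].ravel())
    chunks = np.array_split(gm_idx, len(names))
    labels = np.zeros(int(np.prod(config.grid_shape)), dtype=np.int32)
    lookup: dict[int, str] = {}
    for i, (name, chunk) in enumerate(zip(names, chunks), start=1):
        labels[chunk] = i
        lookup[i] = name
    return ParcellationImage(labels=labels.reshape(config.grid_shape),
                             affine=config.affine, lookup=lookup)


def _cognitive_scores(rng: np.random.Generator, config: SimulationConfig,
                      sites: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Raw scores: site-specific CU scales + group shifts in CU-SD units.

    Higher raw Stroop time means worse performance, so the group shift
    enters with opposite sign for that measure.
    """
    n = len(groups)
    cols: dict[str, np.ndarray] = {}
    site_mu = {(st, m): rng.normal(50.0, 10.0)
               for st in config.sites for m in MEASURES}
    site_sd = {(st, m): rng.uniform(8.0, 12.0)
               for st in config.sites for m in MEASURES}
    for m in MEASURES:
        sign = -1.0 if m == "stroop_time" else 1.0
        raw = np.empty(n)
        for i in range(n):
            shift = sign * config.cognitive_effects.get(groups[i], 0.0)
            raw[i] = site_mu[(sites[i], m)] + \
                site_sd[(sites[i], m)] * (shift + rng.standard_normal())
        cols[m] = raw
    df = pd.DataFrame(cols)
    # per-cell missingness plus a few subjects with only three measures,
    # exercising the composite-score exclusion rule
    if config.missing_rate > 0:
        miss = rng.random(df.shape) < config.missing_rate
        df = df.mask(miss)
    if config.few_measures_rate > 0:
        for i in range(n):
            if rng.random() < config.few_measures_rate:
                keep = rng.choice(MEASURES, size=3, replace=False)
                df.loc[i, [m for m in MEASURES if m not in keep]] = np.nan
    return df


def simulate_cohort(config: SimulationConfig, out_dir: str | Path,
                    effect_specs: list[EffectSpec] | None = None,
                    overwrite: bool = False) -> dict:
    """Write a full synthetic cohort to disk and return its manifest.

    Produces per-subject 4D NIfTI scans and motion TSVs, the K template
    NIfTIs, tissue probability maps, GM mask, labelled parcellation, the
    cohort TSV and a JSON manifest referencing every file together with
    the ground-truth records.
    """
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} exists; pass overwrite=True to replace it")
    out.mkdir(parents=True, exist_ok=True)
    if effect_specs is None:
        effect_specs = default_effect_specs(config)

    layout = tissue_layout(config.grid_shape)
    affine = config.affine
    rng = np.random.default_rng([config.seed, 7])

    def save(vol: np.ndarray, rel: str, dtype=np.float64) -> str:
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=dtype), affine), path)
        return rel

    atlases = [make_atlas(config, k) for k in range(config.n_templates)]
    atlas_files = {a.name: save(a.values, f"atlases/{a.name}.nii.gz")
                   for a in atlases}
    ref_files = {a.name: save(a.reference_mask.astype(np.uint8),
                              f"atlases/{a.name}_refmask.nii.gz", np.uint8)
                 for a in atlases}

    # tissue probability maps: hard layout softened at values 0.9/0.05
    tissue_files = {}
    for tissue in ("gm", "wm", "csf"):
        prob = np.where(layout[tissue], 0.9, 0.0)
        prob += np.where(layout["brain"] & ~layout[tissue], 0.05, 0.0)
        tissue_files[tissue] = save(prob, f"tissue/{tissue}_prob.nii.gz")
    gm_mask_file = save(layout["gm"].astype(np.uint8),
                        "masks/gm_mask.nii.gz", np.uint8)
    wm_mask_file = save(layout["wm"].astype(np.uint8),
                        "masks/wm_mask.nii.gz", np.uint8)
    csf_mask_file = save(layout["csf"].astype(np.uint8),
                         "masks/csf_mask.nii.gz", np.uint8)

    parc = make_parcellation(config)
    parc_file = save(parc.labels, "parcellation/parcellation.nii.gz",
                     np.int32)
    labels_df = pd.DataFrame(
        {"label": list(parc.lookup), "name": list(parc.lookup.values())})
    labels_df.to_csv(out / "parcellation/labels.tsv", sep="\t", index=False)

    # subjects
    groups = [g for g, n in zip(GROUPS, config.n_per_group) for _ in range(n)]
    n_sub = len(groups)
    shares = np.asarray(config.site_shares, dtype=float)
    sites = rng.choice(config.sites, size=n_sub, p=shares / shares.sum())
    sexes = rng.choice(["M", "F"], size=n_sub, p=[0.45, 0.55])
    ages = np.round(rng.normal(70.0, 8.0, n_sub), 1)
    edu = np.clip(np.round(rng.normal(12.5, 3.5, n_sub), 0), 5, 22)
    tiv = np.round(np.exp(rng.normal(np.log(1450.0), 0.1, n_sub)), 1)

    subjects, gt_records = [], []
    for i, group in enumerate(groups):
        sid = f"sub-{i:03d}"
        scan, motion_df, gt = simulate_subject(
            config, atlases, group, seed=i, effect_specs=effect_specs,
            subject=sid)
        scan_file = save(scan, f"{sid}/func.nii.gz")
        motion_file = f"{sid}/motion.tsv"
        motion_df.to_csv(out / motion_file, sep="\t", index=False)
        gt_dir = out / "ground_truth"
        gt_dir.mkdir(exist_ok=True)
        loadings_file = save(np.moveaxis(gt.loadings, 0, -1),
                             f"ground_truth/{sid}_loadings.nii.gz")
        series_df = pd.DataFrame(
            gt.series, columns=[a.name for a in atlases])
        series_file = f"ground_truth/{sid}_series.tsv"
        series_df.to_csv(out / series_file, sep="\t", index=False)
        subjects.append({
            "subject": sid, "group": group, "site": str(sites[i]),
            "scan": scan_file, "motion": motion_file,
            "loadings": loadings_file, "series": series_file,
            "applied_deltas": {str(k): v
                               for k, v in gt.applied_deltas.items()}})
        gt_records.append(gt)

    # biomarker status: patients likelier positive; site S3 unmeasured
    p_pos = {"CU": 0.05, "MCI": 0.6, "dementia": 0.7}
    abeta, ptau = [], []
    for i, group in enumerate(groups):
        if sites[i] == config.sites[-1]:
            abeta.append("")
            ptau.append("")
        else:
            abeta.append("pos" if rng.random() < p_pos[group] else "neg")
            ptau.append("pos" if rng.random() < p_pos[group] else "neg")

    cog = _cognitive_scores(rng, config, sites, np.asarray(groups))
    cohort = pd.DataFrame({
        "subject": [s["subject"] for s in subjects],
        "group": groups, "site": sites, "age": ages, "education": edu,
        "sex": sexes, "tiv": tiv, "abeta_status": abeta,
        "ptau_status": ptau})
    cohort = pd.concat([cohort, cog], axis=1)
    cohort_file = "cohort.tsv"
    cohort.to_csv(out / cohort_file, sep="\t", index=False,
                  float_format="%.6g")

    manifest = {
        "version": "molfc-0.1.0",
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()
                   if k != "effect_specs"},
        "effect_specs": [
            {"template_index": e.template_index, "center": list(e.center),
             "radius": e.radius, "deltas": e.deltas}
            for e in effect_specs],
        "atlases": atlas_files,
        "atlas_reference_masks": ref_files,
        "tissue": tissue_files,
        "gm_mask": gm_mask_file,
        "wm_mask": wm_mask_file,
        "csf_mask": csf_mask_file,
        "parcellation": parc_file,
        "parcellation_labels": "parcellation/labels.tsv",
        "cohort": cohort_file,
        "subjects": subjects,
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
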