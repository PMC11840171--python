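"""End-to-end driver: YAML config, stage orchestration, run records.

The pipeline runs simulate (optional) → atlas preparation → mask building
→ denoising → dual regression (whole-brain and pathway-restricted) →
cognitive scoring → voxel-wise group GLM with permutation cluster
inference. Every stage writes its outputs under the run directory together
with a sentinel recording the configuration hash, so an unchanged rerun
skips completed stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import atlas as atlas_mod
from . import cognition as cog_mod
from . import denoise as dn
from . import stats as stats_mod
from .react import FCMap, react_pathway, stage1_timeseries, stage2_fcmap
from .synthetic import EffectSpec, SimulationConfig, simulate_cohort

log = logging.getLogger("molfc")

DEFAULT_CONFIG = {
    "version": 1,
    "out_dir": "molfc_run",
    "simulate": {},                      # SimulationConfig overrides
    "denoise": {"band": [0.008, 0.1], "despike_k": 4.0,
                "filter_design": "fft", "n_compcor": 5},
    "react": {"pathways": ["mcl", "nst"], "pathway_atlas": "DAT"},
    "cognition": {"direction_flips": ["stroop_time"]},
    "glm": {"forming_p": 0.001, "n_perm": 500, "seed": 7,
            "contrast": "group_f"},
}

_ALLOWED_KEYS = set(DEFAULT_CONFIG)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    bad = set(user) - _ALLOWED_KEYS
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    cfg = {k: (dict(v, **user.get(k, {})) if isinstance(v, dict) else
               user.get(k, v))
           for k, v in DEFAULT_CONFIG.items()}
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage_done(out: Path, stage: str, h: str) -> bool:
    sentinel = out / "run_log" / f"{stage}.json"
    if not sentinel.exists():
        return False
    rec = json.loads(sentinel.read_text())
    return rec.get("config_hash") == h


def _mark_done(out: Path, stage: str, h: str, seconds: float,
               extra: dict | None = None) -> None:
    d = out / "run_log"
    d.mkdir(parents=True, exist_ok=True)
    rec = {"stage": stage, "config_hash": h, "wall_seconds": round(seconds, 3)}
    if extra:
        rec.update(extra)
    (d / f"{stage}.json").write_text(json.dumps(rec, indent=2))


def _load(out: Path, rel: str) -> np.ndarray:
    return np.asarray(nib.load(out / rel).dataobj, dtype=float)


def run_pipeline(config_path: str | Path,
                 out_dir: str | Path | None = None) -> Path:
    """Run every stage described by the YAML config; returns the run dir."""
    cfg = load_config(config_path)
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    h = config_hash(cfg)

    # --- simulate ---------------------------------------------------------
    t0 = time.time()
    if not _stage_done(out, "simulate", h):
        sim_kwargs = dict(cfg["simulate"])
        for key in ("n_per_group", "grid_shape", "sites", "site_shares"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        effect_specs = None
        if "effect_specs" in sim_kwargs:
            effect_specs = [EffectSpec(
                template_index=e["template_index"],
                center=tuple(e["center"]), radius=e["radius"],
                deltas=e["deltas"]) for e in sim_kwargs.pop("effect_specs")]
        sim_cfg = SimulationConfig(**sim_kwargs)
        simulate_cohort(sim_cfg, out / "data", effect_specs=effect_specs,
                        overwrite=True)
        _mark_done(out, "simulate", h, time.time() - t0)
        log.info("simulate: %.1fs", time.time() - t0)
    else:
        log.info("simulate: skipped (up to date)")

    data = out / "data"
    manifest = json.loads((data / "manifest.json").read_text())
    affine = nib.load(data / manifest["gm_mask"]).affine
    gm_mask = _load(data, manifest["gm_mask"]) > 0.5
    wm_mask = _load(data, manifest["wm_mask"]) > 0.5
    csf_mask = _load(data, manifest["csf_mask"]) > 0.5
    subjects = manifest["subjects"]
    tr = manifest["config"]["tr"]

    # --- atlas preparation + masks ---------------------------------------
    t0 = time.time()
    atlases = []
    for name, rel in manifest["atlases"].items():
        raw = atlas_mod.ReceptorAtlas(_load(data, rel), affine, name=name)
        ref = _load(data, manifest["atlas_reference_masks"][name]) > 0.5
        masked = atlas_mod.mask_reference_region(raw, ref)
        atlases.append(atlas_mod.rescale_unit(masked))
    scans = {s["subject"]: _load(data, s["scan"]) for s in subjects}
    masks = atlas_mod.build_masks(list(scans.values()), atlases, gm_mask,
                                  affine=affine)
    parc_labels = np.asarray(
        nib.load(data / manifest["parcellation"]).dataobj).astype(int)
    lut = pd.read_csv(data / manifest["parcellation_labels"], sep="\t")
    parc = atlas_mod.ParcellationImage(
        labels=parc_labels, affine=affine,
        lookup=dict(zip(lut["label"], lut["name"])))
    pathway_masks = {
        "mcl": atlas_mod.build_pathway_mask(parc, atlas_mod.MCL_REGIONS),
        "nst": atlas_mod.build_pathway_mask(parc, atlas_mod.NST_REGIONS),
    }
    log.info("prep: %.1fs", time.time() - t0)

    # --- denoise ----------------------------------------------------------
    t0 = time.time()
    dn_cfg = cfg["denoise"]
    denoised: dict[str, dn.DenoisedScan] = {}
    den_dir = out / "denoised"
    den_dir.mkdir(exist_ok=True)
    skip_denoise = _stage_done(out, "denoise", h)
    for s in subjects:
        sid = s["subject"]
        path = den_dir / f"{sid}_denoised.nii.gz"
        if skip_denoise and path.exists():
            img = nib.load(path)
            arr = np.asarray(img.dataobj, dtype=float)
            denoised[sid] = dn.DenoisedScan(
                data=arr, affine=img.affine, tr=tr,
                valid_mask=np.var(arr, axis=3) > 0)
            continue
        motion = pd.read_csv(data / s["motion"], sep="\t").to_numpy()
        scan = scans[sid]
        wm_pc = dn.acompcor(scan, wm_mask, dn_cfg["n_compcor"])
        csf_pc = dn.acompcor(scan, csf_mask, dn_cfg["n_compcor"])
        conf = dn.build_confounds(motion, wm_pc, csf_pc, tr)
        denoised[sid] = dn.denoise_pipeline(
            scan, affine, conf, band=tuple(dn_cfg["band"]),
            despike_k=dn_cfg["despike_k"],
            filter_design=dn_cfg["filter_design"])
        nib.save(nib.Nifti1Image(
            denoised[sid].data.astype(np.float32), affine), path)
    if not skip_denoise:
        _mark_done(out, "denoise", h, time.time() - t0)
    log.info("denoise: %.1fs", time.time() - t0)

    # --- dual regression --------------------------------------------------
    t0 = time.time()
    fc_dir = out / "fc"
    fc_dir.mkdir(exist_ok=True)
    skip_react = _stage_done(out, "react", h)
    fc_maps: dict[tuple[str, str, str], FCMap] = {}
    pathway_atlas = cfg["react"].get("pathway_atlas", "DAT")
    for s in subjects:
        sid = s["subject"]
        series_rows = {}
        for a in atlases:
            key = (sid, a.name, "none")
            path = fc_dir / f"{sid}_{a.name}_fc.nii.gz"
            if skip_react and path.exists():
                img = nib.load(path)
                fc_maps[key] = FCMap(
                    betas=np.asarray(img.dataobj, dtype=float),
                    mask=masks.atlas_independent, affine=img.affine,
                    atlas=a.name, subject=sid)
                continue
            series = stage1_timeseries(
                denoised[sid], a, masks.atlas_specific[a.name], subject=sid)
            series_rows[a.name] = series.values
            fc_maps[key] = stage2_fcmap(
                denoised[sid], series.zscored(), masks.atlas_independent)
            nib.save(nib.Nifti1Image(
                fc_maps[key].betas.astype(np.float32), affine), path)
        for pw in cfg["react"]["pathways"]:
            a = next((x for x in atlases if x.name == pathway_atlas), None)
            if a is None:
                continue
            key = (sid, a.name, pw)
            path = fc_dir / f"{sid}_{a.name}_{pw}_fc.nii.gz"
            if skip_react and path.exists():
                img = nib.load(path)
                fc_maps[key] = FCMap(
                    betas=np.asarray(img.dataobj, dtype=float),
                    mask=masks.atlas_independent, affine=img.affine,
                    atlas=a.name, subject=sid, pathway=pw)
                continue
            fc_maps[key] = react_pathway(
                denoised[sid], a, pathway_masks[pw],
                masks.atlas_specific[a.name], masks.atlas_independent,
                pathway=pw, subject=sid)
            nib.save(nib.Nifti1Image(
                fc_maps[key].betas.astype(np.float32), affine), path)
        if series_rows:
            pd.DataFrame(series_rows).to_csv(
                fc_dir / f"{sid}_series.tsv", sep="\t", index=False)
    if not skip_react:
        _mark_done(out, "react", h, time.time() - t0)
    log.info("react: %.1fs", time.time() - t0)

    # --- cognition --------------------------------------------------------
    cohort = pd.read_csv(data / manifest["cohort"], sep="\t")
    flips = frozenset(cfg["cognition"]["direction_flips"])
    scored = cog_mod.add_composite(
        cog_mod.zscore_by_site(cohort), direction_flips=flips)
    scored.to_csv(out / "cohort_scored.tsv", sep="\t", index=False,
                  float_format="%.6g")

    # --- group GLM + cluster inference ------------------------------------
    t0 = time.time()
    glm_cfg = cfg["glm"]
    design = stats_mod.build_design(scored)
    contrast = stats_mod.group_f_contrast(design)
    glm_dir = out / "glm"
    glm_dir.mkdir(exist_ok=True)
    for a in atlases:
        stack = np.stack([fc_maps[(s["subject"], a.name, "none")].betas
                          for s in subjects])
        stat = stats_mod.fit_voxelwise_glm(
            stack, design, contrast, mask=masks.atlas_independent,
            affine=affine)
        nib.save(nib.Nifti1Image(stat.values.astype(np.float32), affine),
                 glm_dir / f"{a.name}_group_F.nii.gz")
        table = stats_mod.cluster_inference(
            stack, design, contrast, forming_p=glm_cfg["forming_p"],
            n_perm=glm_cfg["n_perm"], seed=glm_cfg["seed"],
            mask=masks.atlas_independent, affine=affine)
        table.to_csv(glm_dir / f"{a.name}_group_clusters.tsv", sep="\t",
                     index=False)
    record = {"seed": glm_cfg["seed"], "n_perm": glm_cfg["n_perm"],
              "forming_p": glm_cfg["forming_p"], "contrast": "group_f",
              "config_hash": h}
    (glm_dir / "run_record.json").write_text(json.dumps(record, indent=2))
    _mark_done(out, "glm", h, time.time() - t0)
    log.info("glm: %.1fs", time.time() - t0)
    return out
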