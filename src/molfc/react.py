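"""Receptor-enriched functional connectivity by two-stage dual regression.

Stage 1 uses a molecular density template as a *spatial* regressor: at each
timepoint the in-mask voxel values are regressed on [intercept, demeaned
template], and the template coefficients across time form a subject-specific
time series of BOLD fluctuations weighted by the receptor/transporter
distribution. Stage 2 uses that series (z-scored) as a *temporal* regressor:
each voxel's time course is regressed on [intercept, series], and the series
coefficient is the voxel's molecular FC value.

Each template is fitted in its own independent model — simple regression in
both stages — rather than one multivariate model over all templates.
Pathway-restricted variants re-run stage 1 inside a pathway mask while
stage 2 still covers the whole-brain grey-matter mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import MaskSet, ReceptorAtlas
from .denoise import DenoisedScan


@dataclass
class MolecularTimeSeries:
    """Stage-1 output: one T-length series per (subject, atlas)."""

    values: np.ndarray
    atlas: str
    subject: str = ""
    normalization: str = "none"

    def zscored(self) -> "MolecularTimeSeries":
        v = np.asarray(self.values, dtype=float)
        sd = v.std(ddof=0)
        if sd == 0:
            raise ValueError(
                f"stage-1 series for atlas '{self.atlas}' has zero variance")
        return MolecularTimeSeries(values=(v - v.mean()) / sd,
                                   atlas=self.atlas, subject=self.subject,
                                   normalization="zscore")


@dataclass
class FCMap:
    """Stage-2 output: voxel-wise regression coefficients on one grid.

    Values are defined (finite) inside ``mask`` and stored as 0 outside.
    """

    betas: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    atlas: str
    subject: str = ""
    pathway: str = "none"


def stage1_timeseries(scan: DenoisedScan, atlas: ReceptorAtlas,
                      stage1_mask: np.ndarray,
                      subject: str = "") -> MolecularTimeSeries:
    """Spatial regression: template density explains each volume's pattern.

    For each timepoint t, OLS of the in-mask voxel values Y(·, t) on
    [intercept, demeaned template]; the template coefficient series is
    returned un-normalized.
    """
    mask = np.asarray(stage1_mask).astype(bool)
    if not mask.any():
        raise ValueError("empty stage-1 mask")
    if atlas.values.shape != scan.data.shape[:3]:
        raise ValueError("atlas grid does not match scan")
    a = atlas.values[mask].astype(float)
    a = a - a.mean()
    denom = float(a @ a)
    if denom <= 0:
        raise ValueError(
            f"atlas '{atlas.name}' is constant within the stage-1 mask")
    Y = scan.data[mask]                       # V × T
    # intercept+single-regressor OLS closed form, vectorized over t
    series = a @ (Y - Y.mean(axis=0, keepdims=True)) / denom
    return MolecularTimeSeries(values=series, atlas=atlas.name,
                               subject=subject)


def stage2_fcmap(scan: DenoisedScan, series: MolecularTimeSeries,
                 stage2_mask: np.ndarray, pathway: str = "none") -> FCMap:
    """Temporal regression: the molecular series explains each voxel.

    Per in-mask voxel, OLS of the voxel time series on [intercept,
    z-scored series]; the series beta is the FC value.
    """
    if series.normalization != "zscore":
        series = series.zscored()
    s = np.asarray(series.values, dtype=float)
    T = scan.data.shape[3]
    if s.shape[0] != T:
        raise ValueError("series length does not match scan timepoints")
    mask = np.asarray(stage2_mask).astype(bool)
    if not mask.any():
        raise ValueError("empty stage-2 mask")
    denom = float(s @ s)                      # s is demeaned, unit SD
    Y = scan.data[mask]                       # V × T
    betas3d = np.zeros(scan.data.shape[:3])
    betas3d[mask] = (Y - Y.mean(axis=1, keepdims=True)) @ s / denom
    return FCMap(betas=betas3d, mask=mask, affine=scan.affine,
                 atlas=series.atlas, subject=series.subject, pathway=pathway)


def react(scan: DenoisedScan, atlases: list[ReceptorAtlas], masks: MaskSet,
          subject: str = "") -> list[FCMap]:
    """Whole-brain dual regression, one independent model per template."""
    maps = []
    for atlas in atlases:
        if atlas.name not in masks.atlas_specific:
            raise KeyError(f"no atlas-specific mask for '{atlas.name}'")
        series = stage1_timeseries(scan, atlas,
                                   masks.atlas_specific[atlas.name],
                                   subject=subject)
        maps.append(stage2_fcmap(scan, series.zscored(),
                                 masks.atlas_independent))
    return maps


def react_pathway(scan: DenoisedScan, atlas: ReceptorAtlas,
                  pathway_mask: np.ndarray, stage1_mask: np.ndarray,
                  stage2_mask: np.ndarray, pathway: str = "pathway",
                  subject: str = "") -> FCMap:
    """Pathway-restricted dual regression for one template.

    Stage 1 runs inside pathway_mask ∩ atlas-specific mask; stage 2 covers
    the whole-brain grey-matter mask, yielding FC between the pathway's
    molecular system and the entire brain.
    """
    m1 = np.asarray(pathway_mask).astype(bool) & \
        np.asarray(stage1_mask).astype(bool)
    if not m1.any():
        raise ValueError(
            f"pathway '{pathway}' does not intersect the atlas-specific mask")
    series = stage1_timeseries(scan, atlas, m1, subject=subject)
    return stage2_fcmap(scan, series.zscored(), stage2_mask, pathway=pathway)
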