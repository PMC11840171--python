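"""Molecular density atlases: normalization, analysis masks, tissue volumes.

A receptor/transporter density atlas becomes a spatial regressor in three
steps: resample onto the functional grid, mask out its reference region
(the region used for tracer quantification, which carries no specific
binding signal), and min-max rescale the remaining voxels to [0, 1].

This module also builds the analysis masks used by the two-stage dual
regression: one atlas-specific mask per template (coverage ∩ atlas support
∩ grey matter) and a single atlas-independent mask (coverage ∩ grey
matter), plus binary pathway masks assembled from a labelled parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from nilearn.image import resample_img


@dataclass
class ReceptorAtlas:
    """A 3D nonnegative density map with world affine.

    ``reference_mask`` marks voxels belonging to the tracer reference
    region; they are forced to zero and excluded from rescaling
    statistics. ``reference_region`` is its human-readable name
    ("none" when the atlas uses no reference-region method).
    """

    values: np.ndarray
    affine: np.ndarray
    name: str = "atlas"
    reference_region: str = "none"
    reference_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("atlas values must be a 3D grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("atlas values must be finite")

    def to_image(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.float32), self.affine)

    @classmethod
    def from_image(cls, img: nib.Nifti1Image, name: str = "atlas",
                   reference_region: str = "none") -> "ReceptorAtlas":
        return cls(np.asarray(img.dataobj, dtype=float), img.affine,
                   name=name, reference_region=reference_region)


@dataclass
class MaskSet:
    """The seven analysis masks plus optional pathway masks.

    Every atlas-specific mask is a subset of the atlas support intersected
    with the atlas-independent mask; all grids share one geometry.
    """

    atlas_specific: dict[str, np.ndarray]
    atlas_independent: np.ndarray
    affine: np.ndarray
    pathway: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class ParcellationImage:
    """Integer-labelled brain parcellation; label 0 is background."""

    labels: np.ndarray
    affine: np.ndarray
    lookup: dict[int, str]

    def labels_for(self, names: list[str]) -> list[int]:
        by_name = {v: k for k, v in self.lookup.items()}
        missing = [n for n in names if n not in by_name]
        if missing:
            raise KeyError(f"region names not in parcellation: {missing}")
        return [by_name[n] for n in names]


# Default afferent-region lists for the two dopaminergic pathways.
MCL_REGIONS = [
    "nucleus_accumbens", "amygdala", "hippocampus", "entorhinal_cortex",
    "parahippocampal_gyrus", "cingulate_gyrus", "subcallosal_gyrus",
    "lateral_orbitofrontal_cortex", "lateral_superior_frontal_gyrus",
    "medial_superior_frontal_gyrus", "middle_frontal_gyrus",
    "orbital_inferior_frontal_gyrus",
]
NST_REGIONS = ["caudate_nucleus", "putamen", "globus_pallidus"]


def resample_to_grid(atlas: ReceptorAtlas, target_shape: tuple[int, int, int],
                     target_affine: np.ndarray) -> ReceptorAtlas:
    """Resample a density atlas onto a target grid by trilinear interpolation.

    Voxels outside the source support are filled with 0. If the geometry
    already matches, the atlas is returned unchanged.
    """
    target_affine = np.asarray(target_affine, dtype=float)
    if abs(np.linalg.det(target_affine[:3, :3])) < 1e-12 or \
            abs(np.linalg.det(atlas.affine[:3, :3])) < 1e-12:
        raise ValueError("non-invertible affine")
    if atlas.values.shape == tuple(target_shape) and \
            np.allclose(atlas.affine, target_affine):
        return atlas
    out = resample_img(atlas.to_image(), target_affine=target_affine,
                       target_shape=tuple(target_shape),
                       interpolation="continuous", fill_value=0.0,
                       force_resample=True, copy_header=True)
    ref_mask = None
    if atlas.reference_mask is not None:
        ref_img = nib.Nifti1Image(
            atlas.reference_mask.astype(np.float32), atlas.affine)
        ref_out = resample_img(ref_img, target_affine=target_affine,
                               target_shape=tuple(target_shape),
                               interpolation="nearest", fill_value=0.0,
                               force_resample=True, copy_header=True)
        ref_mask = np.asarray(ref_out.dataobj) > 0.5
    return ReceptorAtlas(np.asarray(out.dataobj, dtype=float), target_affine,
                         name=atlas.name,
                         reference_region=atlas.reference_region,
                         reference_mask=ref_mask)


def mask_reference_region(atlas: ReceptorAtlas, ref_mask: np.ndarray,
                          region_name: str = "reference") -> ReceptorAtlas:
    """Zero out the reference region and record it for later rescaling.

    Reference voxels are excluded from the min/max statistics that
    :func:`rescale_unit` computes, not merely set to zero.
    """
    ref_mask = np.asarray(ref_mask).astype(bool)
    if ref_mask.shape != atlas.values.shape:
        raise ValueError("reference mask shape does not match atlas grid")
    nonzero = atlas.values != 0
    if nonzero.any() and not (nonzero & ~ref_mask).any():
        raise ValueError("reference mask covers all nonzero atlas voxels")
    values = atlas.values.copy()
    values[ref_mask] = 0.0
    return replace(atlas, values=values, reference_region=region_name,
                   reference_mask=ref_mask)


def rescale_unit(atlas: ReceptorAtlas) -> ReceptorAtlas:
    """Min-max rescale to [0, 1] over non-reference voxels.

    Reference-region voxels stay at exactly 0 and never enter the min/max.
    """
    keep = np.ones(atlas.values.shape, dtype=bool)
    if atlas.reference_mask is not None:
        keep &= ~atlas.reference_mask
    if not keep.any():
        raise ValueError("no voxels outside the reference region")
    vmin = atlas.values[keep].min()
    vmax = atlas.values[keep].max()
    if vmax <= vmin:
        raise ValueError(f"atlas '{atlas.name}' is constant; cannot rescale")
    values = np.zeros_like(atlas.values)
    values[keep] = (atlas.values[keep] - vmin) / (vmax - vmin)
    return replace(atlas, values=values)


def coverage_mask(scans: list[np.ndarray]) -> np.ndarray:
    """Voxels with nonzero temporal variance in every subject's 4D scan."""
    if not scans:
        raise ValueError("no scans provided")
    cov = np.ones(scans[0].shape[:3], dtype=bool)
    for scan in scans:
        if scan.shape[:3] != cov.shape:
            raise ValueError("scan grids are not aligned")
        cov &= np.var(np.asarray(scan, dtype=float), axis=3) > 0
    return cov


def build_masks(scans: list[np.ndarray], atlases: list[ReceptorAtlas],
                gm_mask: np.ndarray, affine: np.ndarray | None = None
                ) -> MaskSet:
    """Build the atlas-specific and atlas-independent analysis masks.

    coverage = nonzero temporal variance in every subject;
    atlas_specific[a] = coverage ∩ (atlas a > 0) ∩ GM;
    atlas_independent = coverage ∩ GM.
    """
    gm = np.asarray(gm_mask).astype(bool)
    cov = coverage_mask(scans)
    if cov.shape != gm.shape:
        raise ValueError("scan and GM mask grids are not aligned")
    independent = cov & gm
    if not independent.any():
        raise ValueError("empty mask: atlas_independent (coverage ∩ GM)")
    specific: dict[str, np.ndarray] = {}
    for atlas in atlases:
        if atlas.values.shape != gm.shape:
            raise ValueError(f"atlas '{atlas.name}' grid is not aligned")
        m = independent & (atlas.values > 0)
        if not m.any():
            raise ValueError(f"empty mask: atlas_specific[{atlas.name}]")
        specific[atlas.name] = m
    if affine is None:
        affine = atlases[0].affine if atlases else np.eye(4)
    return MaskSet(atlas_specific=specific, atlas_independent=independent,
                   affine=np.asarray(affine, dtype=float))


def build_pathway_mask(parcellation: ParcellationImage,
                       region_names: list[str]) -> np.ndarray:
    """Union of the named parcellation regions as a binary grid."""
    wanted = parcellation.labels_for(region_names)
    mask = np.isin(parcellation.labels, wanted)
    if not mask.any():
        raise ValueError(f"pathway mask is empty for regions {region_names}")
    return mask


def tissue_volume(prob_map: np.ndarray, affine: np.ndarray) -> float:
    """Volume in millilitres of a tissue probability map.

    sum(probabilities) × voxel volume in mm³ / 1000.
    """
    prob = np.asarray(prob_map, dtype=float)
    if (prob < 0).any():
        raise ValueError("negative probabilities in tissue map")
    if (prob > 1).any():
        raise ValueError("tissue probabilities must be ≤ 1")
    voxel_mm3 = float(abs(np.linalg.det(np.asarray(affine)[:3, :3])))
    return float(prob.sum() * voxel_mm3 / 1000.0)


def total_intracranial_volume(gm: np.ndarray, wm: np.ndarray,
                              csf: np.ndarray, affine: np.ndarray) -> float:
    """TIV in ml as the sum of GM, WM and CSF tissue volumes."""
    return (tissue_volume(gm, affine) + tissue_volume(wm, affine)
            + tissue_volume(csf, affine))
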