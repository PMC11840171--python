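"""Group-level inference: voxel-wise GLMs, permutation cluster-extent FWE,
and the scalar demographic tests.

Voxel-wise models are ordinary least squares with group indicators
(cell-means coding) plus age, education, sex, TIV and site covariates, and
optionally a continuous cognitive regressor. Group differences are tested
with an F contrast, pairwise comparisons and regression slopes with t
contrasts, all within the full model.

Cluster-extent family-wise error correction uses Freedman–Lane permutation:
the data are residualized against the nuisance partition of the design,
subject rows of the residuals are permuted, the nuisance fit is added back,
and the full-model statistic map is recomputed; each observed cluster's FWE
p-value is the proportion of permutations whose *maximal* cluster extent
reaches its extent. Clusters are defined by 18-connectivity
(faces + edges) above the parametric quantile of the cluster-forming
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

GROUPS = ["CU", "MCI", "dementia"]

# 3D structuring element connecting faces and edges but not corners
CONNECTIVITY_18 = ndimage.generate_binary_structure(3, 2)


@dataclass
class DesignMatrix:
    """Subjects × predictors design with named columns."""

    values: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise ValueError(
                f"design matrix is rank deficient; columns: {self.columns}")

    def contrast_vector(self, spec: dict[str, float]) -> np.ndarray:
        c = np.zeros(len(self.columns))
        for name, w in spec.items():
            c[self.columns.index(name)] = w
        return c


@dataclass
class StatMap:
    """A 3D map of t or F statistics with its degrees of freedom."""

    values: np.ndarray
    kind: str                    # "t" | "F"
    dof: int
    dof_num: int = 1             # numerator dof for F
    affine: np.ndarray | None = None
    mask: np.ndarray | None = None


def build_design(cohort: pd.DataFrame, group_col: str = "group",
                 covariates: tuple[str, ...] = ("age", "education", "sex",
                                                "tiv", "site"),
                 continuous: str | None = None) -> DesignMatrix:
    """Cell-means group coding plus centred/dummy-coded covariates.

    Categorical covariates (sex, site) are dummy-coded with the first
    level as reference; continuous covariates are mean-centred so the
    group columns keep their interpretation as adjusted group means.
    """
    cols, names = [], []
    for g in GROUPS:
        indicator = (cohort[group_col] == g).to_numpy(dtype=float)
        if indicator.sum() == 0:
            continue
        cols.append(indicator)
        names.append(f"group_{g}")
    for cov in covariates:
        if cov not in cohort.columns:
            raise KeyError(f"covariate '{cov}' missing from cohort table")
        series = cohort[cov]
        if series.dtype == object or str(series.dtype) == "category":
            levels = sorted(series.unique())
            for lev in levels[1:]:
                cols.append((series == lev).to_numpy(dtype=float))
                names.append(f"{cov}_{lev}")
        else:
            v = series.to_numpy(dtype=float)
            cols.append(v - v.mean())
            names.append(cov)
    if continuous is not None:
        v = cohort[continuous].to_numpy(dtype=float)
        cols.append(v - v.mean())
        names.append(continuous)
    return DesignMatrix(values=np.column_stack(cols), columns=names)


def group_f_contrast(design: DesignMatrix) -> np.ndarray:
    """All-groups-equal F contrast over the group columns present."""
    group_cols = [c for c in design.columns if c.startswith("group_")]
    if len(group_cols) < 2:
        raise ValueError("need at least two group columns for an F contrast")
    rows = []
    for a, b in zip(group_cols[:-1], group_cols[1:]):
        rows.append(design.contrast_vector({a: 1.0, b: -1.0}))
    return np.vstack(rows)


def _ols_stats(Y: np.ndarray, X: np.ndarray, C: np.ndarray,
               pinvX: np.ndarray, CXtXiCt_inv: np.ndarray,
               dof: int) -> np.ndarray:
    """t or F statistics per column of Y for contrast C (q×p)."""
    beta = pinvX @ Y
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    sigma2 = np.where(sigma2 > 0, sigma2, np.inf)
    cb = C @ beta                              # q × V
    if C.shape[0] == 1:
        return (cb[0] / np.sqrt(sigma2 * CXtXiCt_inv[0, 0]))
    quad = np.einsum("qv,qr,rv->v", cb, CXtXiCt_inv, cb)
    return quad / (C.shape[0] * sigma2)


def fit_voxelwise_glm(maps: np.ndarray, design: DesignMatrix,
                      contrast: np.ndarray,
                      mask: np.ndarray | None = None,
                      affine: np.ndarray | None = None) -> StatMap:
    """Per-voxel OLS over a subjects × X × Y × Z stack.

    A 1-row contrast yields a t map, a multi-row contrast an F map;
    dof = n − rank(design). Voxels that are non-finite in any subject are
    excluded from the analysis mask.
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if n != design.values.shape[0]:
        raise ValueError("subject count mismatch between maps and design")
    finite = np.all(np.isfinite(maps), axis=0)
    mask = finite if mask is None else (np.asarray(mask).astype(bool) & finite)
    X = design.values
    C = np.atleast_2d(np.asarray(contrast, dtype=float))
    dof = n - np.linalg.matrix_rank(X)
    pinvX = np.linalg.pinv(X)
    XtXi = np.linalg.inv(X.T @ X)
    CXtXiCt_inv = C @ XtXi @ C.T
    if C.shape[0] > 1:
        CXtXiCt_inv = np.linalg.inv(CXtXiCt_inv)
    Y = maps[:, mask]
    stat = _ols_stats(Y, X, C, pinvX, CXtXiCt_inv, dof)
    out = np.zeros(maps.shape[1:])
    out[mask] = stat
    kind = "t" if C.shape[0] == 1 else "F"
    return StatMap(values=out, kind=kind, dof=dof, dof_num=C.shape[0],
                   affine=affine, mask=mask)


def _freedman_lane_partition(X: np.ndarray, C: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Split the design into effect-of-interest and nuisance partitions.

    Following the standard contrast-based partitioning: the columns of
    interest are X C⁺ and the nuisance partition spans X (I − C⁺C).
    """
    Cp = np.linalg.pinv(C)
    M = X @ Cp
    Z_raw = X @ (np.eye(X.shape[1]) - Cp @ C)
    # drop numerically null columns of the nuisance span
    u, s, _ = np.linalg.svd(Z_raw, full_matrices=False)
    keep = s > (s[0] * 1e-10 if s.size and s[0] > 0 else np.inf)
    Z = u[:, keep] * s[keep]
    return M, Z


def _threshold(stat: StatMap, forming_p: float) -> float:
    if stat.kind == "t":
        return float(sps.t.ppf(1.0 - forming_p, stat.dof))
    return float(sps.f.ppf(1.0 - forming_p, stat.dof_num, stat.dof))


def _cluster_extents(binary: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    labels, n_clusters = ndimage.label(binary, structure=CONNECTIVITY_18)
    if n_clusters == 0:
        return labels, 0, np.array([], dtype=int)
    extents = ndimage.sum_labels(np.ones_like(labels), labels,
                                 index=np.arange(1, n_clusters + 1))
    return labels, n_clusters, extents.astype(int)


def cluster_inference(maps: np.ndarray, design: DesignMatrix,
                      contrast: np.ndarray, forming_p: float = 0.001,
                      n_perm: int = 1000, seed: int = 0,
                      mask: np.ndarray | None = None,
                      affine: np.ndarray | None = None) -> pd.DataFrame:
    """Cluster-extent FWE inference by Freedman–Lane permutation.

    Returns a table with one row per supra-threshold cluster: ``fwe_p``,
    ``k`` (extent in voxels), ``peak_stat`` and peak world-space ``x, y,
    z`` (voxel indices when no affine is given), sorted by fwe_p then
    extent. An empty table (no supra-threshold voxels) is a valid result.
    """
    if not 0.0 < forming_p < 1.0:
        raise ValueError("forming_p must lie in (0, 1)")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    observed = fit_voxelwise_glm(maps, design, contrast, mask=mask,
                                 affine=affine)
    thr = _threshold(observed, forming_p)
    analysis_mask = observed.mask
    supra = (observed.values > thr) & analysis_mask
    labels, n_clusters, extents = _cluster_extents(supra)
    columns = ["fwe_p", "k", "peak_stat", "x", "y", "z"]
    if n_clusters == 0:
        return pd.DataFrame(columns=columns)

    X = design.values
    C = np.atleast_2d(np.asarray(contrast, dtype=float))
    _, Z = _freedman_lane_partition(X, C)
    Y = maps[:, analysis_mask]
    # nuisance-only fit: residuals are the exchangeable units
    gamma = np.linalg.lstsq(Z, Y, rcond=None)[0] if Z.size else \
        np.zeros((0, Y.shape[1]))
    Zg = Z @ gamma if Z.size else np.zeros_like(Y)
    E = Y - Zg

    dof = observed.dof
    pinvX = np.linalg.pinv(X)
    XtXi = np.linalg.inv(X.T @ X)
    CXtXiCt_inv = C @ XtXi @ C.T
    if C.shape[0] > 1:
        CXtXiCt_inv = np.linalg.inv(CXtXiCt_inv)

    rng = np.random.default_rng(seed)
    n = maps.shape[0]
    max_extent = np.zeros(n_perm, dtype=int)
    shape3d = maps.shape[1:]
    for j in range(n_perm):
        perm = rng.permutation(n)
        Ystar = Zg + E[perm]
        stat = _ols_stats(Ystar, X, C, pinvX, CXtXiCt_inv, dof)
        vol = np.zeros(shape3d)
        vol[analysis_mask] = stat
        _, _, perm_extents = _cluster_extents((vol > thr) & analysis_mask)
        max_extent[j] = perm_extents.max() if perm_extents.size else 0

    rows = []
    flat = observed.values.ravel()
    for ci in range(1, n_clusters + 1):
        k = int(extents[ci - 1])
        fwe_p = float((np.sum(max_extent >= k) + 1) / (n_perm + 1))
        in_cluster = (labels == ci)
        cluster_vals = np.where(in_cluster, observed.values, -np.inf).ravel()
        peak_flat = int(np.argmax(cluster_vals))  # argmax: lowest index wins
        peak_idx = np.unravel_index(peak_flat, shape3d)
        if affine is not None:
            world = np.asarray(affine) @ np.array([*peak_idx, 1.0])
            x, y, z = world[:3]
        else:
            x, y, z = (float(i) for i in peak_idx)
        rows.append({"fwe_p": fwe_p, "k": k, "peak_stat": float(flat[peak_flat]),
                     "x": float(x), "y": float(y), "z": float(z)})
    table = pd.DataFrame(rows, columns=columns)
    return table.sort_values(["fwe_p", "k"], ascending=[True, False],
                             ignore_index=True)


# --- scalar demographic tests (Tables 1-2 style) ---------------------------

def chisq_test(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson χ² of independence, no continuity correction.

    Returns (statistic, df, p). Expected counts must all be positive.
    """
    obs = np.asarray(table, dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    if obs.sum() <= 0:
        raise ValueError("empty contingency table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal row/column in contingency table")
    stat, p, df, expected = sps.chi2_contingency(obs, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected count of zero")
    return float(stat), int(df), float(p)


def group_anova(samples: list[np.ndarray]) -> tuple[float, int, int, float]:
    """One-way ANOVA across groups: (F, df1, df2, p)."""
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for s in samples:
        if len(s) < 2:
            raise ValueError("every group needs n ≥ 2")
    f, p = sps.f_oneway(*samples)
    df1 = len(samples) - 1
    df2 = sum(len(s) for s in samples) - len(samples)
    return float(f), df1, df2, float(p)


def kruskal_wallis(samples: list[np.ndarray]) -> tuple[float, int, float]:
    """Kruskal–Wallis rank test with tie correction: (H, df, p)."""
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if sum(len(s) for s in samples) < 3:
        raise ValueError("need at least three observations in total")
    h, p = sps.kruskal(*samples)       # raises if all values identical
    return float(h), len(samples) - 1, float(p)


def shapiro_normality(values: np.ndarray) -> float:
    """Shapiro–Wilk p-value, the preliminary normality screen."""
    return float(sps.shapiro(np.asarray(values, dtype=float)).pvalue)
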