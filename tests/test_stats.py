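import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from molfc import (DesignMatrix, build_design, chisq_test, cluster_inference,
                   fit_voxelwise_glm, group_anova, group_f_contrast,
                   kruskal_wallis, shapiro_normality)
from molfc.stats import (CONNECTIVITY_18, _cluster_extents,
                         _freedman_lane_partition)
from molfc.validation import null_design


def _cohort(rng, n=24):
    groups = np.repeat(["CU", "MCI", "dementia"], n // 3)
    return pd.DataFrame({
        "group": groups,
        "age": rng.normal(70, 8, n),
        "education": rng.normal(12, 3, n),
        "sex": rng.choice(["M", "F"], n),
        "tiv": rng.normal(1450, 150, n),
        "site": rng.choice(["S1", "S2"], n),
    })


class TestDesign:
    def test_cell_means_plus_centred_and_dummy_covariates(self, rng):
        cohort = _cohort(rng)
        design = build_design(cohort)
        i_age = design.columns.index("age")
        assert design.values[:, i_age].mean() == pytest.approx(0.0, abs=1e-9)
        group_cols = [i for i, c in enumerate(design.columns)
                      if c.startswith("group_")]
        assert len(group_cols) == 3
        # cell-means indicators partition the subjects
        assert np.array_equal(design.values[:, group_cols].sum(axis=1),
                              np.ones(len(cohort)))
        # first level of each categorical covariate is the reference
        assert "sex_F" not in design.columns and "sex_M" in design.columns
        assert "site_S1" not in design.columns

    def test_continuous_regressor_appended_centred(self, rng):
        cohort = _cohort(rng)
        cohort["cs"] = rng.normal(0, 1, len(cohort))
        design = build_design(cohort, continuous="cs")
        assert design.columns[-1] == "cs"
        assert design.values[:, -1].mean() == pytest.approx(0.0, abs=1e-9)

    def test_missing_covariate_rejected(self, rng):
        cohort = _cohort(rng).drop(columns=["tiv"])
        with pytest.raises(KeyError, match="tiv"):
            build_design(cohort)

    def test_rank_deficient_design_rejected(self):
        X = np.ones((6, 2))
        with pytest.raises(ValueError, match="rank"):
            DesignMatrix(values=X, columns=["a", "b"])

    def test_group_f_contrast_spans_successive_differences(self, rng):
        design = build_design(_cohort(rng))
        C = group_f_contrast(design)
        assert C.shape[0] == 2
        assert np.allclose(C.sum(axis=1), 0.0)


class TestVoxelwiseGLM:
    def test_f_map_matches_one_way_anova_without_covariates(self, rng):
        n, shape = 18, (4, 4, 4)
        design, contrast = null_design(n)
        maps = rng.standard_normal((n, *shape))
        stat = fit_voxelwise_glm(maps, design, contrast)
        groups = np.repeat([0, 1, 2], 6)
        for idx in [(0, 0, 0), (2, 1, 3), (3, 3, 3)]:
            y = maps[(slice(None), *idx)]
            f_ref, _ = sps.f_oneway(*(y[groups == g] for g in range(3)))
            assert stat.values[idx] == pytest.approx(f_ref, rel=1e-10)
        assert stat.kind == "F" and stat.dof == n - 3 and stat.dof_num == 2

    def test_t_map_matches_two_sample_t_test(self, rng):
        n = 12
        X = np.zeros((n, 2))
        X[:6, 0] = 1.0
        X[6:, 1] = 1.0
        design = DesignMatrix(values=X, columns=["a", "b"])
        maps = rng.standard_normal((n, 3, 3, 3))
        stat = fit_voxelwise_glm(maps, design, np.array([1.0, -1.0]))
        y = maps[:, 1, 1, 1]
        t_ref, _ = sps.ttest_ind(y[:6], y[6:], equal_var=True)
        assert stat.values[1, 1, 1] == pytest.approx(t_ref, rel=1e-10)
        assert stat.kind == "t"

    def test_f_statistic_matches_model_comparison_oracle(self, rng):
        """F from the contrast formula equals full-vs-reduced-model SSE."""
        n = 21
        design, contrast = null_design(n)
        cov = rng.standard_normal((n, 2))
        X = np.column_stack([design.values, cov])
        design_full = DesignMatrix(values=X, columns=design.columns
                                   + ["c1", "c2"])
        C = np.hstack([contrast, np.zeros((2, 2))])
        maps = rng.standard_normal((n, 2, 2, 2))
        stat = fit_voxelwise_glm(maps, design_full, C)
        y = maps[:, 0, 1, 0]
        beta_f = np.linalg.lstsq(X, y, rcond=None)[0]
        sse_f = np.sum((y - X @ beta_f) ** 2)
        # reduced model: common group mean + covariates
        Xr = np.column_stack([np.ones(n), cov])
        beta_r = np.linalg.lstsq(Xr, y, rcond=None)[0]
        sse_r = np.sum((y - Xr @ beta_r) ** 2)
        dof = n - np.linalg.matrix_rank(X)
        f_ref = ((sse_r - sse_f) / 2.0) / (sse_f / dof)
        assert stat.values[0, 1, 0] == pytest.approx(f_ref, rel=1e-8)

    def test_non_finite_voxels_are_dropped_from_the_mask(self, rng):
        n = 15
        design, contrast = null_design(n)
        maps = rng.standard_normal((n, 3, 3, 3))
        maps[0, 0, 0, 0] = np.nan
        stat = fit_voxelwise_glm(maps, design, contrast)
        assert not stat.mask[0, 0, 0]
        assert stat.values[0, 0, 0] == 0.0

    def test_subject_count_mismatch_rejected(self, rng):
        design, contrast = null_design(12)
        with pytest.raises(ValueError, match="mismatch"):
            fit_voxelwise_glm(rng.standard_normal((10, 3, 3, 3)), design,
                              contrast)


class TestFreedmanLane:
    def test_partition_preserves_design_span_and_isolates_effect(self, rng):
        cohort = _cohort(rng)
        design = build_design(cohort)
        C = group_f_contrast(design)
        M, Z = _freedman_lane_partition(design.values, C)
        X = design.values
        # [M Z] spans the same column space as X
        full = np.column_stack([M, Z])
        assert np.linalg.matrix_rank(full) == np.linalg.matrix_rank(X)
        proj = full @ np.linalg.pinv(full)
        assert np.allclose(proj @ X, X, atol=1e-8)
        # the nuisance partition carries no contrast signal: fitting X to
        # any vector in span(Z) yields a zero contrast value
        v = Z @ rng.standard_normal(Z.shape[1])
        beta = np.linalg.pinv(X) @ v
        assert np.abs(C @ beta).max() < 1e-8


class TestClusterExtents:
    def test_edge_neighbours_merge_corner_neighbours_do_not(self):
        vol = np.zeros((5, 5, 5), dtype=bool)
        vol[1, 1, 1] = vol[1, 2, 2] = True      # share an edge
        labels, n, extents = _cluster_extents(vol)
        assert n == 1 and extents.tolist() == [2]
        vol2 = np.zeros((5, 5, 5), dtype=bool)
        vol2[1, 1, 1] = vol2[2, 2, 2] = True    # share only a corner
        _, n2, extents2 = _cluster_extents(vol2)
        assert n2 == 2 and sorted(extents2.tolist()) == [1, 1]
        assert CONNECTIVITY_18.sum() == 19       # centre + 18 neighbours

    def test_empty_volume_yields_no_clusters(self):
        _, n, extents = _cluster_extents(np.zeros((4, 4, 4), dtype=bool))
        assert n == 0 and extents.size == 0


class TestClusterInference:
    def test_null_data_yields_no_confident_clusters(self, rng):
        n = 15
        design, contrast = null_design(n)
        maps = rng.standard_normal((n, 6, 6, 6))
        table = cluster_inference(maps, design, contrast, forming_p=0.01,
                                  n_perm=100, seed=1)
        assert list(table.columns) == ["fwe_p", "k", "peak_stat",
                                       "x", "y", "z"]
        if len(table):
            assert table["fwe_p"].min() >= 1.0 / 101.0

    def test_strong_implanted_effect_is_detected_and_localized(self, rng):
        n = 18
        design, contrast = null_design(n)
        maps = rng.standard_normal((n, 8, 8, 8))
        groups = np.repeat([0, 1, 2], 6)
        maps[groups == 2, 3:6, 3:6, 3:6] += 5.0
        table = cluster_inference(maps, design, contrast, forming_p=0.01,
                                  n_perm=200, seed=2)
        top = table.iloc[0]
        assert top["fwe_p"] < 0.05
        assert top["k"] >= 20
        assert 3 <= top["x"] < 6 and 3 <= top["y"] < 6 and 3 <= top["z"] < 6

    def test_peak_reported_in_world_coordinates_with_affine(self, rng):
        n = 18
        design, contrast = null_design(n)
        maps = rng.standard_normal((n, 8, 8, 8))
        maps[np.repeat([0, 1, 2], 6) == 0, 2:5, 2:5, 2:5] += 5.0
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = -8.0
        table = cluster_inference(maps, design, contrast, forming_p=0.01,
                                  n_perm=100, seed=3, affine=affine)
        top = table.iloc[0]
        # world coordinates are affine-transformed voxel indices
        assert top["x"] % 2 == 0 and -8 <= top["x"] <= 8

    def test_invalid_parameters_rejected(self, rng):
        design, contrast = null_design(12)
        maps = rng.standard_normal((12, 4, 4, 4))
        with pytest.raises(ValueError, match="forming_p"):
            cluster_inference(maps, design, contrast, forming_p=1.5)
        with pytest.raises(ValueError, match="permutations"):
            cluster_inference(maps, design, contrast, n_perm=10)


class TestScalarTests:
    def test_chisq_matches_hand_formula(self):
        table = np.array([[29.0, 36.0, 28.0], [47.0, 50.0, 30.0]])
        stat, df, p = chisq_test(table)
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row @ col / table.sum()
        stat_ref = float(((table - expected) ** 2 / expected).sum())
        assert stat == pytest.approx(stat_ref, rel=1e-12)
        assert df == 2
        assert p == pytest.approx(sps.chi2.sf(stat_ref, 2), rel=1e-12)

    def test_chisq_rejects_degenerate_tables(self):
        with pytest.raises(ValueError):
            chisq_test(np.array([[1.0, -2.0], [3.0, 4.0]]))
        with pytest.raises(ValueError):
            chisq_test(np.array([[0.0, 0.0], [3.0, 4.0]]))
        with pytest.raises(ValueError):
            chisq_test(np.zeros((2, 2)))

    def test_anova_matches_sum_of_squares_oracle(self, rng):
        samples = [rng.normal(m, 1.0, 12) for m in (0.0, 0.5, 1.0)]
        f, df1, df2, p = group_anova(samples)
        allv = np.concatenate(samples)
        grand = allv.mean()
        ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
        ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
        f_ref = (ss_between / 2) / (ss_within / (len(allv) - 3))
        assert f == pytest.approx(f_ref, rel=1e-10)
        assert (df1, df2) == (2, 33)

    def test_anova_needs_two_groups_of_two(self, rng):
        with pytest.raises(ValueError):
            group_anova([rng.normal(0, 1, 5)])
        with pytest.raises(ValueError):
            group_anova([rng.normal(0, 1, 5), np.array([1.0])])

    def test_kruskal_matches_hand_ranked_oracle(self):
        samples = [np.array([1.0, 3.0, 5.0]), np.array([2.0, 4.0, 6.0]),
                   np.array([7.0, 8.0, 9.0])]
        h, df, p = kruskal_wallis(samples)
        allv = np.concatenate(samples)
        ranks = sps.rankdata(allv)
        n = len(allv)
        start, h_ref = 0, 0.0
        for s in samples:
            r = ranks[start:start + len(s)]
            h_ref += r.sum() ** 2 / len(s)
            start += len(s)
        h_ref = 12.0 / (n * (n + 1)) * h_ref - 3 * (n + 1)
        assert h == pytest.approx(h_ref, rel=1e-10)  # no ties: no correction
        assert df == 2

    def test_shapiro_flags_heavy_skew(self, rng):
        assert shapiro_normality(rng.normal(0, 1, 200)) > 0.001
        assert shapiro_normality(rng.exponential(1.0, 200) ** 3) < 1e-6
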