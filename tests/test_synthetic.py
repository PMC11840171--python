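import json
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from molfc import (MCL_REGIONS, NST_REGIONS, SimulationConfig,
                   default_effect_specs, make_atlas, make_parcellation,
                   simulate_cohort, simulate_subject, template_loadings,
                   tissue_layout)
from molfc.synthetic import band_limited_series


class TestTissueLayout:
    def test_tissues_partition_the_brain(self):
        layout = tissue_layout((14, 14, 14))
        union = layout["gm"] | layout["wm"] | layout["csf"]
        assert np.array_equal(union, layout["brain"])
        assert not (layout["gm"] & layout["wm"]).any()
        assert not (layout["gm"] & layout["csf"]).any()
        assert not (layout["wm"] & layout["csf"]).any()

    def test_each_tissue_survives_one_voxel_erosion(self):
        from scipy.ndimage import binary_erosion
        layout = tissue_layout((12, 12, 12))
        for tissue in ("gm", "wm", "csf"):
            assert binary_erosion(layout[tissue]).any()

    def test_minimum_grid_enforced(self):
        with pytest.raises(ValueError, match="12"):
            tissue_layout((10, 12, 12))


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_per_group=(0, 5, 5))
        with pytest.raises(ValueError):
            SimulationConfig(spike_rate=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(n_timepoints=0)

    def test_affine_centres_the_grid(self):
        cfg = SimulationConfig(grid_shape=(20, 20, 20), voxel_size=2.0)
        centre = cfg.affine @ np.array([10.0, 10.0, 10.0, 1.0])
        assert np.allclose(centre[:3], 0.0)


class TestAtlasGeneration:
    def test_density_supported_on_grey_matter_only(self, tiny_config):
        atlas = make_atlas(tiny_config, 0)
        layout = tissue_layout(tiny_config.grid_shape)
        assert np.all(atlas.values >= 0)
        assert np.all(atlas.values[~layout["gm"]] == 0)
        assert atlas.reference_mask is not None

    def test_successive_templates_are_orthogonal_over_gm(self, tiny_config):
        layout = tissue_layout(tiny_config.grid_shape)
        gm = layout["gm"]
        fields = []
        for k in range(2):
            v = make_atlas(tiny_config, k).values[gm]
            fields.append(v - v.mean())
        cos = fields[0] @ fields[1] / (np.linalg.norm(fields[0])
                                       * np.linalg.norm(fields[1]))
        assert abs(cos) < 1e-10

    def test_deterministic_given_seed(self, tiny_config):
        a = make_atlas(tiny_config, 1)
        b = make_atlas(tiny_config, 1)
        assert np.array_equal(a.values, b.values)


class TestBandLimitedSeries:
    def test_zero_mean_unit_sd_and_band_confined(self, rng):
        s = band_limited_series(rng, 3, 120, 2.0)
        assert np.allclose(s.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(s.std(axis=0), 1.0, atol=1e-12)
        freqs = np.fft.rfftfreq(120, d=2.0)
        spec = np.abs(np.fft.rfft(s, axis=0))
        out_of_band = (freqs < 0.01) | (freqs > 0.08)
        assert spec[out_of_band].max() < 1e-9

    def test_orthogonalized_series_are_uncorrelated(self, rng):
        s = band_limited_series(rng, 4, 100, 2.0, orthogonalize=True)
        gram = s.T @ s
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_unresolvable_band_rejected(self, rng):
        with pytest.raises(ValueError, match="band"):
            band_limited_series(rng, 1, 20, 0.1, band=(0.0001, 0.0002))


class TestEffects:
    def test_delta_applied_only_inside_sphere_and_support(self, tiny_config):
        atlases = [make_atlas(tiny_config, k) for k in range(2)]
        specs = default_effect_specs(tiny_config)
        W_cu, _ = template_loadings(tiny_config, atlases, "CU", specs)
        W_dem, applied = template_loadings(tiny_config, atlases, "dementia",
                                           specs)
        delta = specs[0].deltas["dementia"]
        assert applied[0] == delta
        diff = W_dem[0] - W_cu[0]
        changed = diff != 0
        assert changed.any()
        assert np.allclose(diff[changed], delta)
        grids = np.indices(tiny_config.grid_shape)
        d2 = sum((grids[i] - specs[0].center[i]) ** 2 for i in range(3))
        assert np.all(d2[changed] <= specs[0].radius ** 2)
        assert np.array_equal(W_dem[1], W_cu[1])   # other template untouched


class TestSimulateSubject:
    def test_deterministic_and_shapes(self, tiny_subject):
        cfg = tiny_subject["config"]
        scan, motion, gt = simulate_subject(cfg, tiny_subject["atlases"],
                                            "CU", seed=0)
        assert np.array_equal(scan, tiny_subject["scan"])
        assert scan.shape == (*cfg.grid_shape, cfg.n_timepoints)
        assert list(motion.columns) == ["tx", "ty", "tz", "rx", "ry", "rz"]
        assert gt.loadings.shape == (2, *cfg.grid_shape)
        assert gt.series.shape == (cfg.n_timepoints, 2)

    def test_component_substreams_are_independent(self, tiny_subject):
        """Switching one corruption off leaves the others untouched."""
        cfg = tiny_subject["config"]
        atlases = tiny_subject["atlases"]
        base, _, _ = simulate_subject(cfg, atlases, "CU", seed=0)
        no_trend, _, _ = simulate_subject(replace(cfg, trend_amp=0.0),
                                          atlases, "CU", seed=0)
        diff = (base - no_trend)[tissue_layout(cfg.grid_shape)["brain"]]
        # the difference is exactly the rank-1 trend component
        sv = np.linalg.svd(diff, compute_uv=False)
        assert sv[1] < sv[0] * 1e-10

    def test_spikes_hit_whole_brain_at_global_timepoints(self, tiny_subject):
        cfg = replace(tiny_subject["config"], spike_rate=0.1)
        atlases = tiny_subject["atlases"]
        with_spikes, _, _ = simulate_subject(cfg, atlases, "CU", seed=0)
        no_spikes, _, _ = simulate_subject(replace(cfg, spike_rate=0.0),
                                           atlases, "CU", seed=0)
        diff = with_spikes - no_spikes
        brain = tissue_layout(cfg.grid_shape)["brain"]
        spiked_t = np.abs(diff[brain]).max(axis=0) > 0
        assert spiked_t.any()
        # at a spiked timepoint every brain voxel is displaced equally
        t0 = int(np.flatnonzero(spiked_t)[0])
        assert np.all(np.abs(diff[brain][:, t0]) > 0)
        assert np.all(diff[~brain] == 0)

    def test_atlas_grid_mismatch_rejected(self, tiny_config):
        wrong = SimulationConfig(grid_shape=(14, 14, 14), n_templates=1)
        atlas = make_atlas(wrong, 0)
        with pytest.raises(ValueError, match="grid"):
            simulate_subject(tiny_config, [atlas], "CU", seed=0)


class TestParcellation:
    def test_pathway_regions_resolve_and_labels_partition_gm(self,
                                                             tiny_config):
        parc = make_parcellation(tiny_config)
        labels = parc.labels_for(MCL_REGIONS + NST_REGIONS)
        assert len(set(labels)) == len(MCL_REGIONS) + len(NST_REGIONS)
        gm = tissue_layout(tiny_config.grid_shape)["gm"]
        assert np.array_equal(parc.labels > 0, gm)


@pytest.fixture(scope="module")
def cohort_dir(tmp_path_factory, tiny_config):
    out = tmp_path_factory.mktemp("cohort")
    manifest = simulate_cohort(tiny_config, out)
    return out, manifest


class TestSimulateCohort:
    def test_manifest_references_existing_files(self, cohort_dir):
        out, manifest = cohort_dir
        for rel in [manifest["gm_mask"], manifest["parcellation"],
                    manifest["cohort"],
                    *manifest["atlases"].values()]:
            assert (out / rel).exists()
        for s in manifest["subjects"]:
            assert (out / s["scan"]).exists()
            assert (out / s["motion"]).exists()
            assert (out / s["loadings"]).exists()

    def test_cohort_table_covers_demographics_and_measures(self, cohort_dir):
        out, manifest = cohort_dir
        cohort = pd.read_csv(out / manifest["cohort"], sep="\t")
        assert len(cohort) == 6
        for col in ("group", "site", "age", "education", "sex", "tiv",
                    "lm_ir", "stroop_time"):
            assert col in cohort.columns

    def test_last_site_has_no_biomarker_measurements(self, cohort_dir):
        out, manifest = cohort_dir
        cohort = pd.read_csv(out / manifest["cohort"], sep="\t")
        last = cohort["site"] == "S3"
        if last.any():
            assert cohort.loc[last, "abeta_status"].isna().all()

    def test_existing_output_protected_without_overwrite(self, cohort_dir,
                                                         tiny_config):
        out, _ = cohort_dir
        with pytest.raises(FileExistsError):
            simulate_cohort(tiny_config, out)
        manifest = simulate_cohort(tiny_config, out, overwrite=True)
        assert json.loads((out / "manifest.json").read_text())["seed"] == \
            manifest["seed"]
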