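import json
import math

import numpy as np
import pytest

from eatquant import (
    DEFAULT_SERIES_MODELS,
    DEFAULT_WINDOW,
    PhantomParams,
    SeriesModel,
    apply_series_model,
    calibrate_fat_model,
    generate_cohort,
    generate_phantom,
    iter_cohort,
    segment_eat,
    eat_volume_ml,
    truncated_normal_stats,
)
from eatquant.phantom import phantom_tissue_masks


class TestGeometry:
    def test_radii_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            PhantomParams(r_blood=30, r_myocardium=20, r_fat=48, r_sac=52)

    def test_empty_fat_shell_rejected(self):
        params = PhantomParams(shape=(4, 4, 4), spacing=(1, 1, 1),
                               r_blood=30, r_myocardium=40, r_fat=48, r_sac=52)
        with pytest.raises(ValueError, match="empty"):
            generate_phantom(params, seed=0)

    def test_fat_count_matches_brute_force_shell_predicate(self, small_params):
        _, _, truth = generate_phantom(small_params, seed=0)
        p = small_params
        count = 0
        for i in range(p.shape[0]):
            for j in range(p.shape[1]):
                for k in range(p.shape[2]):
                    x = (i - (p.shape[0] - 1) / 2) * p.spacing[0]
                    y = (j - (p.shape[1] - 1) / 2) * p.spacing[1]
                    z = (k - (p.shape[2] - 1) / 2) * p.spacing[2]
                    r = math.sqrt(x * x + y * y + z * z)
                    if p.r_myocardium < r <= p.r_fat:
                        count += 1
        assert truth.true_fat_voxel_count == count

    def test_truth_volume_consistent_with_count(self, small_params):
        _, _, truth = generate_phantom(small_params, seed=0)
        voxel_mm3 = float(np.prod(small_params.spacing))
        assert truth.true_fat_volume_ml == truth.true_fat_voxel_count * voxel_mm3 / 1000.0

    def test_mask_is_sac_interior(self, small_params):
        _, mask, _ = generate_phantom(small_params, seed=0)
        np.testing.assert_array_equal(mask.flags,
                                      phantom_tissue_masks(small_params)["sac"])


class TestGeneration:
    def test_zero_noise_fat_values_exact(self, small_params, noiseless_models):
        params = PhantomParams(**{**small_params.__dict__,
                                  "series_models": noiseless_models})
        series, _, _ = generate_phantom(params, seed=0)
        fat = phantom_tissue_masks(params)["fat"]
        for model in noiseless_models:
            vals = series[model.series_label].values[fat]
            assert np.all(vals == -80.0 + model.shift_delta)

    def test_determinism(self, small_params):
        a, _, ta = generate_phantom(small_params, seed=42)
        b, _, tb = generate_phantom(small_params, seed=42)
        for label in a:
            np.testing.assert_array_equal(a[label].values, b[label].values)
        assert ta == tb

    def test_seed_changes_noise_not_truth(self, small_params):
        a, mask_a, ta = generate_phantom(small_params, seed=1)
        b, mask_b, tb = generate_phantom(small_params, seed=2)
        assert ta.true_fat_voxel_count == tb.true_fat_voxel_count
        np.testing.assert_array_equal(mask_a.flags, mask_b.flags)
        assert not np.array_equal(a["TNC"].values, b["TNC"].values)

    def test_series_share_fat_locations(self, small_params):
        series, _, _ = generate_phantom(small_params, seed=3)
        fat = phantom_tissue_masks(small_params)["fat"]
        # outside fat, TNC and VNC_Conv are identical tissue plates
        np.testing.assert_array_equal(series["TNC"].values[~fat],
                                      series["VNC_Conv"].values[~fat])

    def test_cta_blood_pool_enhanced(self, small_params):
        series, _, _ = generate_phantom(small_params, seed=3)
        blood = phantom_tissue_masks(small_params)["blood"]
        assert np.all(series["CTA"].values[blood] == small_params.hu_blood_cta)
        assert np.all(series["TNC"].values[blood] == small_params.hu_blood)

    def test_tnc_model_requires_zero_shift(self):
        with pytest.raises(ValueError, match="shift_delta = 0"):
            SeriesModel("TNC", -80.0, 10.0, shift_delta=1.0)


class TestApplySeriesModel:
    def test_pure_shift_exact(self, small_params):
        series, _, _ = generate_phantom(small_params, seed=0)
        fat = phantom_tissue_masks(small_params)["fat"]
        model = SeriesModel("VNC_Conv", -80.0, 0.0, shift_delta=5.0)
        out = apply_series_model(series["TNC"], fat, model, seed=0)
        np.testing.assert_array_equal(out.values[fat],
                                      series["TNC"].values[fat] + 5.0)
        np.testing.assert_array_equal(out.values[~fat], series["TNC"].values[~fat])

    def test_identity_model(self, small_params):
        series, _, _ = generate_phantom(small_params, seed=0)
        fat = phantom_tissue_masks(small_params)["fat"]
        model = SeriesModel("VNC_PC", -80.0, 0.0)
        out = apply_series_model(series["TNC"], fat, model, seed=0)
        np.testing.assert_array_equal(out.values, series["TNC"].values)

    def test_input_not_modified(self, small_params):
        series, _, _ = generate_phantom(small_params, seed=0)
        fat = phantom_tissue_masks(small_params)["fat"]
        before = series["TNC"].values.copy()
        apply_series_model(series["TNC"], fat,
                           SeriesModel("CTA", -80.0, 0.0, shift_delta=9.0), seed=0)
        np.testing.assert_array_equal(series["TNC"].values, before)

    def test_law_of_large_numbers_shift(self):
        """Mean perturbation over 1e5 fat voxels recovers shift_delta ± 0.05."""
        rng = np.random.default_rng(0)
        from eatquant import VolumeGrid

        shape = (100, 100, 10)
        base = VolumeGrid(rng.normal(-81, 5, size=shape), (1, 1, 1), "TNC", "P")
        fat = np.ones(shape, dtype=bool)
        model = SeriesModel("VNC_Conv", -81.0, 0.0, shift_delta=5.7,
                            extra_noise_sigma=5.0)
        out = apply_series_model(base, fat, model, seed=1)
        assert np.mean(out.values - base.values) == pytest.approx(5.7, abs=0.05)


class TestCalibration:
    @pytest.mark.parametrize("model,target_mean,target_sd", [
        (DEFAULT_SERIES_MODELS[0], -81.1, 32.5),
        (DEFAULT_SERIES_MODELS[1], -75.4, 31.0),
        (DEFAULT_SERIES_MODELS[2], -79.1, 30.3),
        (DEFAULT_SERIES_MODELS[3], -83.1, 32.3),
    ])
    def test_default_models_reproduce_inwindow_stats(self, model, target_mean, target_sd):
        """Truncated-normal closed form of each default model hits its target."""
        m, s = truncated_normal_stats(model.mean, model.total_sigma)
        assert m == pytest.approx(target_mean, abs=0.05)
        assert s == pytest.approx(target_sd, abs=0.05)

    def test_calibration_function_inverts_truncation(self):
        mu, sigma = calibrate_fat_model(-81.1, 32.5)
        m, s = truncated_normal_stats(mu, sigma)
        assert m == pytest.approx(-81.1, abs=1e-6)
        assert s == pytest.approx(32.5, abs=1e-6)

    def test_measured_phantom_stats_match_targets(self, small_params):
        """Sampled in-window mean on >=1e5 fat voxels within 3 SE of target."""
        params = PhantomParams(shape=(72, 72, 72), spacing=(1.0, 1.0, 1.0),
                               r_blood=15.0, r_myocardium=20.0, r_fat=30.0,
                               r_sac=34.0)
        series, mask, truth = generate_phantom(params, seed=5)
        assert truth.true_fat_voxel_count >= 60_000
        from eatquant import eat_mean_hu, eat_noise_hu

        seg = segment_eat(series["TNC"], mask)
        se = 32.5 / math.sqrt(seg.voxel_count)
        assert eat_mean_hu(seg, series["TNC"]) == pytest.approx(-81.1, abs=3 * se)
        assert eat_noise_hu(seg, series["TNC"]) == pytest.approx(32.5, abs=0.5)


class TestMonotoneContamination:
    def test_extra_noise_never_increases_window_retention(self):
        """With the mean within 2σ of a window edge, widening the distribution
        can only push more mass out of the window."""
        for seed in range(3):
            rng = np.random.default_rng(seed)
            fractions = []
            for extra in (0.0, 5.0, 10.0, 20.0):
                model = SeriesModel("TNC", -45.0, 10.0, extra_noise_sigma=extra)
                vals = rng.normal(model.mean, model.total_sigma, size=200_000)
                inwin = np.mean((vals >= -190) & (vals <= -30))
                fractions.append(inwin)
            assert all(a >= b for a, b in zip(fractions, fractions[1:]))


class TestCohort:
    def test_single_patient_file_layout(self, tmp_path, small_params):
        patients, manifest = generate_cohort(1, seed=0, out_dir=tmp_path,
                                             base_params=small_params)
        files = sorted(p.name for p in tmp_path.iterdir())
        assert files == ["P000_CTA.nii.gz", "P000_TNC.nii.gz",
                         "P000_VNC_Conv.nii.gz", "P000_VNC_PC.nii.gz",
                         "P000_mask.nii.gz", "manifest.csv", "truth.json"]
        assert len(manifest.rows) == 4

    def test_regenerated_truth_identical(self, tmp_path, small_params):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_cohort(3, seed=9, out_dir=a, base_params=small_params)
        generate_cohort(3, seed=9, out_dir=b, base_params=small_params)
        assert (a / "truth.json").read_text() == (b / "truth.json").read_text()
        assert json.loads((a / "truth.json").read_text())["master_seed"] == 9

    def test_true_volumes_within_configured_range(self, small_params):
        for pat in iter_cohort(8, seed=4, base_params=small_params,
                               volume_range_ml=(5.0, 15.0)):
            assert 5.0 <= pat.truth.true_fat_volume_ml <= 15.0

    def test_per_patient_seeds_differ(self, small_params):
        patients = list(iter_cohort(2, seed=0, base_params=small_params,
                                    volume_range_ml=(8.0, 12.0)))
        assert patients[0].truth.seed != patients[1].truth.seed


class TestExactRecovery:
    def test_zero_noise_volume_equals_truth(self, small_params, noiseless_models):
        params = PhantomParams(**{**small_params.__dict__,
                                  "series_models": noiseless_models})
        series, mask, truth = generate_phantom(params, seed=0)
        for label, vol in series.items():
            seg = segment_eat(vol, mask, DEFAULT_WINDOW)
            assert eat_volume_ml(seg) == truth.true_fat_volume_ml
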