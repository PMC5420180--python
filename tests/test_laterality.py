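"""Laterality-index engine: single-threshold LI, bootstrap sweep, classes."""

import math
from dataclasses import replace

import numpy as np
import pytest

from memrisk import (
    IndeterminateLateralityError,
    LiConfig,
    MapSimParams,
    StatMapWithMasks,
    bootstrap_li,
    classify_li,
    li_at_threshold,
    make_stat_map,
)
from memrisk.laterality import swap_sides, threshold_sweep_mean
from memrisk.simulate import noise_free_map

DEGENERATE = LiConfig(resample_fraction=1.0, n_boot=1, trim_fraction=0.0)


def two_box_map(left_vals, right_vals, shape=(8, 4, 4)):
    """Tiny map with explicit voxel values in two cubic ROIs."""
    values = np.zeros(shape)
    ml = np.zeros(shape, dtype=bool)
    mr = np.zeros(shape, dtype=bool)
    ml[:2, :2, :2] = True
    mr[-2:, :2, :2] = True
    values[ml] = np.resize(left_vals, ml.sum())
    values[mr] = np.resize(right_vals, mr.sum())
    return StatMapWithMasks(values, ml, mr)


class TestLiAtThreshold:
    def test_one_sided_map_is_plus_one(self):
        m = two_box_map([2.0], [0.0])
        assert li_at_threshold(m, 0.0) == 1.0

    def test_symmetric_map_is_zero(self):
        m = two_box_map([1.5, 2.5], [2.5, 1.5])
        assert li_at_threshold(m, 0.0) == 0.0

    def test_value_weighted_ratio(self):
        # left sums to 3.0, right to 1.0 -> (3-1)/(3+1)
        m = two_box_map([3.0 / 8], [1.0 / 8])
        assert li_at_threshold(m, 0.0) == pytest.approx(0.5)

    def test_all_subthreshold_is_nan(self):
        m = two_box_map([1.0], [1.0])
        assert math.isnan(li_at_threshold(m, 5.0))

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            li_at_threshold(two_box_map([1.0], [1.0]), -0.1)

    def test_antisymmetric_under_mask_swap(self):
        m = two_box_map([3.0, 1.0, 0.5], [2.0, 0.2, 0.1])
        for thr in (0.0, 0.3, 1.0):
            assert li_at_threshold(swap_sides(m), thr) == -li_at_threshold(m, thr)


class TestClassifyLi:
    @pytest.mark.parametrize(
        "li, cls",
        [
            (0.056, "bilateral"),
            (-0.15, "right"),
            (0.1, "bilateral"),     # closed interval: boundary is bilateral
            (-0.1, "bilateral"),
            (0.10001, "left"),
            (0.75, "left"),
            (-1.0, "right"),
        ],
    )
    def test_cutoffs(self, li, cls):
        assert classify_li(li) == cls

    def test_missing_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_li(float("nan"))
        with pytest.raises(ValueError):
            classify_li(1.2)


class TestBootstrapLi:
    def test_one_sided_noise_free(self):
        m = make_stat_map(MapSimParams(asymmetry=1.0, noise_sd=0.0))
        r = bootstrap_li(m)
        assert r.li_overall == pytest.approx(1.0, abs=1e-12)
        assert r.laterality_class == "left"

    def test_mirror_symmetric_is_zero(self):
        m = make_stat_map(MapSimParams(asymmetry=0.0, noise_sd=0.0))
        assert bootstrap_li(m).li_overall == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry_value_swap(self):
        """Mirroring the volume and swapping the masks negates the LI."""
        m = make_stat_map(MapSimParams(asymmetry=0.5, noise_sd=0.5, seed=3))
        mirrored = StatMapWithMasks(
            m.values[::-1].copy(),
            m.mask_right[::-1].copy(),
            m.mask_left[::-1].copy(),
        )
        r = bootstrap_li(m)
        r_m = bootstrap_li(mirrored)
        assert r_m.li_overall == pytest.approx(-r.li_overall, abs=1e-9)

    def test_degenerate_config_equals_deterministic_sweep(self):
        m = make_stat_map(MapSimParams(asymmetry=0.4, noise_sd=0.6, seed=2))
        boot = bootstrap_li(m, DEGENERATE).li_overall
        sweep = threshold_sweep_mean(m, DEGENERATE)
        assert boot == pytest.approx(sweep, abs=1e-12)

    def test_bootstrap_tracks_full_set_oracle(self):
        """Resampled estimate stays within 0.1 of the same map's
        no-resampling threshold-sweep mean."""
        m = make_stat_map(MapSimParams(asymmetry=0.8, noise_sd=0.5, seed=11))
        boot = bootstrap_li(m).li_overall
        oracle = threshold_sweep_mean(m)
        assert boot == pytest.approx(oracle, abs=0.1)

    def test_deterministic_given_seed(self):
        m = make_stat_map(MapSimParams(asymmetry=0.3, noise_sd=0.8, seed=4))
        assert bootstrap_li(m).li_overall == bootstrap_li(m).li_overall

    def test_monotone_in_asymmetry(self):
        lis = [
            bootstrap_li(
                make_stat_map(MapSimParams(asymmetry=a, noise_sd=0.3, seed=5))
            ).li_overall
            for a in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(lis, lis[1:]))

    def test_bounds_and_class_consistency(self):
        for seed, a in [(0, -0.7), (1, 0.05), (2, 0.9)]:
            r = bootstrap_li(
                make_stat_map(MapSimParams(asymmetry=a, noise_sd=0.6, seed=seed))
            )
            assert -1.0 <= r.li_overall <= 1.0
            for t in r.per_threshold:
                if t.li is not None:
                    assert -1.0 <= t.li <= 1.0 + 1e-12
            assert r.laterality_class == classify_li(r.li_overall)

    def test_indeterminate_when_nothing_survives(self):
        m = two_box_map([0.1] * 8, [0.1] * 8)
        with pytest.raises(IndeterminateLateralityError):
            bootstrap_li(m, LiConfig(threshold_min=1.0))

    def test_unweighted_option(self):
        m = make_stat_map(MapSimParams(asymmetry=0.6, noise_sd=0.4, seed=6))
        w = bootstrap_li(m, LiConfig(weighting="threshold")).li_overall
        u = bootstrap_li(m, LiConfig(weighting="unweighted")).li_overall
        # the low, noise-dominated thresholds pull the unweighted mean down
        assert u <= w


class TestConfigAndMapValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(resample_fraction=0.0),
            dict(resample_fraction=1.2),
            dict(trim_fraction=0.5),
            dict(min_voxels=0),
            dict(threshold_min=-1.0),
            dict(weighting="median"),
        ],
    )
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LiConfig(**kwargs)

    def test_overlapping_masks_rejected(self):
        v = np.zeros((4, 4, 4))
        m = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError, match="overlap"):
            StatMapWithMasks(v, m, m)

    def test_shape_mismatch_rejected(self):
        v = np.zeros((4, 4, 4))
        ml = np.zeros((4, 4, 4), dtype=bool)
        ml[0, 0, 0] = True
        mr = np.zeros((5, 4, 4), dtype=bool)
        mr[1, 0, 0] = True
        with pytest.raises(ValueError, match="shape"):
            StatMapWithMasks(v, ml, mr)


class TestNiftiRoundTrip:
    def test_load_stat_map(self, tmp_path):
        import nibabel as nib

        from memrisk import load_stat_map

        m = make_stat_map(MapSimParams(asymmetry=0.8, noise_sd=0.2, seed=1))
        aff = np.eye(4)
        nib.save(nib.Nifti1Image(m.values.astype(np.float32), aff),
                 tmp_path / "map.nii.gz")
        nib.save(nib.Nifti1Image(m.mask_left.astype(np.uint8), aff),
                 tmp_path / "l.nii.gz")
        nib.save(nib.Nifti1Image(m.mask_right.astype(np.uint8), aff),
                 tmp_path / "r.nii.gz")
        loaded = load_stat_map(
            tmp_path / "map.nii.gz", tmp_path / "l.nii.gz", tmp_path / "r.nii.gz"
        )
        assert np.array_equal(loaded.mask_left, m.mask_left)
        got = bootstrap_li(loaded).li_overall
        want = bootstrap_li(m).li_overall
        assert got == pytest.approx(want, abs=1e-4)  # float32 storage
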