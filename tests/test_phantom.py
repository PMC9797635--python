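"""Phantom geometry, filling and acquisition simulator."""

import numpy as np
import pytest

from datquant.phantom import (
    COMPARTMENTS,
    LABELS,
    AcquisitionConfig,
    activity_level_for_ratio,
    build_phantom,
    fill_activities,
    generate_study,
    simulate_spect,
)


class TestBuildPhantom:
    def test_volumes_within_two_percent(self, default_geometry):
        g = default_geometry
        for name in COMPARTMENTS:
            rel = abs(g.achieved_volumes[name] - g.nominal_volumes[name])
            assert rel / g.nominal_volumes[name] <= 0.02

    def test_compartments_disjoint_and_inside_shell(self, default_geometry):
        labels = default_geometry.label_volume
        # labels are exclusive by construction; check each well is surrounded
        # by shell (contained in the shell's convex support)
        from scipy import ndimage
        for name in COMPARTMENTS:
            grown = ndimage.binary_dilation(labels == LABELS[name])
            outside = grown & (labels == 0)
            assert not outside.any(), f"{name} touches the outside"

    def test_revoxelization_consistency(self):
        for vox in (2.13, 4.26):
            g = build_phantom(voxel_size=vox)
            for name in COMPARTMENTS:
                rel = abs(g.achieved_volumes[name] - g.nominal_volumes[name])
                assert rel / g.nominal_volumes[name] <= 0.02

    def test_zero_volume_request_errors(self):
        with pytest.raises(ValueError):
            build_phantom(nominal_volumes={"CA_R": 0.0, "CA_L": 4.6,
                                           "PU_R": 5.4, "PU_L": 6.0})

    def test_subvoxel_volume_request_errors(self):
        with pytest.raises(ValueError, match="smaller than"):
            build_phantom(voxel_size=4.0, matrix_size=48, n_slices=48,
                          nominal_volumes={"CA_R": 0.01, "CA_L": 4.6,
                                           "PU_R": 5.4, "PU_L": 6.0})

    def test_striatal_axial_extent_near_40mm(self, default_geometry):
        zs = np.where(default_geometry.striatal_mask.any(axis=(0, 1)))[0]
        extent = (zs.max() - zs.min() + 1) * default_geometry.voxel_size
        assert 36.0 <= extent <= 46.0


class TestFillActivities:
    def test_no_jitter_exact_ratio(self, default_geometry):
        _, rec = fill_activities(default_geometry, 10, jitter_cv=0.0, seed=0)
        assert rec.achieved_bpi == 9.0
        assert rec.achieved_sbr == 10.0

    def test_sbr_is_bpi_plus_one(self, default_geometry):
        for seed in range(5):
            _, rec = fill_activities(default_geometry, 7, jitter_cv=0.2, seed=seed)
            assert rec.achieved_sbr == rec.achieved_bpi + 1.0

    @pytest.mark.parametrize(
        "ratio,level",
        [(10, "high"), (8, "high"), (7, "intermediary"), (5, "intermediary"),
         (4, "low"), (2, "low")],
    )
    def test_activity_levels(self, ratio, level):
        assert activity_level_for_ratio(ratio) == level

    def test_ratio_below_one_errors(self, default_geometry):
        with pytest.raises(ValueError):
            fill_activities(default_geometry, 0.5)

    def test_jitter_monte_carlo(self, default_geometry):
        # 1000 draws at ratio 10, CV 0.10: mean within 3 %, sd/mean in band
        ratios = np.array([
            fill_activities(default_geometry, 10, jitter_cv=0.10, seed=s)[1].achieved_ratio
            for s in range(1000)
        ])
        assert abs(ratios.mean() - 10.0) / 10.0 < 0.03
        assert 0.07 <= ratios.std() / ratios.mean() <= 0.13

    def test_outside_phantom_is_zero(self, default_geometry):
        activity, _ = fill_activities(default_geometry, 5, jitter_cv=0.0, seed=0)
        assert np.all(activity[default_geometry.label_volume == 0] == 0)


class TestSimulateSpect:
    def test_normalization_contract(self, tiny):
        geometry, _ = tiny
        activity, rec = fill_activities(geometry, 10, jitter_cv=0.0, seed=0)
        cfg = AcquisitionConfig(matrix_size=48, n_slices=48, voxel_size=4.0,
                                expected_total_counts=1e5, seed=0)
        acq = simulate_spect(activity, cfg, geometry, fill=rec, noiseless=True)
        # expected image is normalized exactly; the post-filter conserves
        # counts up to border leakage < 0.1 %
        assert abs(acq.counts_volume.sum() - 1e5) / 1e5 < 1e-3

    def test_zero_blur_noiseless_proportional_to_activity(self, default_geometry):
        activity, rec = fill_activities(default_geometry, 10, jitter_cv=0.0, seed=0)
        cfg = AcquisitionConfig(psf_fwhm=0.0, post_filter_fwhm=0.0, seed=0)
        acq = simulate_spect(activity, cfg, default_geometry, fill=rec,
                             noiseless=True)
        scale = acq.counts_volume.sum() / activity.sum()
        assert np.allclose(acq.counts_volume, activity * scale, rtol=1e-9)

    def test_fixed_seed_bit_identical(self, tiny):
        geometry, _ = tiny
        activity, rec = fill_activities(geometry, 5, jitter_cv=0.0, seed=0)
        cfg = AcquisitionConfig(matrix_size=48, n_slices=48, voxel_size=4.0,
                                expected_total_counts=1e5, seed=42)
        a = simulate_spect(activity, cfg, geometry, fill=rec)
        b = simulate_spect(activity, cfg, geometry, fill=rec)
        assert np.array_equal(a.counts_volume, b.counts_volume)

    def test_nonfinite_activity_errors(self, tiny):
        geometry, _ = tiny
        activity = np.full(geometry.shape, np.nan)
        with pytest.raises(ValueError):
            simulate_spect(activity, AcquisitionConfig(matrix_size=48, n_slices=48,
                                                       voxel_size=4.0), geometry)

    def test_counts_nonnegative(self, tiny):
        _, acq = tiny
        assert np.all(acq.counts_volume >= 0)

    def test_poisson_variance_over_replicates(self, tiny):
        # summed counts in a fixed mask are Poisson before post-filtering:
        # variance/mean of the sum over replicates must be near 1
        geometry, _ = tiny
        activity, rec = fill_activities(geometry, 5, jitter_cv=0.0, seed=0)
        mask = geometry.striatal_mask
        sums = []
        for s in range(300):
            cfg = AcquisitionConfig(matrix_size=48, n_slices=48, voxel_size=4.0,
                                    expected_total_counts=2e5,
                                    post_filter_fwhm=0.0, seed=1000 + s)
            acq = simulate_spect(activity, cfg, geometry, fill=rec)
            sums.append(acq.counts_volume[mask].sum())
        sums = np.asarray(sums)
        assert 0.8 <= sums.var() / sums.mean() <= 1.2

    def test_striatal_counts_increase_with_ratio(self, default_geometry):
        means = []
        for ratio in (2, 4, 6, 8, 10):
            activity, rec = fill_activities(default_geometry, ratio,
                                            jitter_cv=0.0, seed=0)
            acq = simulate_spect(activity, AcquisitionConfig(seed=0),
                                 default_geometry, fill=rec, noiseless=True)
            means.append(acq.counts_volume[default_geometry.striatal_mask].mean())
        assert np.all(np.diff(means) > 0)


class TestGenerateStudy:
    def test_default_design_counts(self, default_geometry):
        _, acqs = generate_study(master_seed=0, geometry=default_geometry,
                                 noiseless=True)
        assert len(acqs) == 23
        levels = [a.fill.activity_level for a in acqs]
        assert levels.count("high") == 8
        assert levels.count("intermediary") == 8
        assert levels.count("low") == 7

    def test_single_acquisition_design(self, default_geometry):
        _, acqs = generate_study(design=[(10, 1)], master_seed=0,
                                 geometry=default_geometry, noiseless=True)
        assert len(acqs) == 1
        assert acqs[0].fill.activity_level == "high"

    def test_same_master_seed_identical_fills(self, default_geometry):
        _, a = generate_study(master_seed=3, geometry=default_geometry,
                              noiseless=True)
        _, b = generate_study(master_seed=3, geometry=default_geometry,
                              noiseless=True)
        assert [x.fill.to_dict() for x in a] == [y.fill.to_dict() for y in b]

    def test_empty_design_errors(self, default_geometry):
        with pytest.raises(ValueError):
            generate_study(design=[], geometry=default_geometry)
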