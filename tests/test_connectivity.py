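"""Motion indices, censoring, nuisance regression, FC, networks, ReHo."""

import numpy as np
import pandas as pd
import pytest

from rotorelax import connectivity as cn


class TestFramewiseDisplacement:
    def test_constant_trace_gives_zero(self):
        m = np.tile([0.3, -0.1, 0.2, 0.01, 0.0, -0.02], (50, 1))
        assert np.allclose(cn.framewise_displacement(m), 0.0)

    def test_single_translation_step(self):
        m = np.zeros((30, 6))
        m[12:, 0] = 0.2  # 0.2 mm x step between frames 11 and 12
        fd = cn.framewise_displacement(m, sphere_radius=50)
        expected = np.zeros(30)
        expected[12] = 0.2
        assert np.allclose(fd, expected)

    def test_matches_direct_summation_oracle(self, rng):
        m = rng.normal(0, 0.05, (40, 6))
        fd = cn.framewise_displacement(m, sphere_radius=50)
        for t in range(1, 40):
            direct = sum(abs(m[t, j] - m[t - 1, j]) for j in range(3))
            direct += 50 * sum(abs(m[t, j] - m[t - 1, j]) for j in range(3, 6))
            assert fd[t] == pytest.approx(direct, rel=1e-12)
        assert fd[0] == 0.0

    def test_nonfinite_parameters_rejected(self):
        m = np.zeros((5, 6))
        m[2, 1] = np.inf
        with pytest.raises(ValueError, match="finite"):
            cn.framewise_displacement(m)


class TestCensoring:
    def test_quiet_trace_keeps_everything(self):
        m = np.zeros((100, 6))
        cm = cn.censor_mask(m, threshold=0.33)
        assert cm.n_kept == 100 and cm.keep.all()

    def test_suprathreshold_frame_removes_itself_and_previous(self):
        m = np.zeros((200, 6))
        m[100:, 0] = 0.5  # derivative only at frame 100
        cm = cn.censor_mask(m, threshold=0.33)
        removed = np.flatnonzero(~cm.keep)
        assert removed.tolist() == [99, 100]
        assert cm.n_kept == 198

    def test_consecutive_spikes_remove_union_without_double_count(self):
        m = np.zeros((200, 6))
        m[50, 0] = 0.5   # spike at 50: derivatives at 50 and 51 exceed
        cm = cn.censor_mask(m, threshold=0.33)
        assert np.flatnonzero(~cm.keep).tolist() == [49, 50, 51]
        # staircase: derivatives at 60 and 61
        m2 = np.zeros((200, 6))
        m2[60, 0] = 0.5
        m2[61:, 0] = 1.0
        cm2 = cn.censor_mask(m2, threshold=0.33)
        assert np.flatnonzero(~cm2.keep).tolist() == [59, 60, 61]

    def test_rotations_converted_via_sphere_radius(self):
        m = np.zeros((50, 6))
        m[10:, 3] = 0.008  # 0.008 rad * 50 mm = 0.4 mm > 0.33
        cm = cn.censor_mask(m, threshold=0.33, sphere_radius=50)
        assert not cm.keep[10] and not cm.keep[9]
        cm2 = cn.censor_mask(m, threshold=0.33, sphere_radius=10)
        assert cm2.keep.all()

    def test_dof_is_kept_minus_design_rank(self, rng):
        m = np.zeros((100, 6))
        m[40, 0] = 0.5
        design = rng.normal(size=(100, 7))
        cm = cn.censor_mask(m, threshold=0.33, design=design, min_dof=20)
        assert cm.n_kept == 97
        assert cm.dof_remaining == 97 - 7
        assert not cm.excluded

    def test_high_motion_subject_flagged_excluded(self, rng):
        m = np.zeros((60, 6))
        m[np.arange(2, 58, 3), 0] = 0.5  # dense spikes
        design = rng.normal(size=(60, 10))
        cm = cn.censor_mask(m, threshold=0.33, design=design, min_dof=20)
        assert cm.excluded
        assert cm.dof_remaining < 20


class TestNuisanceDesign:
    def _sim(self, rng, n=120, shape=(10, 10, 6)):
        bold = rng.normal(size=shape + (n,))
        motion = rng.normal(0, 0.01, (n, 6))
        wm = np.zeros(shape, bool)
        wm[1:9, 1:9, 1:5] = True
        csf = np.zeros(shape, bool)
        csf[3:8, 3:8, 1:5] = False
        csf[0:9, 0:9, 0:6] = False
        csf[2:9, 2:9, 2:5] = True
        return bold, motion, wm, csf

    def test_spectral_columns_match_frequency_grid_enumeration(self):
        n, tr = 492, 0.9
        cols = cn.spectral_regressors(n, tr, (0.01, 0.1))
        expected = 0
        for k in range(1, n // 2 + 1):
            f = k / (n * tr)
            if f < 0.01 or f > 0.1:
                expected += 1 if (n % 2 == 0 and k == n // 2) else 2
        assert cols.shape == (n, expected)
        # every retained column's dominant frequency is outside the band
        spec = np.abs(np.fft.rfft(cols, axis=0))
        freqs = np.fft.rfftfreq(n, tr)
        dom = freqs[np.argmax(spec, axis=0)]
        assert ((dom < 0.01) | (dom > 0.1)).all()

    def test_column_group_sizes(self, rng):
        bold, motion, wm, csf = self._sim(rng)
        d = cn.nuisance_design(motion, bold, wm, csf, tr=0.9,
                               wm_erosion=1, csf_erosion=1)
        counts = pd.Series(d.column_groups).value_counts()
        assert counts["legendre"] == 3
        assert counts["motion"] == 6
        assert counts["motion_derivative"] == 6
        assert counts["wm_compcor"] == 5
        assert counts["csf_compcor"] == 5

    def test_planted_wm_component_recovered(self, rng):
        bold, motion, wm, csf = self._sim(rng, n=150)
        planted = np.sin(2 * np.pi * 7 * np.arange(150) / 150)
        bold[wm] += 5.0 * planted
        d = cn.nuisance_design(motion, bold, wm, csf, tr=0.9,
                               wm_erosion=1, csf_erosion=1)
        pc1 = d.group_columns("wm_compcor")[:, 0]
        r = np.corrcoef(pc1, planted - planted.mean())[0, 1]
        assert abs(r) > 0.99

    def test_zero_variance_voxels_tolerated(self, rng):
        bold, motion, wm, csf = self._sim(rng)
        bold[wm] = np.where(rng.random(bold[wm].shape) < 0.2, 0.0, bold[wm])
        bold[2, 2, 2, :] = 0.0
        d = cn.nuisance_design(motion, bold, wm, csf, tr=0.9,
                               wm_erosion=1, csf_erosion=1)
        assert np.isfinite(d.matrix).all()

    def test_empty_mask_after_erosion_suggests_smaller_erosion(self, rng):
        bold, motion, wm, csf = self._sim(rng)
        with pytest.raises(ValueError, match="erosion"):
            cn.nuisance_design(motion, bold, wm, csf, tr=0.9, wm_erosion=8)


class TestDenoise:
    def test_design_column_regressed_to_zero(self, rng):
        design = np.column_stack([np.ones(80), rng.normal(size=80)])
        bold = np.tile(design[:, 1], (2, 2, 2, 1)) * 3.5
        resid, dof = cn.denoise(bold, design)
        assert np.allclose(resid, 0.0, atol=1e-10)
        assert dof == 78

    def test_intercept_only_demeans(self, rng):
        bold = rng.normal(5.0, 1.0, (3, 3, 3, 50))
        resid, dof = cn.denoise(bold, np.ones((50, 1)))
        assert np.allclose(resid, bold - bold.mean(axis=-1, keepdims=True))
        assert dof == 49

    def test_censored_frames_absent_from_output(self, rng):
        bold = rng.normal(size=(2, 2, 2, 40))
        keep = np.ones(40, bool)
        keep[[5, 6, 20]] = False
        cm = cn.CensorMask(keep, int(keep.sum()), None)
        resid, dof = cn.denoise(bold, np.ones((40, 1)), cm)
        assert resid.shape[-1] == 37
        assert dof == 36

    def test_orthogonal_signal_survives_regression(self, rng):
        n = 200
        design = np.column_stack([np.ones(n), np.linspace(-1, 1, n)])
        signal = np.sin(2 * np.pi * np.arange(n) * 10 / n)  # orthogonal-ish
        bold = (rng.normal(size=(4, 4, 2, n)) * 0.1 + signal).astype(float)
        resid, _ = cn.denoise(bold, design)
        amp = resid.reshape(-1, n) @ signal / (signal @ signal)
        assert np.abs(1 - amp).max() < 0.05

    def test_frame_relabeling_commutes_with_censored_regression(self, rng):
        # permuting frames (data + regressors + mask consistently) permutes
        # the kept-frame residuals and nothing else
        n = 60
        design = rng.normal(size=(n, 4))
        bold = rng.normal(size=(3, 3, 1, n))
        keep = rng.random(n) > 0.2
        cm = cn.CensorMask(keep, int(keep.sum()), None)
        r1, d1 = cn.denoise(bold, design, cm)
        perm = rng.permutation(n)
        cmp_ = cn.CensorMask(keep[perm], int(keep.sum()), None)
        r2, d2 = cn.denoise(bold[..., perm], design[perm], cmp_)
        # each kept frame's residual is the same regardless of frame order
        kept_orig = np.flatnonzero(keep).tolist()
        kept_perm = perm[keep[perm]]
        idx = [kept_orig.index(f) for f in kept_perm]
        assert np.allclose(r2, r1[..., idx], atol=1e-10)
        assert d1 == d2


class TestSmoothness:
    def test_white_noise_smoothed_to_four_mm(self, rng):
        x = rng.standard_normal((40, 40, 24, 6))
        sm = cn.smooth_to_fwhm(x, 4.0, (2.0, 2.0, 3.0))
        est = cn.estimate_fwhm(sm, (2.0, 2.0, 3.0))
        assert np.nanmean(est) == pytest.approx(4.0, abs=0.5)

    def test_zero_target_is_identity(self, rng):
        x = rng.standard_normal((8, 8, 8, 3))
        assert cn.smooth_to_fwhm(x, 0.0, (2, 2, 2)) is x

    def test_target_below_intrinsic_is_noop_with_warning(self, rng, caplog):
        x = rng.standard_normal((20, 20, 12, 4))
        sm = cn.smooth_to_fwhm(x, 6.0, (2.0, 2.0, 2.0))
        import logging

        with caplog.at_level(logging.WARNING, logger="rotorelax.connectivity"):
            again = cn.smooth_to_fwhm(sm, 3.0, (2.0, 2.0, 2.0))
        assert again is sm
        assert "intrinsic" in caplog.text

    def test_resmoothing_to_same_target_is_nearly_idempotent(self, rng):
        x = rng.standard_normal((36, 36, 20, 4))
        once = cn.smooth_to_fwhm(x, 6.0, (2.0, 2.0, 2.0))
        twice = cn.smooth_to_fwhm(once, 6.0, (2.0, 2.0, 2.0))
        e1 = np.nanmean(cn.estimate_fwhm(once, (2, 2, 2)))
        e2 = np.nanmean(cn.estimate_fwhm(twice, (2, 2, 2)))
        assert abs(e2 - e1) < 0.6


class TestFisherZ:
    def test_zero_correlation_is_fixed_point(self):
        assert cn.fisher_z(0.0, 55) == 0.0

    def test_closed_form_example(self):
        assert cn.fisher_z(0.5, 52) == pytest.approx(np.arctanh(0.5) * 7)

    def test_monotone_in_dof(self):
        zs = [cn.fisher_z(0.4, d) for d in (10, 30, 100)]
        assert zs[0] < zs[1] < zs[2]

    def test_perfect_correlation_clipped_finite(self):
        assert np.isfinite(cn.fisher_z(1.0, 20))
        with pytest.raises(ValueError):
            cn.fisher_z(0.5, 3)

    def test_seed_fc_invariant_to_affine_bold_rescaling(self, rng):
        labels = np.zeros((6, 6, 4), int)
        labels[:2, :2, :2] = 1
        bold = rng.normal(size=(6, 6, 4, 60))
        a = cn.seed_fc(bold, labels, [1], dof=40)
        b = cn.seed_fc(3.7 * bold + 11.0, labels, [1], dof=40)
        assert np.allclose(a.z, b.z, atol=1e-10)

    def test_zero_variance_voxel_flagged(self, rng):
        labels = np.zeros((4, 4, 2), int)
        labels[0, 0, 0] = 1
        labels[0, 1, 0] = 1
        bold = rng.normal(size=(4, 4, 2, 30))
        bold[3, 3, 1] = 0.0
        fc = cn.seed_fc(bold, labels, [1], dof=25)
        assert fc.z[3, 3, 1] == 0.0
        assert not fc.valid_mask[3, 3, 1]


class TestNetworkDefinition:
    def _maps(self, rng, blob, n_maps=10, z0=5.0, shape=(12, 12, 8)):
        maps = []
        for _ in range(n_maps):
            z = rng.normal(0, 0.05, shape)
            z[blob] += z0 + rng.normal(0, 0.2)
            maps.append(z)
        return maps

    def test_planted_blob_recovered_exactly(self, rng):
        blob = np.zeros((12, 12, 8), bool)
        blob[2:7, 3:6, 2:4] = True  # 30 voxels, connected
        net = cn.define_network(self._maps(rng, blob), 0.0005, 20)
        assert np.array_equal(net.mask, blob)

    def test_small_blob_rejected_by_cluster_threshold(self, rng):
        blob = np.zeros((12, 12, 8), bool)
        blob[2:7, 3:5, 2] = True  # 10 voxels
        net = cn.define_network(self._maps(rng, blob), 0.0005, 20)
        assert not net.mask.any()

    def test_threshold_agrees_with_direct_t_oracle(self, rng):
        from scipy import stats

        maps = [rng.normal(0.4, 1.0, (6, 6, 4)) for _ in range(8)]
        net = cn.define_network(maps, alpha=0.05, min_cluster=1)
        stack = np.stack(maps)
        mean = stack.mean(0)
        se = stack.std(0, ddof=1) / np.sqrt(8)
        p = stats.t.sf(mean / se, df=7)
        assert np.array_equal(net.mask, p < 0.05)

    def test_fewer_than_three_maps_rejected(self, rng):
        with pytest.raises(ValueError, match="3"):
            cn.define_network([rng.normal(size=(4, 4, 4))] * 2)


class TestNetworkStrength:
    def test_constant_map_returns_the_constant(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[1:3, 1:3, 1:3] = True
        z = np.full((5, 5, 5), 2.25)
        assert cn.network_strength(z, mask) == pytest.approx(2.25)

    def test_empty_network_is_nan(self):
        assert np.isnan(cn.network_strength(np.ones((3, 3, 3)),
                                            np.zeros((3, 3, 3), bool)))


def _brute_force_w(series):
    """Literal textbook computation with pandas mid-ranks."""
    m, n = series.shape
    ranks = np.stack([pd.Series(row).rank().to_numpy() for row in series])
    r = ranks.sum(axis=0)
    s = ((r - r.mean()) ** 2).sum()
    ties = 0.0
    for row in series:
        for _, cnt in pd.Series(row).value_counts().items():
            ties += cnt**3 - cnt
    return 12 * s / (m**2 * (n**3 - n) - m * ties)


class TestReHo:
    def test_identical_series_give_unit_w(self):
        x = np.tile(np.arange(10.0), (19, 1))
        assert cn.kendall_w(x) == pytest.approx(1.0)

    def test_hand_built_three_by_four_matches_brute_force(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0],
                      [2.0, 1.0, 4.0, 3.0],
                      [1.0, 3.0, 2.0, 4.0]])
        assert cn.kendall_w(x) == pytest.approx(_brute_force_w(x))

    def test_random_neighborhoods_match_brute_force_with_ties(self, rng):
        for i in range(20):
            x = rng.normal(size=(19, 12))
            if i % 2:
                x = np.round(x)  # force ties
            assert cn.kendall_w(x) == pytest.approx(_brute_force_w(x),
                                                    rel=1e-10)

    def test_map_routine_equals_per_voxel_kendall_w(self, rng):
        shape = (5, 4, 3)
        bold = rng.normal(size=shape + (8,))
        bold[bold > 1.0] = 1.0  # introduce ties
        mask = rng.random(shape) > 0.2
        rh = cn.reho(bold, mask)
        offs = [(dx, dy, dz)
                for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                if abs(dx) + abs(dy) + abs(dz) in (1, 2)]
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    if not mask[i, j, k]:
                        assert not rh.valid_mask[i, j, k]
                        continue
                    members = [bold[i, j, k]]
                    for dx, dy, dz in offs:
                        a, b, c = i + dx, j + dy, k + dz
                        if (0 <= a < shape[0] and 0 <= b < shape[1]
                                and 0 <= c < shape[2] and mask[a, b, c]):
                            members.append(bold[a, b, c])
                    if len(members) < 3:
                        assert not rh.valid_mask[i, j, k]
                        continue
                    expect = _brute_force_w(np.stack(members))
                    assert rh.w[i, j, k] == pytest.approx(expect, rel=1e-9), \
                        (i, j, k)

    def test_invariant_under_monotone_transform(self, rng):
        bold = rng.normal(size=(6, 6, 4, 10))
        mask = np.ones((6, 6, 4), bool)
        a = cn.reho(bold, mask)
        b = cn.reho(np.exp(bold), mask)  # strictly monotone
        assert np.allclose(a.w[a.valid_mask], b.w[b.valid_mask], atol=1e-12)

    def test_standardized_map_has_zero_mean_unit_sd(self, rng):
        bold = rng.normal(size=(8, 8, 5, 12))
        rh = cn.reho(bold, np.ones((8, 8, 5), bool))
        assert np.nanmean(rh.z[rh.valid_mask]) == pytest.approx(0.0, abs=1e-10)
        assert np.nanstd(rh.z[rh.valid_mask]) == pytest.approx(1.0, abs=1e-10)

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ValueError, match="4 time frames"):
            cn.reho(rng.normal(size=(4, 4, 4, 3)), np.ones((4, 4, 4), bool))
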