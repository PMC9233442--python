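"""Per-subject mapping: filtering, nuisance design, seed GLM, smoothing,
and the map-level normalizations."""

import numpy as np
import pytest

from varconn import rsfc, synth
from varconn.rsfc import (bandpass, bandpass_response, build_nuisance_design,
                          demean_by_subgroup, extract_seed_timecourse,
                          seed_glm_map, site_standardize,
                          site_standardize_voxelwise, smooth_map)

from conftest import tiny_spec


class TestBandpass:
    def test_dc_removed(self, rng):
        x = np.full(200, 7.3) + 0.01 * rng.standard_normal(200)
        y = bandpass(x, tr=2.0)
        assert abs(y.mean()) < 1e-10

    def test_invalid_band_for_tr(self):
        with pytest.raises(ValueError, match="invalid band"):
            bandpass(np.zeros(100), tr=6.0, low_hz=0.01, high_hz=0.1)

    @pytest.mark.parametrize("freq,in_band", [(0.05, True), (0.2, False), (0.003, False)])
    def test_sinusoid_attenuation(self, freq, in_band):
        tr, n = 2.0, 400
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * freq * t)
        y = bandpass(x, tr)
        ratio = y.std() / x.std()
        if in_band:
            assert ratio > 0.9
        else:
            assert ratio < 0.1

    def test_amplitude_matches_analytic_response(self):
        """A pure in-band sinusoid comes out scaled by the filter's
        frequency response at its own frequency."""
        tr, n = 2.0, 400
        f_target = 25 / (n * tr)            # exactly on an FFT bin
        t = np.arange(n) * tr
        x = np.cos(2 * np.pi * f_target * t)
        y = bandpass(x, tr)
        f, resp = bandpass_response(n, tr)
        expected = resp[np.argmin(np.abs(f - f_target))]
        assert y.std() / x.std() == pytest.approx(expected, abs=1e-9)


class TestSeedExtraction:
    def test_empty_mask(self):
        with pytest.raises(ValueError, match="empty"):
            extract_seed_timecourse(np.zeros((4, 4, 4, 10)), np.zeros((4, 4, 4), bool))

    def test_constant_seed(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="zero variance"):
            extract_seed_timecourse(np.ones((4, 4, 4, 10)), mask)

    def test_single_voxel_z_scored(self, rng):
        bold = rng.standard_normal((3, 3, 3, 50))
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 2, 0] = True
        ts = extract_seed_timecourse(bold, mask)
        ref = bold[1, 2, 0]
        assert np.allclose(ts, (ref - ref.mean()) / ref.std())


class TestNuisanceDesign:
    def _session(self, n_t=50, motion=None, rng=None):
        rng = rng or np.random.default_rng(0)
        bold = rng.standard_normal((6, 6, 6, n_t)).astype(np.float32)
        motion = motion if motion is not None else rng.standard_normal((n_t, 6))
        return synth.ScanSession("s", "blind", "A", 30, 12, 2.0, bold, motion)

    def test_column_counts(self):
        ses = self._session()
        wm = np.zeros((6, 6, 6), bool); wm[0] = True
        vent = np.zeros((6, 6, 6), bool); vent[1] = True
        X = build_nuisance_design(ses, wm, vent, use_global=False)
        assert X.shape[1] == 15                     # 6 + 6 + 2 + intercept
        Xg = build_nuisance_design(ses, wm, vent, use_global=True)
        assert Xg.shape[1] == 16

    def test_zero_motion_flagged_degenerate(self):
        ses = self._session(motion=np.zeros((50, 6)))
        wm = np.zeros((6, 6, 6), bool); wm[0] = True
        vent = np.zeros((6, 6, 6), bool); vent[1] = True
        with pytest.warns(UserWarning, match="degenerate"):
            X = build_nuisance_design(ses, wm, vent)
        assert np.allclose(X[:, :12], 0.0)

    def test_length_mismatch(self):
        ses = self._session()
        wm = np.zeros((6, 6, 6), bool); wm[0] = True
        with pytest.raises(ValueError, match="timepoints"):
            build_nuisance_design(ses, wm, wm, motion=np.zeros((45, 6)))

    def test_backward_difference_convention(self):
        motion = np.cumsum(np.ones((10, 6)), axis=0)
        ses = self._session(n_t=10, motion=motion)
        wm = np.zeros((6, 6, 6), bool); wm[0] = True
        vent = np.zeros((6, 6, 6), bool); vent[1] = True
        with pytest.warns(UserWarning):
            X = build_nuisance_design(ses, wm, vent)
        # constant-step walk: derivative is constant except the padded 0 row
        deriv_col = X[:, 6]
        assert deriv_col[0] == deriv_col.min()
        assert np.allclose(deriv_col[2:], deriv_col[1])


class TestSeedGLM:
    def test_perfect_predictor(self, rng):
        n_t = 60
        seed = rng.standard_normal(n_t)
        bold = np.zeros((2, 2, 1, n_t))
        bold[0, 0, 0] = seed
        bold[1, 1, 0] = rng.standard_normal(n_t)
        mask = np.ones((2, 2, 1), bool)
        design = np.ones((n_t, 1))
        tmap, bmap, dof = seed_glm_map(bold, seed, design, mask)
        assert bmap.data[0, 0, 0] == pytest.approx(1.0, abs=1e-9)
        assert tmap.data[0, 0, 0] > 1e3 or np.isinf(tmap.data[0, 0, 0])

    def test_orthogonal_voxel_beta_zero(self):
        n_t = 64
        t = np.arange(n_t)
        seed = np.cos(2 * np.pi * 4 * t / n_t)
        ortho = np.sin(2 * np.pi * 4 * t / n_t)
        bold = np.zeros((1, 1, 1, n_t))
        bold[0, 0, 0] = ortho
        tmap, bmap, _ = seed_glm_map(bold, seed, np.ones((n_t, 1)),
                                     np.ones((1, 1, 1), bool))
        assert abs(bmap.data[0, 0, 0]) < 1e-9

    def test_matches_normal_equations_oracle(self, rng):
        """10-timepoint worked example against explicit OLS algebra."""
        n_t = 10
        seed = rng.standard_normal(n_t)
        nuis = np.column_stack([rng.standard_normal(n_t), np.ones(n_t)])
        y = rng.standard_normal(n_t)
        bold = y.reshape(1, 1, 1, n_t)
        tmap, bmap, dof = seed_glm_map(bold, seed, nuis, np.ones((1, 1, 1), bool))

        yz = (y - y.mean()) / y.std()
        sz = (seed - seed.mean()) / seed.std()
        X = np.column_stack([sz, nuis])
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ yz
        resid = yz - X @ beta
        df = n_t - X.shape[1]
        t_oracle = beta[0] / np.sqrt(resid @ resid / df * XtX_inv[0, 0])
        assert bmap.data[0, 0, 0] == pytest.approx(beta[0], abs=1e-10)
        assert tmap.data[0, 0, 0] == pytest.approx(t_oracle, abs=1e-10)
        assert dof == df

    def test_degenerate_voxel_nan(self):
        n_t = 20
        bold = np.zeros((1, 2, 1, n_t))
        bold[0, 1, 0] = np.random.default_rng(0).standard_normal(n_t)
        seed = np.random.default_rng(1).standard_normal(n_t)
        with pytest.warns(UserWarning, match="degenerate"):
            tmap, _, _ = seed_glm_map(bold, seed, np.ones((n_t, 1)),
                                      np.ones((1, 2, 1), bool))
        assert np.isnan(tmap.data[0, 0, 0])
        assert np.isfinite(tmap.data[0, 1, 0])


class TestSmoothing:
    def test_fwhm_zero_identity(self, rng):
        m = rng.standard_normal((8, 8, 8))
        assert np.array_equal(smooth_map(m, 0.0, 3.0), m)

    def test_impulse_fwhm_within_5pct(self):
        grid = np.zeros((31, 31, 31))
        grid[15, 15, 15] = 1.0
        out = smooth_map(grid, 6.0, voxel_size_mm=3.0,
                         mask=np.ones(grid.shape, bool))
        profile = out[:, 15, 15]
        # moment-based sigma of the impulse response
        x = (np.arange(31) - 15) * 3.0
        sigma = np.sqrt((profile * x ** 2).sum() / profile.sum())
        fwhm = sigma * 2 * np.sqrt(2 * np.log(2))
        assert fwhm == pytest.approx(6.0, rel=0.05)

    def test_mask_renormalization_keeps_constant(self):
        m = np.full((10, 10, 10), 3.7)
        mask = np.zeros((10, 10, 10), bool)
        mask[2:8, 2:8, 2:8] = True
        out = smooth_map(np.where(mask, m, np.nan), 6.0, 3.0, mask)
        assert np.allclose(out[mask], 3.7)
        assert np.isnan(out[0, 0, 0])


class TestStandardization:
    def test_per_subject_mean0_sd1(self, rng):
        v = rng.standard_normal((6, 100)) * 3 + 1
        out = site_standardize(v)
        assert np.allclose(out.mean(1), 0, atol=1e-9)
        assert np.allclose(out.std(1), 1, atol=1e-9)

    def test_affine_site_effect_removed(self, rng):
        v = rng.standard_normal((6, 100))
        cohorts = np.array(["A", "A", "A", "B", "B", "B"])
        v2 = v.copy()
        v2[cohorts == "B"] = v2[cohorts == "B"] * 2.0 + 0.5
        assert np.allclose(site_standardize(v, cohorts), site_standardize(v2, cohorts))

    def test_zero_sd_map_errors(self):
        v = np.vstack([np.ones(50), np.random.default_rng(0).standard_normal(50)])
        with pytest.raises(ValueError, match="zero-SD"):
            site_standardize(v)

    def test_voxelwise_preserves_variance_ratio(self, rng):
        """Per-voxel within-cohort scaling must leave the blind/sighted
        variance ratio at every voxel untouched."""
        v = rng.standard_normal((20, 60))
        v[:8] *= 3.0                      # blind more variable
        cohorts = np.array(["A"] * 20)
        groups = np.array(["blind"] * 8 + ["sighted"] * 12)
        out = site_standardize_voxelwise(v, cohorts)
        before = v[:8].var(0, ddof=1) / v[8:].var(0, ddof=1)
        after = out[:8].var(0, ddof=1) / out[8:].var(0, ddof=1)
        assert np.allclose(before, after, rtol=1e-12)
        assert np.allclose(out.mean(0), 0, atol=1e-9)


class TestDemeaning:
    def test_cell_means_zero_variance_kept(self, rng):
        v = rng.standard_normal((12, 40)) + 5
        groups = np.array(["blind"] * 6 + ["sighted"] * 6)
        cohorts = np.tile(["A", "A", "A", "B", "B", "B"], 2)
        out = demean_by_subgroup(v, groups, cohorts)
        for g in ("blind", "sighted"):
            for c in ("A", "B"):
                cell = (groups == g) & (cohorts == c)
                assert np.allclose(out[cell].mean(0), 0, atol=1e-9)
                assert np.allclose(out[cell].var(0), v[cell].var(0), atol=1e-9)

    def test_singleton_cell_errors(self, rng):
        v = rng.standard_normal((3, 10))
        with pytest.raises(ValueError, match="singleton"):
            demean_by_subgroup(v, ["blind", "blind", "sighted"], ["A", "A", "A"])


class TestPipeline:
    def test_near_noise_free_rank_recovery(self):
        """With vanishing noise the unsmoothed t map ranks voxels like the
        planted weights (t is monotone in the weight at fixed noise)."""
        from scipy.stats import spearmanr

        spec = tiny_spec(noise_sd=0.05, motion_coupling=0.0, nuisance_leak_sd=0.0)
        sessions, atlas, parts, truth = synth.simulate_study(spec)
        values, groups, cohorts = rsfc.study_connectivity_maps(
            sessions[:3], atlas, smoothing_fwhm_mm=0.0, standardize=None)
        lab = atlas.labels[atlas.gray_mask]
        for i in range(3):
            # parcel-level ranking (within-parcel planted values are tied)
            est = [values[i][lab == r].mean() for r in range(1, 7)]
            rho = spearmanr(est, truth.weight_by_subject_region[i]).statistic
            assert rho > 0.99

    def test_subject_order_equivariance(self, small_study):
        sessions, atlas, parts, truth = small_study
        v1, g1, _ = rsfc.study_connectivity_maps(sessions[:6], atlas)
        order = [3, 0, 5, 1, 4, 2]
        v2, g2, _ = rsfc.study_connectivity_maps([sessions[i] for i in order], atlas)
        assert np.allclose(v1[order], v2, atol=1e-9)

    def test_global_variant_same_grid(self, small_study):
        sessions, atlas, *_ = small_study
        v0, *_ = rsfc.study_connectivity_maps(sessions[:4], atlas)
        v1, *_ = rsfc.study_connectivity_maps(sessions[:4], atlas, use_global=True)
        assert v0.shape == v1.shape
        assert np.isfinite(v1).all()
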