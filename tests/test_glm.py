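"""Design construction, AR(1)-whitened fitting, contrasts, smoothing."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from faceprint.glm import (
    GLMOptions,
    SmoothingParams,
    StatMap,
    build_design_matrix,
    conjunction_min_t,
    contrast_tmap,
    fit_glm,
    group_ttest,
    polarity_reference,
    roi_condition_means,
    smooth_volume,
    t_critical,
)
from faceprint.synth import (
    Acquisition,
    NoiseParams,
    StimulusSchedule,
    build_schedule,
    make_subject_template,
    simulate_session,
)


def _empty_schedule(conditions=("faces", "houses")):
    return StimulusSchedule((), (), 0.0, conditions)


class TestDesignMatrix:
    def test_empty_schedule_gives_zero_condition_columns(self):
        d = build_design_matrix(_empty_schedule(), 2.0, 20)
        for name in ("faces", "houses"):
            assert np.all(d.matrix[:, d.names.index(name)] == 0)
        assert "constant" in d.names

    def test_drift_column_count_closed_form(self):
        # number of cosines with k/(2*T) < cutoff, k >= 1
        tr, n, cutoff = 1.7, 331, 1.0 / 128.0
        d = build_design_matrix(_empty_schedule(), tr, n)
        k_expected = sum(
            1 for k in range(1, n) if k / (2 * n * tr) < cutoff
        )
        n_drift = sum(1 for name in d.names if name.startswith("drift_"))
        assert n_drift == k_expected == 8

    def test_block_regressor_matches_numerical_convolution_oracle(self):
        """Independent oracle: direct numerical convolution of a 16 s boxcar
        with the double-gamma HRF, on its own fine grid."""
        from nilearn.glm.first_level import spm_hrf

        sched = build_schedule(1, 1, 20, 0.8, 0.0)
        tr, n = 0.5, 100
        d = build_design_matrix(sched, tr, n, drift=False)
        reg = d.matrix[:, 0]

        dt = 0.01
        t = np.arange(0, 60, dt)
        box = ((t >= 0) & (t < 16.0)).astype(float)
        h = spm_hrf(dt, oversampling=1, time_length=32.0)
        h = h / (h.sum() * dt)
        oracle = np.convolve(box, h)[: len(t)] * dt
        oracle_at_frames = np.interp(np.arange(n) * tr, t, oracle)
        np.testing.assert_allclose(reg, oracle_at_frames, atol=5e-3)
        # haemodynamic lag: the response to a 16 s block peaks late in the
        # block, several seconds after onset but before block end + lag
        t_peak = (np.arange(n) * tr)[np.argmax(reg)]
        assert 8.0 <= t_peak <= 16.0

    def test_schedule_beyond_scan_rejected(self):
        sched = build_schedule(4, 8, 20, 0.8, 27.0)
        with pytest.raises(ValueError, match="scan"):
            build_design_matrix(sched, 1.7, 100)

    def test_condition_columns_zero_before_onset(self):
        sched = build_schedule(1, 1, 20, 0.8, 0.0, start_s=30.0)
        d = build_design_matrix(sched, 1.0, 60, drift=False)
        assert np.all(d.matrix[:30, 0] == 0)
        assert d.matrix[:, 0].max() > 0.5


class TestFitGLM:
    def test_noiseless_fit_is_exact_for_any_ar_coefficient(self):
        rng = np.random.default_rng(0)
        sched = build_schedule(4, 2, 5, 0.8, 8.0, order_seed=1)
        for rho in (0.0, 0.2, 0.7):
            opts = GLMOptions(ar_coefficient=rho)
            d = build_design_matrix(sched, 1.7, 30, opts)
            beta = rng.normal(size=(len(d.names), 5))
            y = d.matrix @ beta
            fit = fit_glm(y, d, opts)
            got = np.stack([fit.betas[n].ravel() for n in d.names])
            np.testing.assert_allclose(got, beta, atol=1e-9)

    def test_whitened_ols_equals_closed_form_gls(self):
        """Oracle: explicit GLS with the AR(1) covariance on a small fixture."""
        rng = np.random.default_rng(1)
        T, p, rho = 18, 3, 0.2
        X = np.column_stack([np.ones(T), rng.normal(size=(T, p - 1))])
        y = rng.normal(size=(T, 4))
        V = rho ** np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
        Vinv = np.linalg.inv(V)
        oracle = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)

        d = build_design_matrix(_empty_schedule(("faces",)), 1.0, T, drift=False)
        d.matrix = X
        d.names = ["constant"] + [f"r{i}" for i in range(p - 1)]
        fit = fit_glm(y, d, GLMOptions(ar_coefficient=rho))
        got = np.stack([fit.betas[n].ravel() for n in d.names])
        np.testing.assert_allclose(got, oracle, atol=1e-8)

    def test_ar1_noise_betas_empirically_unbiased(self):
        sched = build_schedule(4, 2, 5, 0.8, 8.0, order_seed=1)
        opts = GLMOptions(ar_coefficient=0.2)
        d = build_design_matrix(sched, 1.7, 30, opts)
        beta_true = 2.0
        rng = np.random.default_rng(7)
        n_vox = 200
        y = np.outer(d.matrix[:, 0], np.full(n_vox, beta_true))
        e = rng.standard_normal((30, n_vox))
        for t in range(1, 30):
            e[t] += 0.2 * e[t - 1]
        fit = fit_glm(y + e, d, opts)
        err = fit.betas["faces"].ravel() - beta_true
        ci = 1.96 * err.std(ddof=1) / np.sqrt(n_vox)
        assert abs(err.mean()) < ci + 0.05

    def test_constant_series_loads_on_constant_column(self):
        sched = build_schedule(2, 2, 5, 0.8, 0.0, order_seed=0)
        d = build_design_matrix(sched, 1.7, 20)
        y = np.full((20, 3), 7.0)
        fit = fit_glm(y, d, GLMOptions())
        np.testing.assert_allclose(fit.betas["constant"].ravel(), 7.0, atol=1e-9)
        for c in ("faces", "houses"):
            np.testing.assert_allclose(fit.betas[c].ravel(), 0.0, atol=1e-9)

    def test_rank_deficient_design_names_collinear_columns(self):
        d = build_design_matrix(_empty_schedule(("faces",)), 1.0, 10, drift=False)
        d.matrix = np.column_stack([np.ones(10), np.arange(10.0), np.arange(10.0) * 2])
        d.names = ["constant", "ramp", "ramp_copy"]
        with pytest.raises(ValueError, match="ramp_copy"):
            fit_glm(np.zeros((10, 2)), d, GLMOptions())

    def test_df_is_volumes_minus_rank(self):
        sched = build_schedule(4, 2, 5, 0.8, 8.0, order_seed=1)
        d = build_design_matrix(sched, 1.7, 30)
        fit = fit_glm(np.random.default_rng(0).normal(size=(30, 2)), d, GLMOptions())
        assert fit.df == 30 - d.matrix.shape[1]


class TestContrasts:
    @staticmethod
    def _simple_fit(y, X, names, rho=0.0):
        d = build_design_matrix(_empty_schedule(("faces",)), 1.0, X.shape[0], drift=False)
        d.matrix = X
        d.names = names
        return fit_glm(y, d, GLMOptions(ar_coefficient=rho))

    def test_hand_computed_single_voxel_fixture(self):
        """Scalar-arithmetic oracle on a 4-column orthogonal design."""
        T = 8
        X = np.zeros((T, 4))
        for j in range(4):
            X[2 * j : 2 * j + 2, j] = 1.0
        y = np.array([3.0, 1.0, 1.0, -1.0, 0.5, 0.5, 0.0, 0.0])[:, None]
        fit = self._simple_fit(y, X, ["faces", "houses", "objects", "landscapes"])
        # by hand: betas = per-pair means (2, 0, 0.5, 0); df = 4;
        # RSS = sum of within-pair deviations = 1+1+1+1 = 4 -> s2 = 1
        # c = f - h: c'(X'X)^-1 c = 1/2 + 1/2 = 1 -> t = 2/sqrt(1*1) = 2
        tmap = contrast_tmap(fit, "f>h")
        assert tmap.df == 4
        assert tmap.values.ravel()[0] == pytest.approx(2.0)

    def test_equal_betas_give_zero_t(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.tile([1.0, 0.0], 6), np.tile([0.0, 1.0], 6)])
        y = np.tile([5.0, 5.0], 6)[:, None] + rng.normal(size=(12, 1)) * 0.1
        fit = self._simple_fit(y, X, ["faces", "houses"])
        tmap = contrast_tmap(fit, "f>h")
        # both conditions share the same mean: t is near zero, far below any
        # suprathreshold value
        assert abs(tmap.values.ravel()[0]) < t_critical(fit.df, 0.05)

    def test_scaling_data_leaves_t_unchanged(self):
        sched = build_schedule(4, 2, 5, 0.8, 8.0, order_seed=2)
        opts = GLMOptions()
        d = build_design_matrix(sched, 1.7, 30, opts)
        rng = np.random.default_rng(4)
        y = d.matrix @ rng.normal(size=(len(d.names), 6)) + rng.normal(size=(30, 6))
        t1 = contrast_tmap(fit_glm(y, d, opts), "f>h").values
        t10 = contrast_tmap(fit_glm(10 * y, d, opts), "f>h").values
        np.testing.assert_allclose(t1, t10, rtol=1e-9)

    def test_all_zero_weights_rejected(self):
        fit = self._simple_fit(
            np.zeros((6, 1)), np.ones((6, 1)), ["faces"]
        )
        with pytest.raises(ValueError, match="zero"):
            contrast_tmap(fit, np.zeros(1))

    def test_polarity_reference_is_faces_only_contrast(self):
        T = 10
        rng = np.random.default_rng(5)
        X = np.column_stack([rng.normal(size=T), np.ones(T)])
        y = X @ np.array([[2.0], [1.0]]) + rng.normal(size=(T, 1)) * 0.1
        fit = self._simple_fit(y, X, ["faces", "constant"])
        pol = polarity_reference(fit)
        direct = contrast_tmap(fit, np.array([1.0, 0.0]))
        np.testing.assert_allclose(pol.values, direct.values)


class TestConjunction:
    def _map(self, vals, df=10):
        return StatMap(np.asarray(vals, dtype=float), "t", df, np.eye(4))

    def test_single_map_identity(self):
        m = self._map([[ [1.0, 2.0] ]])
        out = conjunction_min_t([m])
        np.testing.assert_array_equal(out.values, m.values)

    def test_voxelwise_minimum(self):
        maps = [self._map([[[3.0]]]), self._map([[[2.0]]]), self._map([[[5.0]]])]
        assert conjunction_min_t(maps).values.ravel()[0] == 2.0

    def test_never_exceeds_inputs_and_idempotent(self, rng):
        maps = [self._map(rng.normal(size=(4, 4, 3))) for _ in range(3)]
        out = conjunction_min_t(maps)
        for m in maps:
            assert np.all(out.values <= m.values + 1e-12)
        again = conjunction_min_t([out, out])
        np.testing.assert_array_equal(again.values, out.values)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            conjunction_min_t(
                [self._map(np.zeros((2, 2, 2))), self._map(np.zeros((3, 2, 2)))]
            )


class TestSmoothing:
    def test_fwhm_zero_is_identity(self, rng):
        v = rng.normal(size=(8, 8, 6))
        out = smooth_volume(v, SmoothingParams(0.0), np.diag([3, 3, 3, 1.0]))
        np.testing.assert_array_equal(out, v)

    def test_constant_volume_unchanged(self):
        v = np.full((10, 10, 8), 3.5)
        out = smooth_volume(v, SmoothingParams(8.0), np.diag([3, 3, 3, 1.0]))
        np.testing.assert_allclose(out, 3.5, atol=1e-9)

    def test_impulse_matches_sampled_gaussian_kernel(self):
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        v = np.zeros((21, 21, 21))
        v[10, 10, 10] = 1.0
        fwhm = 8.0
        out = smooth_volume(v, SmoothingParams(fwhm), affine)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        sigma_mm = fwhm / (2 * np.sqrt(2 * np.log(2)))
        # direct kernel evaluation at a few offsets (in mm), normalized the
        # same way a discrete separable kernel is
        i = np.arange(-10, 11) * 3.0
        k1 = np.exp(-(i**2) / (2 * sigma_mm**2))
        k1 /= k1.sum()
        for off in [(0, 0, 0), (1, 0, 0), (1, 2, 3)]:
            expected = k1[10 + off[0]] * k1[10 + off[1]] * k1[10 + off[2]]
            got = out[10 + off[0], 10 + off[1], 10 + off[2]]
            assert got == pytest.approx(expected, rel=1e-4, abs=1e-12)

    def test_sheared_affine_rejected(self):
        aff = np.eye(4)
        aff[0, 1] = 0.5
        with pytest.raises(ValueError, match="shear"):
            smooth_volume(np.zeros((4, 4, 4)), SmoothingParams(8.0), aff)


class TestGroupTTest:
    def _map(self, vals):
        return StatMap(np.asarray(vals, dtype=float), "contrast", None, np.eye(4))

    def test_identical_nonzero_maps_give_infinite_t_with_warning(self):
        maps = [self._map(np.ones((2, 2, 2))) for _ in range(5)]
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            out = group_ttest(maps)
        assert np.all(np.isinf(out.values))
        assert any("variance" in str(x.message) for x in w)
        assert out.df == 4

    def test_sign_flip_negates_t(self, rng):
        maps = [self._map(rng.normal(size=(3, 3, 2))) for _ in range(6)]
        flipped = [self._map(-m.values) for m in maps]
        np.testing.assert_allclose(
            group_ttest(maps).values, -group_ttest(flipped).values, atol=1e-12
        )

    def test_null_maps_type_i_rate_matches_alpha(self):
        rng = np.random.default_rng(11)
        n_sub, shape = 12, (12, 12, 8)
        maps = [self._map(rng.normal(size=shape)) for _ in range(n_sub)]
        out = group_ttest(maps)
        thr = t_critical(out.df, 0.05 / 2, two_sided=False)  # |t| two-sided 0.05
        rate = np.mean(np.abs(out.values) > thr)
        n_vox = np.prod(shape)
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_vox)
        assert rate == pytest.approx(0.05, abs=3 * ci)

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValueError):
            group_ttest([self._map(np.zeros((2, 2, 2)))])


class TestROIMeans:
    def test_uniform_beta_recovered_and_disjoint_masks_separate(self):
        sched = build_schedule(2, 2, 5, 0.8, 0.0, order_seed=0)
        opts = GLMOptions()
        d = build_design_matrix(sched, 1.7, 20, opts)
        # 2 voxels: planted betas differ between them
        beta = np.zeros((len(d.names), 2))
        beta[0] = [1.5, -2.0]  # faces
        beta[1] = [0.5, 0.5]  # houses
        y = d.matrix @ beta
        fit = fit_glm(y, d, opts)
        grid = fit.betas["faces"].shape
        m0 = np.zeros(grid, dtype=bool)
        m0.ravel()[0] = True
        m1 = np.zeros(grid, dtype=bool)
        m1.ravel()[1] = True
        assert roi_condition_means(fit, m0)["faces"] == pytest.approx(1.5)
        assert roi_condition_means(fit, m1)["faces"] == pytest.approx(-2.0)
        with pytest.raises(ValueError, match="empty"):
            roi_condition_means(fit, np.zeros(grid, dtype=bool))

    def test_planted_task_positive_roi_prefers_faces(self, tiny_atlas):
        tpl = make_subject_template(tiny_atlas, subject_seed=8)
        sched = build_schedule(4, 2, 5, 0.8, 8.0, order_seed=2)
        sess = simulate_session(
            tpl, sched, Acquisition(1.7, 30, 0), NoiseParams(0.2, 0.5, 0.0), 3
        )
        opts = GLMOptions()
        d = build_design_matrix(sched, 1.7, 30, opts)
        fit = fit_glm(sess.series.astype(float), d, opts)
        means = roi_condition_means(fit, tiny_atlas.mask(["FFA_L", "FFA_R"]))
        assert all(means["faces"] > means[c] for c in ("houses", "objects", "landscapes"))


@given(scale=st.floats(0.1, 50.0))
def test_t_map_invariant_to_positive_scaling(scale):
    sched = build_schedule(2, 2, 5, 0.8, 0.0, order_seed=9)
    opts = GLMOptions()
    d = build_design_matrix(sched, 1.7, 20, opts)
    rng = np.random.default_rng(99)
    y = d.matrix @ rng.normal(size=(len(d.names), 3)) + rng.normal(size=(20, 3))
    base = contrast_tmap(fit_glm(y, d, opts), "f>h").values
    scaled = contrast_tmap(fit_glm(scale * y, d, opts), "f>h").values
    np.testing.assert_allclose(base, scaled, rtol=1e-8, atol=1e-10)
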