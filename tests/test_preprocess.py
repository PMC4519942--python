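"""Temporal preprocessing: discard, regression, detrend, filter, motion."""

import numpy as np
import pytest

from restmap.bold import BoldSeries, MotionTrace
from restmap.preprocess import (
    BandSpec,
    NuisanceSet,
    apply_motion_exclusion,
    bandpass_ideal,
    build_nuisance_set,
    discard_initial,
    fwhm_to_sigma,
    gaussian_smooth,
    linear_detrend,
    regress_nuisance,
    run_preprocessing,
    summarize_motion,
)
from restmap.synthetic import EffectSpec, generate_subject_series


def make_series(mask, data, tr=2.0):
    return BoldSeries(data, tr_seconds=tr, mask=mask)


@pytest.fixture
def noise_series(box_mask):
    rng = np.random.default_rng(0)
    return make_series(box_mask, rng.standard_normal((60, box_mask.n_voxels)))


class TestDiscardInitial:
    def test_drops_first_volumes(self, box_mask):
        rng = np.random.default_rng(1)
        s = make_series(box_mask, rng.standard_normal((200, box_mask.n_voxels)))
        out = discard_initial(s, 5)
        assert out.n_volumes == 195
        np.testing.assert_array_equal(out.data, s.data[5:])

    def test_zero_is_identity(self, noise_series):
        np.testing.assert_array_equal(
            discard_initial(noise_series, 0).data, noise_series.data
        )

    def test_discarding_everything_rejected(self, noise_series):
        with pytest.raises(ValueError):
            discard_initial(noise_series, noise_series.n_volumes)


class TestRegressNuisance:
    def _nuisance(self, cols, names):
        return NuisanceSet(np.column_stack(cols), names)

    def test_series_equal_to_regressor_gives_zero_residual(self, box_mask):
        rng = np.random.default_rng(2)
        g = rng.standard_normal(60)
        data = np.tile(g[:, None], (1, box_mask.n_voxels))
        s = make_series(box_mask, data)
        out = regress_nuisance(s, self._nuisance([g], ["global"]))
        assert np.abs(out.data).max() < 1e-10

    def test_residuals_orthogonal_to_all_regressors(self, noise_series):
        rng = np.random.default_rng(3)
        cols = [rng.standard_normal(60) for _ in range(4)]
        nuis = self._nuisance(cols, ["a", "b", "c", "d"])
        out = regress_nuisance(noise_series, nuis)
        for col in cols:
            dots = np.abs(out.data.T @ col)
            limit = 1e-8 * np.linalg.norm(col) * np.linalg.norm(out.data, axis=0)
            assert (dots <= np.maximum(limit, 1e-9)).all()

    def test_matches_hand_computed_projection(self, mask3):
        # 5 timepoints, intercept + 2 regressors: residual = y - X(X'X)^-1 X'y
        y = np.array([[1.0], [3.0], [2.0], [5.0], [4.0]])
        y = np.tile(y, (1, 3))
        r1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r2 = np.array([1.0, -1.0, 1.0, -1.0, 1.0])
        X = np.column_stack([np.ones(5), r1, r2])
        beta = np.linalg.solve(X.T @ X, X.T @ y[:, :1])
        expected = y[:, :1] - X @ beta
        s = make_series(mask3, y)
        out = regress_nuisance(s, self._nuisance([r1, r2], ["r1", "r2"]))
        np.testing.assert_allclose(out.data, np.tile(expected, (1, 3)), atol=1e-10)

    def test_collinear_regressor_pruned_with_warning(self, noise_series):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(60)
        nuis = self._nuisance([a, 2 * a], ["a", "a2"])
        with pytest.warns(UserWarning, match="collinear"):
            out = regress_nuisance(noise_series, nuis)
        assert np.isfinite(out.data).all()

    def test_constant_zero_column_rejected(self):
        with pytest.raises(ValueError, match="constant-zero"):
            NuisanceSet(np.zeros((10, 1)), ["dead"])


class TestLinearDetrend:
    def test_pure_ramp_removed(self, box_mask):
        t = np.arange(50, dtype=float)
        data = np.outer(2.0 + 0.3 * t, np.ones(box_mask.n_voxels))
        out = linear_detrend(make_series(box_mask, data))
        assert np.abs(out.data).max() < 1e-10

    def test_noise_recentred_and_slope_free(self, noise_series):
        out = linear_detrend(noise_series)
        t = np.arange(out.n_volumes, dtype=float)
        tc = t - t.mean()
        assert np.abs(out.data.mean(axis=0)).max() < 1e-12
        slopes = (tc @ out.data) / (tc @ tc)
        assert np.abs(slopes).max() < 1e-12

    def test_sinusoid_on_ramp_recovered_analytically(self, mask3):
        # detrend is a linear projection: the output must equal the sinusoid
        # minus its own closed-form projection onto {1, t}
        n = 100
        t = np.arange(n, dtype=float)
        sin = np.sin(2 * np.pi * 4 * t / n)
        ramp = 1.5 - 0.2 * t
        tc = t - t.mean()
        proj = sin.mean() + tc * ((tc @ sin) / (tc @ tc))
        expected = sin - proj
        data = np.tile((ramp + sin)[:, None], (1, 3))
        out = linear_detrend(make_series(mask3, data))
        assert np.sqrt(np.mean((out.data[:, 0] - expected) ** 2)) < 1e-8


class TestBandpassIdeal:
    def test_in_band_sinusoid_preserved(self, mask3):
        n, tr = 195, 2.0
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * 0.04 * t)
        s = make_series(mask3, np.tile(x[:, None], (1, 3)), tr=tr)
        out = bandpass_ideal(s, BandSpec(0.01, 0.08))
        in_rms = np.sqrt(np.mean(x**2))
        out_rms = np.sqrt(np.mean(out.data[:, 0] ** 2))
        assert abs(out_rms - in_rms) / in_rms < 0.02

    def test_out_of_band_sinusoid_suppressed(self, mask3):
        n, tr = 195, 2.0
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * 0.2 * t)
        s = make_series(mask3, np.tile(x[:, None], (1, 3)), tr=tr)
        out = bandpass_ideal(s, BandSpec(0.01, 0.08))
        assert np.sqrt(np.mean(out.data[:, 0] ** 2)) < 0.05 * np.sqrt(np.mean(x**2))

    def test_idempotent(self, noise_series):
        band = BandSpec(0.01, 0.08)
        once = bandpass_ideal(noise_series, band)
        twice = bandpass_ideal(once, band)
        assert np.abs(twice.data - once.data).max() < 1e-10

    @pytest.mark.parametrize("low,high", [(0.0, 0.08), (0.08, 0.01), (0.01, 0.3)])
    def test_invalid_band_rejected(self, noise_series, low, high):
        with pytest.raises(ValueError):
            bandpass_ideal(noise_series, BandSpec(low, high))


class TestMotion:
    @pytest.mark.parametrize(
        "trans,expected",
        [
            (np.tile([0.1, 0.0, 0.0], (10, 1)), 0.1),
            (np.zeros((10, 3)), 0.0),
            (np.array([[0.3, 0, 0], [-0.3, 0, 0]] * 5), 0.3),
        ],
    )
    def test_summarize_translation_norms(self, trans, expected):
        trace = MotionTrace(trans, np.zeros_like(trans))
        mt, mr = summarize_motion(trace)
        assert mt == pytest.approx(expected)
        assert mr == 0.0

    def test_exclusion_boundary(self, small_cohort_table):
        cohort, traces = small_cohort_table
        kept, excluded = apply_motion_exclusion(cohort, traces)
        assert list(excluded["subject_id"]) == ["s3"]

    def test_exactly_at_limit_is_kept(self):
        import pandas as pd

        cohort = pd.DataFrame({"subject_id": ["a"]})
        tr = np.zeros((5, 3))
        tr[2, 0] = 1.5  # strictly greater than 1.5 is required for exclusion
        kept, excluded = apply_motion_exclusion(
            cohort, {"a": MotionTrace(tr, np.zeros_like(tr))}
        )
        assert len(kept) == 1 and len(excluded) == 0

    def test_missing_trace_raises(self):
        import pandas as pd

        cohort = pd.DataFrame({"subject_id": ["a", "b"]})
        with pytest.raises(KeyError):
            apply_motion_exclusion(
                cohort, {"a": MotionTrace(np.zeros((5, 3)), np.zeros((5, 3)))}
            )


@pytest.fixture
def small_cohort_table():
    import pandas as pd

    cohort = pd.DataFrame({"subject_id": ["s1", "s2", "s3"]})
    zeros = np.zeros((5, 3))
    spike = zeros.copy()
    spike[1, 1] = 1.6
    traces = {
        "s1": MotionTrace(zeros, zeros),
        "s2": MotionTrace(zeros + 0.2, zeros),
        "s3": MotionTrace(spike, zeros),
    }
    return cohort, traces


class TestGaussianSmooth:
    def test_fwhm_to_sigma_closed_form(self):
        assert fwhm_to_sigma(6.0) == pytest.approx(2.548, abs=1e-3)

    def test_delta_mass_conserved_unmasked(self):
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        out = gaussian_smooth(vol, 6.0, voxel_size_mm=3.0)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_zero_fwhm_identity(self, small_mask):
        rng = np.random.default_rng(5)
        v = rng.standard_normal(small_mask.n_voxels)
        np.testing.assert_array_equal(gaussian_smooth(v, 0.0, mask=small_mask), v)

    def test_negative_fwhm_rejected(self, small_mask):
        with pytest.raises(ValueError):
            gaussian_smooth(np.zeros(small_mask.n_voxels), -1.0, mask=small_mask)

    def test_masked_smoothing_remasks_edges(self, small_mask):
        v = np.ones(small_mask.n_voxels)
        out = gaussian_smooth(v, 6.0, mask=small_mask)
        assert out.shape == (small_mask.n_voxels,)
        assert out.max() <= 1.0 + 1e-9  # convolution against outside zeros


class TestFullPipeline:
    def test_output_band_limited_and_orthogonal(self, small_mask):
        from restmap.masks import default_tissue_masks
        from restmap.synthetic import generate_motion_trace

        spec = EffectSpec()
        s = generate_subject_series(small_mask, spec, 2.0, 120, seed=8)
        trace = generate_motion_trace(120, False, seed=8)
        wm, csf = default_tissue_masks(small_mask)
        out = run_preprocessing(s, trace, wm, csf, n_discard=5)
        assert out.n_volumes == 115
        band = BandSpec(0.01, 0.08)
        again = bandpass_ideal(out, band)
        assert np.abs(again.data - out.data).max() < 1e-9


class TestMotionSummaryProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        data=st.lists(
            st.lists(
                st.floats(min_value=-2.0, max_value=2.0, allow_nan=False),
                min_size=6, max_size=6,
            ),
            min_size=1, max_size=40,
        ),
        scale=st.floats(min_value=0.1, max_value=5.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_sign_invariance_and_scale_equivariance(self, data, scale):
        m = np.asarray(data)
        trace = MotionTrace(m[:, :3], m[:, 3:])
        mt, mr = summarize_motion(trace)
        flipped = MotionTrace(-m[:, :3], -m[:, 3:])
        assert summarize_motion(flipped) == pytest.approx((mt, mr))
        scaled = MotionTrace(scale * m[:, :3], scale * m[:, 3:])
        st, sr = summarize_motion(scaled)
        assert (st, sr) == pytest.approx((scale * mt, scale * mr), rel=1e-9)
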