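"""Exponential regression core: downsampling, fitting, F-filter, mechanics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lungtau.breath_timing import build_phase_grid
from lungtau.expfit import (
    block_downsample,
    dynamic_elastance,
    exp_model,
    f_significance,
    fit_all_voxels,
    fit_exponential,
    fit_series_stack,
    fit_volume_time_constant,
)
from lungtau.io import AlignedSequence, InputError, VentilatorTrace
from lungtau.phantom import PhantomSpec, render_ventilator_trace

TIMES = np.arange(15) / 7.0  # 21-phase sequence at 20 / min


class TestBlockDownsample:
    def _seq(self, inten, mask=None):
        if mask is None:
            mask = np.ones(inten.shape[:3], bool)
        return AlignedSequence(inten, mask, np.full(3, 0.6))

    def test_constant_block_unchanged(self):
        seq = self._seq(np.full((4, 4, 4, 2), -400.0))
        ds = block_downsample(seq, 2)
        assert ds.grid_shape == (2, 2, 2)
        np.testing.assert_allclose(ds.intensity, -400.0)
        np.testing.assert_allclose(ds.spacing_mm, 1.2)

    def test_block_mean_value(self):
        inten = np.empty((2, 2, 2, 1))
        inten[0] = -400.0  # four voxels
        inten[1] = -200.0  # four voxels
        ds = block_downsample(self._seq(inten), 2)
        assert ds.intensity[0, 0, 0, 0] == pytest.approx(-300.0)

    def test_factor_one_identity(self, small_seq):
        assert block_downsample(small_seq, 1) is small_seq

    def test_mask_majority_vote(self):
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = True  # 1/8 children in mask -> out
        seq = self._seq(np.zeros((2, 2, 2, 1)), mask)
        ds = np.zeros(0)
        with pytest.raises(InputError):
            # a downsampled mask with no lung voxels is rejected on construction
            block_downsample(seq, 2)
        mask[:, :, 0] = True  # 4/8 children -> in (>= half)
        ds = block_downsample(self._seq(np.zeros((2, 2, 2, 1)), mask), 2)
        assert ds.mask[0, 0, 0]

    def test_factor_exceeding_grid_rejected(self, small_seq):
        with pytest.raises(ValueError, match="factor"):
            block_downsample(small_seq, 100)


class TestFitExponential:
    def test_noiseless_roundtrip(self):
        y = exp_model(TIMES, -400.0, -250.0, 0.4)
        fit = fit_exponential(TIMES, y)
        assert fit.d0 == pytest.approx(-400.0, rel=1e-6)
        assert fit.dinf == pytest.approx(-250.0, rel=1e-6)
        assert fit.tau_s == pytest.approx(0.4, rel=1e-6)
        assert fit.significant

    def test_fit_at_t0_is_d0(self):
        y = exp_model(TIMES, -620.0, -410.0, 0.9)
        fit = fit_exponential(TIMES, y)
        assert exp_model(0.0, fit.d0, fit.dinf, fit.tau_s) == pytest.approx(fit.d0)
        assert fit.d0 == pytest.approx(-620.0, abs=1e-4)

    def test_constant_series(self):
        fit = fit_exponential(TIMES, np.full(15, -512.0))
        assert fit.d0 == pytest.approx(-512.0)
        assert fit.dinf == pytest.approx(-512.0)
        assert not fit.significant

    def test_paradoxical_amplitude(self):
        y = exp_model(TIMES, -250.0, -400.0, 0.5)  # density falls
        fit = fit_exponential(TIMES, y)
        assert fit.dinf < fit.d0
        assert fit.tau_s == pytest.approx(0.5, rel=1e-5)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential(np.array([0.0, 0.1, 0.2]), np.array([1.0, 2.0, 3.0]))

    def test_times_must_start_at_zero(self):
        with pytest.raises(ValueError):
            fit_exponential(TIMES + 1.0, np.zeros(15))

    @given(
        d0=st.floats(-1000, 0),
        amp=st.floats(-300, 300),
        tau=st.floats(0.05, 3.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_prediction_and_dee_bracketing(self, d0, amp, tau):
        """The fitted curve is monotone; D_EE always lies between D0 and Dinf."""
        fit = fit_exponential(TIMES, exp_model(TIMES, d0, d0 + amp, tau), t_exp_s=2.0)
        pred = exp_model(np.linspace(0, 2, 50), fit.d0, fit.dinf, fit.tau_s) \
            if np.isfinite(fit.tau_s) else np.full(50, fit.d0)
        diffs = np.diff(pred)
        assert np.all(diffs >= -1e-8) or np.all(diffs <= 1e-8)
        lo, hi = sorted((fit.d0, fit.dinf))
        assert lo - 1e-6 <= fit.d_ee <= hi + 1e-6

    def test_nonequilibrated_change_vanishes_at_long_exhalation(self):
        y = exp_model(TIMES, -400.0, -250.0, 0.2)
        fit = fit_exponential(TIMES, y, t_exp_s=2.0)  # t_exp = 10 tau
        assert abs(fit.nonequilibrated_change) <= 1e-2
        fit5 = fit_exponential(TIMES, exp_model(TIMES, -400, -250, 0.4), t_exp_s=2.0)
        assert abs(fit5.nonequilibrated_change) <= 0.007 * 150 + 1e-6


class TestFSignificance:
    def test_no_improvement_means_excluded(self):
        f, p = f_significance(100.0, 100.0, 15)
        assert f == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_example_f54(self):
        f, p = f_significance(100.0, 10.0, 15)
        assert f == pytest.approx(54.0)
        # closed form for F(2, 12): sf = (1 + F/6)^-6 = 1e-6 at F = 54
        assert p == pytest.approx(1e-6, rel=1e-9)

    def test_perfect_fit_is_significant(self):
        f, p = f_significance(50.0, 0.0, 15)
        assert p == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            f_significance(10.0, 5.0, 3)

    def test_null_rejection_rate_is_conservative(self, rng):
        """Pure-noise voxels: the filter never exceeds its nominal 5% level.

        With tau unidentified under the null the F(2, n-3) reference is
        conservative, so the observed type-I error sits below 0.05 (but the
        filter still rejects at a nontrivial rate).
        """
        Y = rng.normal(0.0, 15.0, size=(6000, 15))
        res = fit_series_stack(TIMES, Y)
        _, p = f_significance(res["sse_mean"], res["sse_model"], 15)
        rate = (p <= 0.05).mean()
        assert 0.02 <= rate <= 0.056


class TestFitAllVoxels:
    def test_all_constant_phantom_fully_excluded(self):
        inten = np.full((6, 6, 6, 13), -500.0)
        seq = AlignedSequence(inten, np.ones((6, 6, 6), bool), np.ones(3))
        grid = build_phase_grid(13, 24)
        fits = fit_all_voxels(seq, grid)
        assert fits.summary["excluded_fraction"] == 1.0

    def test_noiseless_phantom_recovery(
        self, small_noiseless_seq, small_grid, small_truth
    ):
        fits = fit_all_voxels(small_noiseless_seq, small_grid)
        m = small_truth.mask & (np.abs(small_truth.amplitude_map) >= 5)
        assert fits.significant[m].all()
        err = np.abs(fits.tau_s[m] - small_truth.tau_map[m])
        assert np.nanmax(err) <= 1e-4

    def test_excluded_voxels_are_low_amplitude(self, small_seq, small_grid, small_truth):
        fits = fit_all_voxels(small_seq, small_grid)
        excl = small_truth.mask & ~fits.significant
        if excl.any():
            # excluded voxels concentrate where the true intratidal change is tiny
            med_excl = np.median(np.abs(small_truth.amplitude_map[excl]))
            med_all = np.median(np.abs(small_truth.amplitude_map[small_truth.mask]))
            assert med_excl < med_all


class TestGlobalMechanics:
    def test_volume_time_constant_roundtrip(self, small_truth):
        spec = PhantomSpec(volume_tau_s=0.3)
        tr = render_ventilator_trace(small_truth, spec)
        mech = fit_volume_time_constant(tr)
        assert mech.tau_volume_s == pytest.approx(0.300, abs=1e-4)
        assert mech.driving_pressure_cmh2o == pytest.approx(20.8 - 8.1, abs=1e-6)

    def test_flat_volume_trace_rejected(self):
        t = np.arange(600) / 200.0
        p = np.where(np.mod(t, 3.0) < 2.0, 8.0, 21.0)
        tr = VentilatorTrace(t, p, np.zeros_like(t))
        with pytest.raises(InputError, match="flat|expiration"):
            fit_volume_time_constant(tr)

    def test_flat_pressure_has_no_window(self):
        t = np.arange(600) / 200.0
        tr = VentilatorTrace(t, np.full_like(t, 10.0), np.abs(np.sin(t)))
        with pytest.raises(InputError, match="window"):
            fit_volume_time_constant(tr)

    @pytest.mark.parametrize(
        "dp,vt,expected", [(12.0, 0.1, 120.0), (0.0, 0.5, 0.0), (12.7, 0.0888, 143.018)]
    )
    def test_dynamic_elastance(self, dp, vt, expected):
        assert dynamic_elastance(dp, vt) == pytest.approx(expected, abs=0.001)

    def test_elastance_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError):
            dynamic_elastance(12.0, 0.0)
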