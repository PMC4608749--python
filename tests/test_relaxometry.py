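import numpy as np
import pytest
from hypothesis import given, strategies as st

from qcart.protocols import build_time_axis
from qcart.relaxometry import (
    FitOptions,
    ImageSeries,
    SeriesError,
    fit_ir_t1,
    fit_monoexp,
    fit_series,
    make_mask,
    two_point_exact,
)

from oracles import grid_search_ir_magnitude, grid_search_monoexp


def monoexp_series(times, amps, ts, protocol=None):
    """Series whose pixels are noiseless mono-exponentials (1 x n image)."""
    times = np.asarray(times, float)
    amps = np.atleast_1d(np.asarray(amps, float))
    ts = np.atleast_1d(np.asarray(ts, float))
    frames = amps[None, None, :] * np.exp(-times[:, None, None] / ts[None, None, :])
    return ImageSeries(frames=frames, times_ms=times, protocol=protocol)


def ir_series(times, amps, t1s, protocol=None):
    times = np.asarray(times, float)
    amps = np.atleast_1d(np.asarray(amps, float))
    t1s = np.atleast_1d(np.asarray(t1s, float))
    frames = np.abs(amps[None, None, :] * (1 - 2 * np.exp(-times[:, None, None] / t1s[None, None, :])))
    return ImageSeries(frames=frames, times_ms=times, protocol=protocol)


class TestTwoPointExact:
    def test_definition_of_e(self):
        assert two_point_exact(100.0, 100.0 / np.e, 0.0, 100.0) == pytest.approx(100.0)

    def test_half_life(self):
        assert two_point_exact(200.0, 100.0, 0.0, 69.3147) == pytest.approx(100.0, rel=1e-5)

    @given(
        t=st.floats(5.0, 500.0),
        a=st.floats(1.0, 1e4),
        t1=st.floats(0.0, 50.0),
        dt=st.floats(1.0, 200.0),
    )
    def test_recovers_generating_decay_time(self, t, a, t1, dt):
        s1 = a * np.exp(-t1 / t)
        s2 = a * np.exp(-(t1 + dt) / t)
        assert two_point_exact(s1, s2, t1, t1 + dt) == pytest.approx(t, rel=1e-9)

    def test_rejects_non_decaying_input(self):
        with pytest.raises(ValueError):
            two_point_exact(50.0, 100.0, 0.0, 10.0)
        with pytest.raises(ValueError):
            two_point_exact(100.0, 50.0, 10.0, 10.0)


class TestNoiselessExactness:
    """Data generated by the model at the protocol's own time points must be
    recovered to 1e-6 relative, for every preparation."""

    @pytest.mark.parametrize("name", ["T2", "T1RHO", "AD_T1RHO", "RAFF"])
    def test_monoexp_preparations(self, protocols, name, rng):
        times = build_time_axis(protocols[name])
        ts = rng.uniform(0.3 * times.max(), 2.0 * times.max(), size=12)
        amps = rng.uniform(200.0, 2000.0, size=12)
        pm = fit_monoexp(monoexp_series(times, amps, ts, protocols[name]))
        assert pm.valid.all()
        np.testing.assert_allclose(pm.tmap[0], ts, rtol=1e-6)
        np.testing.assert_allclose(pm.amplitude[0], amps, rtol=1e-6)

    def test_inversion_recovery(self, protocols, rng):
        times = build_time_axis(protocols["T1"])
        t1s = rng.uniform(500.0, 2500.0, size=12)
        amps = rng.uniform(200.0, 2000.0, size=12)
        pm = fit_ir_t1(ir_series(times, amps, t1s, protocols["T1"]))
        assert pm.valid.all()
        np.testing.assert_allclose(pm.tmap[0], t1s, rtol=1e-6)

    def test_polarity_modes_agree_on_noiseless_data(self, protocols):
        times = build_time_axis(protocols["T1"])
        series = ir_series(times, [1000.0], [1200.0], protocols["T1"])
        default = fit_ir_t1(series)
        signed = fit_ir_t1(series, FitOptions(restore_polarity=True))
        assert default.tmap[0, 0] == pytest.approx(1200.0, rel=1e-6)
        assert signed.tmap[0, 0] == pytest.approx(1200.0, rel=1e-6)

    def test_fixed_t1rho_example(self, protocols):
        # value scale of week-3 viable spin-lock T1rho
        pm = fit_monoexp(monoexp_series([0, 10, 20, 40, 80], [500.0], [90.8]))
        assert pm.tmap[0, 0] == pytest.approx(90.8, rel=1e-6)


def test_signal_null_falls_at_t1_ln2(protocols):
    """|S| of an inversion recovery is smallest at the TI nearest T1*ln2."""
    times = build_time_axis(protocols["T1"])
    series = ir_series(times, [1000.0], [1000.0], protocols["T1"])
    i_null = int(np.argmin(series.frames[:, 0, 0]))
    expected = int(np.argmin(np.abs(times - 1000.0 * np.log(2))))
    assert i_null == expected  # TI = 640 ms for the published TI ladder


class TestOracleEquivalence:
    def test_monoexp_matches_grid_search(self, rng):
        times = np.array([0.0, 10.0, 20.0, 40.0, 80.0])
        grid = np.arange(10.0, 400.0, 0.05)
        ts = rng.uniform(30.0, 250.0, size=10)
        amps = rng.uniform(300.0, 1500.0, size=10)
        pm = fit_monoexp(monoexp_series(times, amps, ts))
        for k in range(ts.size):
            _, t_grid = grid_search_monoexp(times, amps[k] * np.exp(-times / ts[k]), grid)
            assert abs(pm.tmap[0, k] - t_grid) <= 0.05

    def test_ir_matches_grid_search(self, protocols, rng):
        times = build_time_axis(protocols["T1"])
        grid = np.arange(300.0, 3000.0, 0.5)
        t1s = rng.uniform(600.0, 2400.0, size=10)
        amps = rng.uniform(300.0, 1500.0, size=10)
        pm = fit_ir_t1(ir_series(times, amps, t1s, protocols["T1"]))
        for k in range(t1s.size):
            y = np.abs(amps[k] * (1 - 2 * np.exp(-times / t1s[k])))
            _, t_grid = grid_search_ir_magnitude(times, y, grid)
            assert abs(pm.tmap[0, k] - t_grid) <= 0.5


class TestInvariants:
    def test_scale_equivariance(self, rng):
        times = np.array([0.0, 10.0, 20.0, 40.0, 80.0])
        ts = rng.uniform(40.0, 200.0, size=8)
        amps = rng.uniform(300.0, 1500.0, size=8)
        base = monoexp_series(times, amps, ts)
        scaled = ImageSeries(frames=7.3 * base.frames, times_ms=times)
        pm1, pm2 = fit_monoexp(base), fit_monoexp(scaled)
        np.testing.assert_allclose(pm2.tmap, pm1.tmap, rtol=1e-6)
        np.testing.assert_allclose(pm2.amplitude, 7.3 * pm1.amplitude, rtol=1e-6)

    def test_time_unit_consistency(self, rng):
        times_ms = np.array([0.0, 10.0, 20.0, 40.0, 80.0])
        ts = rng.uniform(40.0, 200.0, size=8)
        amps = rng.uniform(300.0, 1500.0, size=8)
        pm_ms = fit_monoexp(monoexp_series(times_ms, amps, ts))
        pm_s = fit_monoexp(monoexp_series(times_ms / 1000.0, amps, ts / 1000.0))
        np.testing.assert_allclose(pm_s.tmap, pm_ms.tmap / 1000.0, rtol=1e-6)

    def test_error_degrades_monotonically_with_noise(self):
        times = np.array([0.0, 10.0, 20.0, 40.0, 80.0])
        rng = np.random.default_rng(7)
        ts = rng.uniform(60.0, 200.0, size=200)
        amp = 1000.0
        clean = amp * np.exp(-times[:, None, None] / ts[None, None, :])
        errors = []
        for sigma in (0.0, amp / 100, amp / 50, amp / 20):
            noisy = np.hypot(clean + rng.normal(0, max(sigma, 1e-12), clean.shape),
                             rng.normal(0, max(sigma, 1e-12), clean.shape))
            pm = fit_monoexp(ImageSeries(frames=noisy, times_ms=times))
            err = np.abs(pm.tmap[0] - ts)[pm.valid[0]]
            errors.append(err.mean())
        assert all(a <= b + 1e-9 for a, b in zip(errors, errors[1:]))

    def test_map_contracts_hold_under_noise(self, week5_phantom, protocols):
        from qcart.synthetic import simulate_series

        series = simulate_series(week5_phantom, protocols["T1RHO"], noise_sigma=20.0, seed=5)
        pm = fit_series(series, mask=week5_phantom.labels > 0)
        assert np.all(pm.tmap[pm.valid] > 0)
        assert np.all(pm.r2_fit[pm.valid] <= 1.0 + 1e-12)
        assert np.all(np.isnan(pm.tmap[~pm.valid]))
        assert not pm.valid[week5_phantom.labels == 0].any()


class TestDegenerateInputs:
    def test_all_zero_pixel_is_invalid_not_an_exception(self):
        times = np.array([0.0, 10.0, 20.0, 40.0])
        frames = np.zeros((4, 1, 2))
        frames[:, 0, 1] = 500 * np.exp(-times / 50.0)
        pm = fit_monoexp(ImageSeries(frames=frames, times_ms=times))
        assert not pm.valid[0, 0] and np.isnan(pm.tmap[0, 0])
        assert pm.valid[0, 1]

    def test_constant_signal_lands_on_bound_and_is_invalid(self):
        times = np.array([0.0, 10.0, 20.0, 40.0])
        frames = np.full((4, 1, 1), 100.0)
        pm = fit_monoexp(ImageSeries(frames=frames, times_ms=times))
        assert not pm.valid[0, 0]

    def test_too_few_time_points_raise(self):
        with pytest.raises(SeriesError):
            fit_monoexp(monoexp_series([0.0, 10.0], [100.0], [50.0]))

    def test_model_protocol_mismatch_raises(self, protocols):
        times = build_time_axis(protocols["T2"])
        series = monoexp_series(times, [100.0], [50.0], protocols["T2"])
        with pytest.raises(SeriesError):
            fit_ir_t1(series)


class TestMakeMask:
    def test_all_zero_image_gives_empty_mask(self):
        series = ImageSeries(frames=np.zeros((3, 8, 8)), times_ms=[0.0, 1.0, 2.0])
        with pytest.warns(UserWarning):
            assert not make_mask(series).any()

    def test_separable_intensities_recover_support(self, week5_phantom, protocols):
        from qcart.synthetic import simulate_series

        series = simulate_series(week5_phantom, protocols["T1RHO"], noise_sigma=0.0)
        mask = make_mask(series, rel_threshold=0.1)
        np.testing.assert_array_equal(mask, week5_phantom.labels > 0)

    def test_mask_area_stable_under_rician_noise(self, week5_phantom, protocols):
        from qcart.synthetic import simulate_series

        series = simulate_series(week5_phantom, protocols["T1RHO"], noise_sigma=2.0, seed=11)
        mask = make_mask(series, rel_threshold=0.1)
        support = int((week5_phantom.labels > 0).sum())
        assert abs(int(mask.sum()) - support) <= 0.02 * support

    def test_threshold_must_be_a_fraction(self, week5_phantom, protocols):
        from qcart.synthetic import simulate_series

        series = simulate_series(week5_phantom, protocols["T1RHO"])
        with pytest.raises(ValueError):
            make_mask(series, rel_threshold=1.5)
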