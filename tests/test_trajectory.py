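"""Gap traces, replicate averaging, ACF, equalization, half period, spectra."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from holehop.constants import THZ_TO_WAVENUMBER
from holehop.errors import (
    AlignmentError,
    DegenerateInputError,
    InvalidParameterError,
    MissingChannelError,
)
from holehop.synthetic import ou_process
from holehop.trajectory import (
    ACFResult,
    SiteEnergyTrace,
    Trace,
    acf_half_period,
    autocorrelation,
    equalization_time,
    fourier_spectrum,
    gap_trace,
    replicate_average,
)


def _site_trace(times, donor, acceptor, replicate=None):
    return SiteEnergyTrace(
        times=times, e_donor=np.asarray(donor, float),
        e_acceptor=np.asarray(acceptor, float), replicate=replicate,
    )


TIMES = np.arange(0.0, 100.0, 0.5)


class TestGapTrace:
    def test_equal_channels_give_zero_gap(self):
        v = np.sin(TIMES)
        assert np.all(gap_trace(_site_trace(TIMES, v, v)).values == 0.0)

    def test_constant_levels(self):
        # donor 2 eV below acceptor: hole injected on the donor, gap -2 eV
        gap = gap_trace(_site_trace(TIMES, np.full_like(TIMES, -7.0),
                                    np.full_like(TIMES, -5.0)))
        assert np.all(gap.values == -2.0)

    def test_linearity_under_scaling(self):
        d, a = np.cos(TIMES), np.sin(TIMES)
        doubled = gap_trace(_site_trace(TIMES, 2 * d, 2 * a))
        assert np.allclose(doubled.values,
                           2 * gap_trace(_site_trace(TIMES, d, a)).values)

    def test_single_channel_input_rejected(self):
        with pytest.raises(MissingChannelError):
            gap_trace(Trace(times=TIMES, values=np.cos(TIMES)))


class TestReplicateAverage:
    def test_plus_minus_one(self):
        plus = _site_trace(TIMES, np.ones_like(TIMES), np.zeros_like(TIMES), 0)
        minus = _site_trace(TIMES, -np.ones_like(TIMES), np.zeros_like(TIMES), 1)
        avg = replicate_average([plus, minus])
        assert np.allclose(avg.e_donor, 0.0)
        assert np.allclose(avg.sem_donor, 1.0)  # sd([-1, 1]) / sqrt(2) = 1

    def test_single_replicate_identity_without_sem(self):
        t = _site_trace(TIMES, np.cos(TIMES), np.sin(TIMES))
        avg = replicate_average([t])
        assert np.array_equal(avg.e_donor, t.e_donor)
        assert avg.sem_donor is None

    def test_mismatched_grids_rejected(self):
        a = _site_trace(TIMES, np.cos(TIMES), np.sin(TIMES))
        b = _site_trace(TIMES + 0.25, np.cos(TIMES), np.sin(TIMES))
        with pytest.raises(AlignmentError):
            replicate_average([a, b])

    def test_ou_replicates_recover_zero_mean(self):
        """Replicate mean within 3 true SEM nearly everywhere (<1% of points)."""
        n, sigma = 4000, 0.15
        reps = [
            Trace(times=np.arange(n) * 0.5,
                  values=ou_process(n, 0.5, sigma, 10.0, seed=100 + i))
            for i in range(3)
        ]
        avg = replicate_average(reps)
        sem_true = sigma / np.sqrt(3)
        assert np.mean(np.abs(avg.values) > 3 * sem_true) < 0.01

    def test_commutes_with_gap(self):
        rng = np.random.default_rng(5)
        reps = [
            _site_trace(TIMES, rng.normal(size=TIMES.size),
                        rng.normal(size=TIMES.size), i)
            for i in range(3)
        ]
        a = gap_trace(replicate_average(reps))
        b = replicate_average([gap_trace(t) for t in reps])
        assert np.allclose(a.values, b.values, atol=1e-12)


def _brute_acf(values, n_lags):
    d = values - values.mean()
    denom = np.sum(d * d)
    return np.array(
        [np.sum(d[: len(d) - l] * d[l:]) for l in range(n_lags + 1)]
    ) / denom


class TestAutocorrelation:
    def test_lag_zero_is_exactly_one(self, rng):
        tr = Trace(times=TIMES, values=rng.normal(size=TIMES.size))
        assert autocorrelation(tr).acf[0] == 1.0

    def test_matches_bruteforce_on_white_noise(self, rng):
        values = rng.normal(size=1000)
        tr = Trace(times=np.arange(1000) * 0.5, values=values)
        res = autocorrelation(tr)
        brute = _brute_acf(values, len(res.lags) - 1)
        assert np.max(np.abs(res.acf - brute)) < 1e-12

    @given(st.integers(min_value=10, max_value=200), st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_bruteforce_property(self, n, seed):
        values = np.random.default_rng(seed).normal(size=n)
        tr = Trace(times=np.arange(n) * 1.0, values=values)
        res = autocorrelation(tr)
        brute = _brute_acf(values, len(res.lags) - 1)
        assert np.max(np.abs(res.acf - brute)) < 1e-12

    def test_alternating_series_lag_one(self):
        """ACF(1 sample) of +1,-1,+1,... equals -(N-1)/N under N-normalization."""
        n = 64
        values = np.tile([1.0, -1.0], n // 2)
        tr = Trace(times=np.arange(n) * 1.0, values=values)
        res = autocorrelation(tr)
        assert res.acf[1] == pytest.approx(_brute_acf(values, 1)[1], abs=1e-14)
        assert res.acf[1] == pytest.approx(-(n - 1) / n, abs=1e-12)

    @given(a=st.floats(min_value=-10, max_value=10).filter(lambda a: abs(a) > 1e-3),
           b=st.floats(min_value=-10, max_value=10))
    def test_affine_invariance(self, a, b):
        values = np.random.default_rng(11).normal(size=300)
        base = autocorrelation(Trace(times=np.arange(300) * 1.0, values=values))
        scaled = autocorrelation(
            Trace(times=np.arange(300) * 1.0, values=a * values + b)
        )
        assert np.allclose(base.acf, scaled.acf, atol=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            autocorrelation(Trace(times=TIMES, values=np.ones_like(TIMES)))

    def test_max_lag_must_be_inside_record(self):
        tr = Trace(times=TIMES, values=np.cos(TIMES))
        with pytest.raises(InvalidParameterError):
            autocorrelation(tr, max_lag_ps=1e4)


class TestHalfPeriod:
    def test_cosine_reversal(self):
        """cos(pi*lag/900 ps) changes sign at 450 ps -> half period 900 ps."""
        lags = np.arange(0.0, 1000.5, 0.5)
        res = ACFResult(lags=lags, acf=np.cos(np.pi * lags / 900.0),
                        mean=0.0, variance=1.0)
        est = acf_half_period(res)
        assert est.found
        assert est.reversal_lag_ps == pytest.approx(450.0, abs=0.5)
        assert est.half_period_ps == pytest.approx(900.0, abs=1.0)

    def test_monotone_decay_not_found(self):
        lags = np.arange(0.0, 500.5, 0.5)
        res = ACFResult(lags=lags, acf=np.exp(-lags / 100.0), mean=0.0, variance=1.0)
        est = acf_half_period(res)
        assert not est.found
        assert est.half_period_ps is None

    def test_matches_exhaustive_scan_on_emulation_acf(self):
        """Estimator equals 2x the first smoothed sign change found by scan."""
        from holehop.synthetic import TraceConfig, generate_gap_trace

        cfg = TraceConfig(seed=3)
        gap = gap_trace(replicate_average(
            [generate_gap_trace(cfg, i) for i in range(3)]
        ))
        res = autocorrelation(gap)
        est = acf_half_period(res, smooth_window_ps=25.0)
        # independent scan: same smoothing, explicit first sign-flip search
        n_w = 51  # 25 ps / 0.5 ps, forced odd
        kernel = np.full(n_w, 1.0 / n_w)
        smoothed = np.convolve(res.acf, kernel, mode="valid")
        offset = (n_w - 1) // 2
        idx = next(i for i, v in enumerate(smoothed) if np.sign(v) != np.sign(smoothed[0]))
        s0, s1 = smoothed[idx - 1], smoothed[idx]
        lag = res.lags[offset + idx - 1] + 0.5 * s0 / (s0 - s1)
        assert est.found
        assert est.half_period_ps == pytest.approx(2.0 * lag, abs=1e-9)


class TestEqualizationTime:
    def test_noiseless_ramp_crosses_at_800(self):
        t = np.arange(0.0, 2000.5, 0.5)
        gap = Trace(times=t, values=-2.0 + 2.5e-3 * t)
        est = equalization_time(gap, window_ps=50.0)
        assert est.found
        assert est.t_eq_ps == pytest.approx(800.0, abs=1e-6)

    def test_constant_trace_not_found(self):
        gap = Trace(times=TIMES, values=np.full_like(TIMES, -1.0))
        est = equalization_time(gap, window_ps=10.0)
        assert not est.found
        assert est.final_smoothed_value == pytest.approx(-1.0)

    def test_noisy_ramp_recovery_within_80ps(self):
        t = np.arange(0.0, 2000.5, 0.5)
        noise = ou_process(t.size, 0.5, 0.15, 10.0, seed=8)
        gap = Trace(times=t, values=-2.0 + 2.5e-3 * t + noise)
        est = equalization_time(gap, window_ps=50.0)
        assert est.found
        assert abs(est.t_eq_ps - 800.0) <= 80.0

    def test_linear_fit_mode_on_ramp(self):
        t = np.arange(0.0, 2000.5, 0.5)
        gap = Trace(times=t, values=-2.0 + 2.5e-3 * t)
        est = equalization_time(gap, window_ps=50.0, mode="linear_fit")
        assert est.found
        assert est.t_eq_ps == pytest.approx(800.0, abs=1e-6)

    def test_time_shift_equivariance_and_scale_invariance(self):
        t = np.arange(0.0, 2000.5, 0.5)
        noise = ou_process(t.size, 0.5, 0.1, 10.0, seed=21)
        values = -2.0 + 2.5e-3 * t + noise
        base = equalization_time(Trace(times=t, values=values))
        shifted = equalization_time(Trace(times=t + 123.0, values=values))
        scaled = equalization_time(Trace(times=t, values=3.0 * values))
        assert shifted.t_eq_ps == pytest.approx(base.t_eq_ps + 123.0, abs=1e-9)
        assert scaled.t_eq_ps == pytest.approx(base.t_eq_ps, abs=1e-9)

    def test_window_longer_than_record_rejected(self):
        gap = Trace(times=TIMES, values=np.cos(TIMES))
        with pytest.raises(InvalidParameterError):
            equalization_time(gap, window_ps=1e4)


def _cosine_trace(wavenumbers, n=10_000, dt=0.001, amps=None):
    t = np.arange(n) * dt
    amps = amps or [1.0] * len(wavenumbers)
    values = np.zeros(n)
    for wn, amp in zip(wavenumbers, amps):
        values += amp * np.cos(2 * np.pi * (wn / THZ_TO_WAVENUMBER) * t)
    return Trace(times=t, values=values)


class TestFourierSpectrum:
    def test_single_peak_in_correct_bin(self):
        spec = fourier_spectrum(_cosine_trace([1000.0]))
        bin_width = spec.wavenumbers[1] - spec.wavenumbers[0]
        peak = spec.wavenumbers[np.argmax(spec.amplitude)]
        assert abs(peak - 1000.0) <= bin_width

    def test_equal_amplitude_bin_centered_peaks_equal_height(self):
        spec0 = fourier_spectrum(_cosine_trace([1000.0]))
        bin_width = spec0.wavenumbers[1] - spec0.wavenumbers[0]
        wn_a, wn_b = 90 * bin_width, 750 * bin_width  # ~300 and ~2500 cm^-1
        spec = fourier_spectrum(_cosine_trace([wn_a, wn_b]))
        h_a = spec.amplitude[90]
        h_b = spec.amplitude[750]
        assert h_a == pytest.approx(h_b, rel=0.01)

    def test_parseval_identity(self, rng):
        from scipy.signal import get_window

        values = rng.normal(size=512) + 0.01 * np.arange(512)
        tr = Trace(times=np.arange(512) * 0.001, values=values)
        spec = fourier_spectrum(tr, detrend="linear", window="hann")
        # reconstruct the windowed, detrended signal independently
        from scipy.signal import detrend as sp_detrend

        y = sp_detrend(values, type="linear") * get_window("hann", 512)
        energy_time = np.sum(y**2)
        a = spec.amplitude
        energy_freq = (a[0] ** 2 + 2 * np.sum(a[1:-1] ** 2) + a[-1] ** 2) / 512
        assert energy_freq == pytest.approx(energy_time, rel=1e-6)

    def test_short_series_rejected(self):
        tr = Trace(times=np.arange(8) * 0.001, values=np.arange(8.0))
        with pytest.raises(InvalidParameterError):
            fourier_spectrum(tr)

    def test_nonuniform_grid_rejected(self):
        times = np.concatenate([np.arange(10.0), [10.5, 12.0, 13.0, 14.0, 15.0, 16.0]])
        with pytest.raises(InvalidParameterError):
            Trace(times=times, values=np.zeros(16))
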