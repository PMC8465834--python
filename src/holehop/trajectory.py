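"""Statistics for site-energy and potential time series from MD/QM-MM output.

Works on uniformly sampled traces: the donor/acceptor HOMO-energy proxies and
their gap ΔE(t) = E_donor − E_acceptor (negative while the hole is more stable
on the donor), replicate averaging with standard errors, the normalized
energy-gap autocorrelation function ACF(ℓ) = ⟨δE(0)δE(ℓ)⟩/⟨(δE)²⟩, the lag of
its first direction reversal (half period = twice that lag), the time at which
donor and acceptor levels equalize (smoothed zero crossing of the gap), and
one-sided Fourier spectra on a wavenumber axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import detrend as _detrend, get_window

from .constants import THZ_TO_WAVENUMBER
from .errors import (
    AlignmentError,
    DegenerateInputError,
    InvalidParameterError,
    MissingChannelError,
)

__all__ = [
    "Trace",
    "SiteEnergyTrace",
    "ACFResult",
    "EqualizationEstimate",
    "HalfPeriodEstimate",
    "SpectrumResult",
    "gap_trace",
    "replicate_average",
    "autocorrelation",
    "acf_half_period",
    "equalization_time",
    "fourier_spectrum",
]

#: Relative tolerance on time-grid uniformity.
_GRID_RTOL = 1e-9


def _check_grid(times: np.ndarray) -> float:
    """Validate a strictly increasing uniform time grid; return the step."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise InvalidParameterError("time grid must be 1-D with at least 2 samples")
    steps = np.diff(times)
    dt = float(steps[0])
    if dt <= 0 or np.any(steps <= 0):
        raise InvalidParameterError("times must be strictly increasing")
    if np.max(np.abs(steps - dt)) > _GRID_RTOL * abs(dt):
        raise InvalidParameterError("time grid is not uniform")
    return dt


@dataclass
class Trace:
    """A single-channel uniformly sampled time series (times in ps)."""

    times: np.ndarray
    values: np.ndarray
    label: str = "value"
    replicate: int | None = None
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self._dt = _check_grid(self.times)
        if self.values.shape != self.times.shape:
            raise InvalidParameterError("values and times must have equal length")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.times.shape:
                raise InvalidParameterError("sem and times must have equal length")

    @property
    def dt(self) -> float:
        return self._dt

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class SiteEnergyTrace:
    """Donor/acceptor site-energy channels on a shared uniform time grid.

    Energies are HOMO-energy proxies in eV; ``sem_donor``/``sem_acceptor``
    hold per-point standard errors after replicate averaging.
    """

    times: np.ndarray
    e_donor: np.ndarray
    e_acceptor: np.ndarray
    replicate: int | None = None
    sem_donor: np.ndarray | None = None
    sem_acceptor: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self._dt = _check_grid(self.times)
        for name in ("e_donor", "e_acceptor", "sem_donor", "sem_acceptor"):
            arr = getattr(self, name)
            if arr is None:
                if name.startswith("e_"):
                    raise MissingChannelError(f"channel {name} is required")
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.times.shape:
                raise InvalidParameterError(f"{name} and times must have equal length")
            setattr(self, name, arr)

    @property
    def dt(self) -> float:
        return self._dt


def gap_trace(trace: SiteEnergyTrace) -> Trace:
    """Donor-minus-acceptor gap ΔE(t) in eV as a single-channel trace.

    Negative while the hole is more stable on the donor (donor level below the
    acceptor level), so a trace emulating hole injection at G starts near
    −2 eV and rises toward zero.
    """
    if not isinstance(trace, SiteEnergyTrace):
        raise MissingChannelError(
            "gap_trace needs a two-channel SiteEnergyTrace, got a single-channel trace"
        )
    if trace.e_donor is None or trace.e_acceptor is None:
        raise MissingChannelError("gap_trace needs both donor and acceptor channels")
    return Trace(
        times=trace.times.copy(),
        values=trace.e_donor - trace.e_acceptor,
        label="gap_eV",
        replicate=trace.replicate,
    )


def _same_grid(grids: list[np.ndarray]) -> np.ndarray:
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape or np.max(np.abs(g - ref)) > _GRID_RTOL * max(
            1.0, float(np.max(np.abs(ref)))
        ):
            raise AlignmentError(
                "replicate time grids differ; no silent interpolation is performed"
            )
    return ref


def replicate_average(traces):
    """Pointwise mean over replicates with standard-error channels.

    Accepts a list of :class:`SiteEnergyTrace` (averages both channels) or a
    list of :class:`Trace` (averages the single channel).  SEM is the sample
    standard deviation (ddof=1) divided by sqrt(n); for a single replicate it
    is left ``None``.  Time grids must be identical.
    """
    if not traces:
        raise InvalidParameterError("need at least one replicate")
    n = len(traces)
    if isinstance(traces[0], Trace):
        times = _same_grid([t.times for t in traces])
        stack = np.vstack([t.values for t in traces])
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else None
        return Trace(times=times.copy(), values=stack.mean(axis=0),
                     label=traces[0].label, sem=sem)
    times = _same_grid([t.times for t in traces])
    donor = np.vstack([t.e_donor for t in traces])
    acceptor = np.vstack([t.e_acceptor for t in traces])
    if n > 1:
        sem_d = donor.std(axis=0, ddof=1) / np.sqrt(n)
        sem_a = acceptor.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem_d = sem_a = None
    return SiteEnergyTrace(
        times=times.copy(),
        e_donor=donor.mean(axis=0),
        e_acceptor=acceptor.mean(axis=0),
        sem_donor=sem_d,
        sem_acceptor=sem_a,
    )


@dataclass
class ACFResult:
    """Normalized autocorrelation on a lag grid starting at zero.

    ``mean`` is the record mean used as the equilibrium value, ``variance``
    the N-normalized variance ⟨(δE)²⟩ that normalizes the estimator.
    ACF(0) = 1 exactly by construction.
    """

    lags: np.ndarray
    acf: np.ndarray
    mean: float
    variance: float


def autocorrelation(trace: Trace, max_lag_ps: float | None = None) -> ACFResult:
    """N-normalized (biased) autocorrelation estimator of a trace.

    ACF(ℓ) = Σ_t δx(t) δx(t+ℓ) / Σ_t δx(t)² with δx = x − mean(x); the 1/N
    factors of the standard biased estimator cancel in the ratio.  The default
    maximum lag is half the record span; the lag grid starts at zero and
    advances by one sampling interval.
    """
    values = trace.values
    n = values.size
    mean = float(values.mean())
    delta = values - mean
    denom = float(np.dot(delta, delta))
    variance = denom / n
    if denom <= 0.0 or not np.isfinite(denom):
        raise DegenerateInputError("series has zero variance; ACF undefined")
    if max_lag_ps is None:
        max_lag_ps = trace.span / 2.0
    if max_lag_ps >= trace.span:
        raise InvalidParameterError("max_lag must be smaller than the record span")
    n_lags = int(np.floor(max_lag_ps / trace.dt + _GRID_RTOL))
    n_lags = min(n_lags, n - 1)
    corr = np.correlate(delta, delta, mode="full")[n - 1 : n + n_lags]
    acf = corr / denom
    acf[0] = 1.0
    lags = np.arange(n_lags + 1) * trace.dt
    return ACFResult(lags=lags, acf=acf, mean=mean, variance=variance)


def _centered_smooth(values: np.ndarray, n_window: int) -> np.ndarray:
    """Centered moving average over an odd window, valid region only."""
    if n_window <= 1:
        return values.copy()
    kernel = np.full(n_window, 1.0 / n_window)
    return np.convolve(values, kernel, mode="valid")


def _odd_window_samples(window_ps: float, dt: float, n: int) -> int:
    n_window = max(1, int(round(window_ps / dt)))
    if n_window % 2 == 0:
        n_window += 1
    if n_window > n:
        raise InvalidParameterError(
            f"smoothing window ({window_ps} ps) exceeds the record length"
        )
    return n_window


@dataclass
class HalfPeriodEstimate:
    """Half period of the slow ACF oscillation: 2x the first reversal lag."""

    half_period_ps: float | None
    reversal_lag_ps: float | None
    found: bool
    smooth_window_ps: float


def acf_half_period(
    result: ACFResult, smooth_window_ps: float = 25.0
) -> HalfPeriodEstimate:
    """Half period from the first sign reversal of the smoothed ACF.

    For a cosine-like ACF the correlation changes sign a quarter period after
    lag zero (for cos(pi * lag / T) the crossing sits at T/2), so twice the
    lag of the first zero crossing of the smoothed ACF estimates the half
    period of the slow mode.  The crossing is linearly interpolated between
    lag samples.  An ACF that never changes sign within its lag range (e.g. a
    monotone exponential decay) yields ``found=False`` rather than an
    exception.
    """
    if result.lags.size < 3:
        return HalfPeriodEstimate(None, None, False, smooth_window_ps)
    dt = float(result.lags[1] - result.lags[0])
    n_window = _odd_window_samples(smooth_window_ps, dt, result.acf.size)
    smoothed = _centered_smooth(result.acf, n_window)
    offset = (n_window - 1) // 2
    sign0 = np.sign(smoothed[0])
    if sign0 == 0:
        return HalfPeriodEstimate(None, None, False, smooth_window_ps)
    flips = np.nonzero(np.sign(smoothed) == -sign0)[0]
    if flips.size == 0:
        return HalfPeriodEstimate(None, None, False, smooth_window_ps)
    k = int(flips[0])
    lag_k = result.lags[offset + k]
    if k == 0:
        reversal_lag = float(lag_k)
    else:
        s0, s1 = smoothed[k - 1], smoothed[k]
        lag_prev = result.lags[offset + k - 1]
        reversal_lag = float(lag_prev + (lag_k - lag_prev) * s0 / (s0 - s1))
    return HalfPeriodEstimate(
        half_period_ps=2.0 * reversal_lag,
        reversal_lag_ps=reversal_lag,
        found=True,
        smooth_window_ps=smooth_window_ps,
    )


@dataclass
class EqualizationEstimate:
    """Time at which the smoothed donor-acceptor gap first crosses zero."""

    t_eq_ps: float | None
    found: bool
    method: str
    window_ps: float
    final_smoothed_value: float


def equalization_time(
    gap: Trace, window_ps: float = 50.0, mode: str = "moving_average"
) -> EqualizationEstimate:
    """Estimate the donor/acceptor level-equalization time from a gap trace.

    ``moving_average`` (default): first zero crossing of the centered moving
    average of ΔE(t), linearly interpolated between samples.  ``linear_fit``:
    straight-line fit to the raw gap over the segment preceding the smoothed
    crossing (the full record when there is none), intersected with zero.

    When no crossing exists the estimate is flagged not-found and the final
    smoothed value is reported.
    """
    if mode not in ("moving_average", "linear_fit"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    n = gap.values.size
    n_window = _odd_window_samples(window_ps, gap.dt, n)
    smoothed = _centered_smooth(gap.values, n_window)
    offset = (n_window - 1) // 2
    t_valid = gap.times[offset : n - offset]

    sign0 = np.sign(smoothed[0])
    crossing_idx: int | None = None
    if sign0 == 0:
        crossing_idx = 0
    else:
        opposite = np.nonzero(np.sign(smoothed) != sign0)[0]
        if opposite.size:
            crossing_idx = int(opposite[0])

    if crossing_idx is None:
        if mode == "moving_average":
            return EqualizationEstimate(
                None, False, mode, window_ps, float(smoothed[-1])
            )
        fit_stop = n
    else:
        fit_stop = offset + crossing_idx

    if mode == "moving_average":
        k = crossing_idx
        if k == 0:
            t_eq = float(t_valid[0])
        else:
            s0, s1 = smoothed[k - 1], smoothed[k]
            t0, t1 = t_valid[k - 1], t_valid[k]
            t_eq = float(t0 + (t1 - t0) * s0 / (s0 - s1)) if s1 != s0 else float(t1)
        return EqualizationEstimate(t_eq, True, mode, window_ps, float(smoothed[-1]))

    # linear_fit: fit the pre-crossing raw segment and intersect with zero.
    fit_stop = max(fit_stop, 2)
    slope, intercept = np.polyfit(gap.times[:fit_stop], gap.values[:fit_stop], 1)
    if slope == 0.0:
        return EqualizationEstimate(None, False, mode, window_ps, float(smoothed[-1]))
    root = -intercept / slope
    found = bool(gap.times[0] <= root <= gap.times[-1])
    return EqualizationEstimate(
        float(root) if found else None, found, mode, window_ps, float(smoothed[-1])
    )


@dataclass
class SpectrumResult:
    """One-sided amplitude spectrum on a wavenumber axis.

    ``amplitude`` is the raw rfft magnitude |X_k| of the detrended, tapered
    signal, so Parseval's identity reads
    Σ_t y(t)² = (|X_0|² + 2 Σ_mid |X_k|² + [|X_Nyq|² if N even]) / N.
    """

    wavenumbers: np.ndarray
    amplitude: np.ndarray
    detrend: str
    window: str
    n_samples: int
    dt_ps: float

    @property
    def nyquist_wavenumber(self) -> float:
        return float(self.wavenumbers[-1])


def fourier_spectrum(
    trace: Trace, detrend: str = "mean", window: str = "hann"
) -> SpectrumResult:
    """Discrete Fourier spectrum of a uniformly sampled trace.

    The mean (or a linear trend, ``detrend='linear'``) is removed, the taper
    applied (Hann by default; any scipy window name), and the one-sided rfft
    magnitude returned against wavenumbers in cm^-1 (1 THz = 33.35641 cm^-1).
    A 0.5 ps sampling interval caps the axis near 33 cm^-1; resolving the
    100–3000 cm^-1 vibrational band requires fs-sampled input.
    """
    if trace.values.size < 16:
        raise InvalidParameterError("spectrum requires at least 16 samples")
    if detrend == "mean":
        y = trace.values - trace.values.mean()
    elif detrend == "linear":
        y = _detrend(trace.values, type="linear")
    elif detrend == "none":
        y = trace.values.copy()
    else:
        raise InvalidParameterError(f"unknown detrend mode {detrend!r}")
    taper = get_window(window, trace.values.size)
    y = y * taper
    amplitude = np.abs(np.fft.rfft(y))
    freqs_thz = np.fft.rfftfreq(y.size, d=trace.dt)  # 1/ps = THz
    return SpectrumResult(
        wavenumbers=freqs_thz * THZ_TO_WAVENUMBER,
        amplitude=amplitude,
        detrend=detrend,
        window=window,
        n_samples=y.size,
        dt_ps=trace.dt,
    )
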