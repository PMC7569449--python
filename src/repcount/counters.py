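"""The three training-free repetition counters.

All three operate on a :class:`~repcount.preprocess.SignedMagnitudeSeries`
and return a :class:`CountResult`:

``threshold``
    Count upward crossings of a level placed at a fixed fraction (default
    2/3) of the signal range, with a refractory period (default 0.1 s) after
    each counted crossing during which further crossings are suppressed.
``threshold_lowpass``
    Identical, but applied after a first-order recursive low-pass filter
    ``A_{i+1} = (1−α)·A_i + α·X_i`` (default α = 0.1) that attenuates
    high-frequency noise; the threshold is recomputed on the filtered signal.
``fourier``
    Mean-subtract, find the dominant frequency f* of the magnitude spectrum
    inside a physiological band, and report ``count = round(f* · T)`` where
    T is the session duration.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy.signal import lfilter

from .errors import DegenerateSignalError, ParameterError
from .preprocess import SignedMagnitudeSeries

__all__ = [
    "METHODS",
    "CounterConfig",
    "CountResult",
    "threshold_level",
    "count_threshold",
    "lowpass_filter",
    "count_threshold_lowpass",
    "count_fourier",
    "run_counter",
]

log = logging.getLogger(__name__)

#: Canonical method identifiers, in presentation order.
METHODS = ("threshold", "threshold_lowpass", "fourier")

# below this range the signal is considered flat and counts are zero
_RANGE_EPS = 1e-9


@dataclasses.dataclass(frozen=True)
class CounterConfig:
    """Parameters shared by the counting methods.

    threshold_frac
        Fraction of the min-to-max range at which the crossing threshold is
        placed, in (0, 1). Default 2/3.
    refractory_s
        Seconds after a counted crossing during which further crossings are
        suppressed (they do not reset the period). Default 0.1 s.
    alpha
        Coefficient of the recursive low-pass filter, in (0, 1). Default 0.1.
    band_hz
        (f_min, f_max) search band for the dominant frequency, Hz. Default
        (0.2, 5.0): covers human repetition cadences while excluding the DC
        bin and tremor-band noise.
    round_mode
        How the Fourier count maps to an integer: ``nearest`` (half up) or
        ``floor``.
    """

    threshold_frac: float = 2.0 / 3.0
    refractory_s: float = 0.1
    alpha: float = 0.1
    band_hz: tuple[float, float] = (0.2, 5.0)
    round_mode: str = "nearest"

    def __post_init__(self) -> None:
        if not 0 < self.threshold_frac < 1:
            raise ParameterError(f"threshold_frac must be in (0,1), got {self.threshold_frac}")
        if self.refractory_s < 0:
            raise ParameterError(f"refractory_s must be ≥ 0, got {self.refractory_s}")
        if not 0 < self.alpha < 1:
            raise ParameterError(f"alpha must be in (0,1), got {self.alpha}")
        f_min, f_max = self.band_hz
        if not 0 <= f_min < f_max:
            raise ParameterError(f"need 0 ≤ f_min < f_max, got {self.band_hz}")
        if self.round_mode not in ("nearest", "floor"):
            raise ParameterError(f"unknown round_mode {self.round_mode!r}")


@dataclasses.dataclass(frozen=True)
class CountResult:
    """One counter's estimate for one session."""

    method: str
    count: int
    duration_s: float
    threshold_used: float | None = None
    dominant_freq_hz: float | None = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ParameterError("count must be non-negative")


def threshold_level(series: SignedMagnitudeSeries,
                    threshold_frac: float = 2.0 / 3.0) -> float:
    """Threshold τ = min(s) + frac·(max(s) − min(s)).

    Raises
    ------
    DegenerateSignalError
        If the signal range is below 1e−9 (flat signal); callers report a
        count of zero in that case.
    """
    if not 0 < threshold_frac < 1:
        raise ParameterError(f"threshold_frac must be in (0,1), got {threshold_frac}")
    lo = float(np.min(series.s))
    hi = float(np.max(series.s))
    if hi - lo < _RANGE_EPS:
        raise DegenerateSignalError(f"signal range {hi - lo:.3g} is degenerate")
    return lo + threshold_frac * (hi - lo)


def _crossings_with_refractory(s: np.ndarray, fs: float, tau: float,
                               refractory_s: float) -> int:
    """Upward crossings s_{k-1} < τ ≤ s_k, with suppression-only refractory.

    The refractory clock starts at each *counted* crossing; suppressed
    crossings do not reset it.
    """
    idx = np.flatnonzero((s[:-1] < tau) & (s[1:] >= tau)) + 1
    count = 0
    last_t = -math.inf
    for k in idx:
        t = k / fs
        if t - last_t >= refractory_s:
            count += 1
            last_t = t
    return count


def count_threshold(series: SignedMagnitudeSeries,
                    cfg: CounterConfig | None = None) -> CountResult:
    """Threshold-crossing count with refractory period."""
    cfg = cfg or CounterConfig()
    try:
        tau = threshold_level(series, cfg.threshold_frac)
    except DegenerateSignalError:
        log.warning("degenerate (flat) signal: threshold count is 0")
        return CountResult(method="threshold", count=0,
                           duration_s=series.duration_s)
    count = _crossings_with_refractory(series.s, series.fs, tau, cfg.refractory_s)
    return CountResult(method="threshold", count=count,
                       duration_s=series.duration_s, threshold_used=tau)


def lowpass_filter(series: SignedMagnitudeSeries, alpha: float = 0.1,
                   initial: float | None = None) -> SignedMagnitudeSeries:
    """First-order recursive low-pass ``A_{i+1} = (1−α)·A_i + α·X_i``.

    The input sample X_i drives the *next* output sample, as the recursion
    is written. ``initial`` sets A_0; by default A_0 = X_0, which avoids a
    startup transient (``initial=0.0`` exposes the raw impulse response).
    Output length equals input length.
    """
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0,1), got {alpha}")
    x = series.s
    a0 = float(x[0]) if initial is None else float(initial)
    out = np.empty_like(x)
    out[0] = a0
    # A[1:] is the IIR response to X[:-1] with state A_0
    out[1:], _ = lfilter([alpha], [1.0, -(1.0 - alpha)], x[:-1],
                         zi=[(1.0 - alpha) * a0])
    return SignedMagnitudeSeries(fs=series.fs, s=out, mode=series.mode)


def count_threshold_lowpass(series: SignedMagnitudeSeries,
                            cfg: CounterConfig | None = None) -> CountResult:
    """Threshold-crossing count on the low-pass-filtered signal.

    Exactly ``count_threshold(lowpass_filter(series, α))`` with the threshold
    recomputed on the filtered signal.
    """
    cfg = cfg or CounterConfig()
    filtered = lowpass_filter(series, cfg.alpha)
    base = count_threshold(filtered, cfg)
    return dataclasses.replace(base, method="threshold_lowpass")


def count_fourier(series: SignedMagnitudeSeries,
                  cfg: CounterConfig | None = None) -> CountResult:
    """Dominant-frequency count: ``count = round(f* · T)``.

    The series mean is removed, the magnitude spectrum computed, and f* taken
    as the highest-magnitude bin inside ``band_hz`` (ties break toward the
    lower frequency, avoiding harmonic capture). If no bin falls in the band
    the count is zero.
    """
    cfg = cfg or CounterConfig()
    n = len(series)
    if n < 4:
        raise ParameterError("fourier counting needs at least 4 samples")
    duration = series.duration_s
    if float(np.max(series.s)) - float(np.min(series.s)) < _RANGE_EPS:
        log.warning("degenerate (flat) signal: fourier count is 0")
        return CountResult(method="fourier", count=0, duration_s=duration)
    mag = np.abs(np.fft.rfft(series.s - np.mean(series.s)))
    freqs = np.fft.rfftfreq(n, d=1.0 / series.fs)
    f_min, f_max = cfg.band_hz
    in_band = np.flatnonzero((freqs >= f_min) & (freqs <= f_max))
    if in_band.size == 0:
        log.warning("no spectral bin inside band %s at fs=%g, n=%d",
                    cfg.band_hz, series.fs, n)
        return CountResult(method="fourier", count=0, duration_s=duration)
    # argmax returns the first maximum, i.e. the lowest tied frequency
    f_star = float(freqs[in_band[np.argmax(mag[in_band])]])
    raw = f_star * duration
    count = math.floor(raw + 0.5) if cfg.round_mode == "nearest" else math.floor(raw)
    return CountResult(method="fourier", count=count, duration_s=duration,
                       dominant_freq_hz=f_star)


_DISPATCH = {
    "threshold": count_threshold,
    "threshold_lowpass": count_threshold_lowpass,
    "fourier": count_fourier,
}


def run_counter(method: str, series: SignedMagnitudeSeries,
                cfg: CounterConfig | None = None) -> CountResult:
    """Dispatch a method identifier to its counter."""
    try:
        fn = _DISPATCH[method]
    except KeyError:
        raise ParameterError(
            f"unknown method {method!r}; choose from {METHODS}") from None
    return fn(series, cfg)
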