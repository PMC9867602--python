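"""Fiber-photometry preprocessing.

Normalization to dF/F (isosbestic-fit or moving-average baseline), zero-phase
Chebyshev band-pass filtering, anti-aliased resampling onto the widefield
frame clock, z-scoring, and a sum-of-squares SNR. The same temporal filter is
applied to photometry and to cortical pixels so that filtering introduces no
relative lag between the two signals; all filters run forward-backward
(zero phase), which additionally preserves absolute event times for the lag
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from mesophot.core import (
    DegenerateDataError,
    NumericalDomainError,
    ParameterError,
    AlignmentError,
    Trace,
    moving_mean,
)


@dataclass
class DFFTrace(Trace):
    """A dF/F trace; ``method`` records which baseline definition produced it."""

    method: str = "moving_average"


def isosbestic_dff(f465: Trace, f405: Trace) -> DFFTrace:
    """dF/F using the isosbestic channel as fitted baseline.

    The calcium-insensitive 405-nm channel is fitted to the 465-nm channel by
    ordinary least squares (F0 = a*F405 + b) and treated as baseline
    fluorescence F0; the output is (F465 - F0) / F0. Because the fit is
    affine, the result is invariant to affine rescaling of the 405 channel.

    Raises
    ------
    DegenerateDataError
        If the 405 channel is constant (the fit is underdetermined).
    NumericalDomainError
        If the fitted baseline is not strictly positive everywhere.
    """
    if f465.n != f405.n:
        raise AlignmentError(f"channel lengths differ: {f465.n} vs {f405.n}")
    if not np.isclose(f465.fs, f405.fs):
        raise AlignmentError(f"channel rates differ: {f465.fs} vs {f405.fs} Hz")
    x = f405.samples
    y = f465.samples
    if np.ptp(x) == 0:
        raise DegenerateDataError("405 channel is constant; isosbestic fit is degenerate")
    a, b = np.polyfit(x, y, 1)
    f0 = a * x + b
    if np.any(f0 <= 0):
        raise NumericalDomainError(
            "fitted baseline F0 is not strictly positive; cannot form dF/F"
        )
    return DFFTrace((y - f0) / f0, fs=f465.fs, t0=f465.t0, method="isosbestic")


def moving_avg_dff(trace: Trace, window_s: float = 10.0, divide: bool = True) -> DFFTrace:
    """dF/F using a centered moving average (default 10 s) as baseline F0.

    ``divide=True`` returns (F - F0)/F0 for dimensional consistency with the
    isosbestic method and the cortical dF/F; ``divide=False`` gives the
    subtract-only variant F - F0. The window shrinks at the recording edges so
    F0 is defined at every sample.
    """
    n = int(round(window_s * trace.fs))
    if n < 1:
        raise ParameterError(
            f"window of {window_s} s covers no samples at fs={trace.fs} Hz"
        )
    f0 = moving_mean(trace.samples, n)
    if divide:
        if np.any(f0 <= 0):
            raise NumericalDomainError(
                "moving-average baseline F0 is not strictly positive; "
                "use divide=False for the subtract-only variant"
            )
        out = (trace.samples - f0) / f0
    else:
        out = trace.samples - f0
    return DFFTrace(out, fs=trace.fs, t0=trace.t0, method="moving_average")


def _bandpass_sos(low: float, high: float, fs: float) -> np.ndarray:
    if not (0 < low < high < fs / 2):
        raise ParameterError(
            f"band ({low}, {high}) Hz is invalid for fs={fs} Hz (need 0 < low < high < fs/2)"
        )
    return signal.cheby1(2, 0.5, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(trace: Trace, low: float = 0.1, high: float = 12.0) -> Trace:
    """Zero-phase Chebyshev type-I band-pass (order 2, 0.5 dB ripple).

    Applied forward-backward with :func:`scipy.signal.sosfiltfilt`, so the
    magnitude response is the squared single-pass response and the phase is
    zero (no group delay).
    """
    sos = _bandpass_sos(low, high, trace.fs)
    return trace.with_samples(signal.sosfiltfilt(sos, trace.samples))


def _antialias_sos(fs: float, fs_out: float) -> np.ndarray:
    # MATLAB-style decimation filter: Chebyshev I, order 8, 0.05 dB ripple,
    # cutoff at 0.8x the output Nyquist.
    return signal.cheby1(8, 0.05, 0.8 * fs_out / 2, btype="low", fs=fs, output="sos")


def resample_trace(trace: Trace, fs_out: float = 40.0) -> Trace:
    """Resample onto the widefield frame clock with an anti-aliasing filter.

    A zero-phase low-pass Chebyshev type-I filter of order 8 (cutoff
    0.8 * fs_out/2) is applied, then the trace is linearly interpolated onto
    the output grid ``t0 + k / fs_out``. If ``fs_out == fs`` the trace is
    returned unchanged (identical grid, pure passband).
    """
    if fs_out > trace.fs:
        raise ParameterError(
            f"cannot resample upward: fs_out={fs_out} > fs={trace.fs}"
        )
    if np.isclose(fs_out, trace.fs):
        return trace.with_samples(trace.samples.copy())
    filtered = signal.sosfiltfilt(_antialias_sos(trace.fs, fs_out), trace.samples)
    n_out = int(np.floor(trace.duration * fs_out)) + 1
    t_out = trace.t0 + np.arange(n_out) / fs_out
    out = np.interp(t_out, trace.times, filtered)
    return Trace(out, fs=fs_out, t0=trace.t0)


def zscore_trace(trace: Trace) -> Trace:
    """Z-score (population SD). A constant trace maps to all zeros."""
    x = trace.samples
    sd = x.std()
    if sd == 0:
        return trace.with_samples(np.zeros_like(x))
    return trace.with_samples((x - x.mean()) / sd)


def snr_db(sig: Trace | np.ndarray, noise: Trace | np.ndarray) -> float:
    """Signal-to-noise ratio in dB: 10*log10(sum(s^2) / sum(n^2))."""
    s = sig.samples if isinstance(sig, Trace) else np.asarray(sig, dtype=np.float64)
    n = noise.samples if isinstance(noise, Trace) else np.asarray(noise, dtype=np.float64)
    if s.size == 0 or n.size == 0:
        raise ParameterError("signal and noise must be non-empty")
    ss = float(np.sum(s.astype(np.float64) ** 2))
    nn = float(np.sum(n.astype(np.float64) ** 2))
    if nn == 0:
        warnings.warn("noise power is zero; SNR is infinite", RuntimeWarning)
        return np.inf
    return 10.0 * np.log10(ss / nn)
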