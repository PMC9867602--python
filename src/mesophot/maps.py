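"""Pixel-wise correlation, partial correlation, and lag maps.

Each map compares every cortical pixel's time series against the striatal
photometry trace (already resampled to the widefield frame clock). The lag
map reports, per pixel, the integer-frame lag maximizing the cross-correlation;
pixels whose peak correlation falls below a threshold (default 0.5) are marked
invalid ("gray"). Sign convention throughout: negative lag means the cortical
signal leads the striatal signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from mesophot.core import (
    AlignmentError,
    DegenerateDataError,
    ParameterError,
    Trace,
    WidefieldStack,
)

_MIN_OVERLAP = 10


@dataclass
class CorrelationMap:
    """Per-pixel Pearson r image; ``kind`` is "full" or "partial"."""

    values: np.ndarray
    kind: str
    mask: np.ndarray
    degenerate: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = np.zeros_like(self.mask, dtype=bool)


@dataclass
class LagMap:
    """Per-pixel lag (s) at the cross-correlation peak, with validity flags.

    ``lags`` is in seconds (negative: cortex leads); ``peak_r`` holds the peak
    correlation; ``valid`` marks masked pixels whose peak reaches
    ``r_threshold``. Lags are integer multiples of one frame (no sub-sample
    interpolation).
    """

    lags: np.ndarray
    peak_r: np.ndarray
    valid: np.ndarray
    mask: np.ndarray
    r_threshold: float = 0.5
    max_lag: float = 2.0


def _check_aligned(stack: WidefieldStack, trace: Trace) -> None:
    if trace.n != stack.n_frames:
        raise AlignmentError(
            f"trace length {trace.n} does not match stack frames {stack.n_frames}; "
            "resample the trace to the widefield clock first"
        )
    if not np.isclose(trace.fs, stack.fs):
        raise AlignmentError(f"trace fs {trace.fs} != stack fs {stack.fs}")


def _pixel_trace_pearson(X: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r of each row of X against b (float64 accumulation)."""
    T = X.shape[1]
    b = np.asarray(b, dtype=np.float64)
    bc = b - b.mean()
    sb = float(bc @ bc)
    sx = X.sum(axis=1, dtype=np.float64)
    sxx = np.einsum("pt,pt->p", X, X, dtype=np.float64)
    sxb = X @ bc.astype(X.dtype) if X.dtype != np.float64 else X @ bc
    varx = sxx - sx * sx / T
    varx = np.maximum(varx, 0.0)
    den = np.sqrt(varx * sb)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.asarray(sxb, dtype=np.float64) / den
    r[den == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def correlation_map(stack: WidefieldStack, trace: Trace) -> CorrelationMap:
    """Pearson r between each masked pixel's time series and the trace."""
    _check_aligned(stack, trace)
    X = stack.masked_pixels()
    r = _pixel_trace_pearson(X, trace.samples)
    values = np.full(stack.mask.shape, np.nan)
    values[stack.mask] = r
    degen = np.zeros(stack.mask.shape, dtype=bool)
    degen[stack.mask] = ~np.isfinite(r)
    values[degen] = 0.0
    return CorrelationMap(values=values, kind="full", mask=stack.mask, degenerate=degen)


def partial_correlation_map(
    stack: WidefieldStack, trace: Trace, global_trace: Trace
) -> CorrelationMap:
    """Pixel-trace correlation controlling for the global cortical signal.

    Uses the closed form r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))
    with x = pixel, y = trace, z = global signal. Pixels whose residual variance
    after removing the global signal vanishes (|r_xz| = 1) are set to 0 and
    flagged degenerate.
    """
    _check_aligned(stack, trace)
    _check_aligned(stack, global_trace)
    z = global_trace.samples
    if np.ptp(z) == 0:
        raise DegenerateDataError("global signal is constant; cannot control for it")
    X = stack.masked_pixels()
    r_xy = _pixel_trace_pearson(X, trace.samples)
    r_xz = _pixel_trace_pearson(X, z)
    r_yz = _pixel_trace_pearson(trace.samples[None, :], z)[0]
    if not np.isfinite(r_yz):
        raise DegenerateDataError("trace is constant; correlation undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        den = np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
        r = (r_xy - r_xz * r_yz) / den
    bad = ~np.isfinite(r)
    r[bad] = 0.0
    values = np.full(stack.mask.shape, np.nan)
    values[stack.mask] = np.clip(r, -1.0, 1.0)
    degen = np.zeros(stack.mask.shape, dtype=bool)
    degen[stack.mask] = bad
    return CorrelationMap(
        values=values, kind="partial", mask=stack.mask, degenerate=degen
    )


def _pearson_at_lags(X: np.ndarray, b: np.ndarray, m: int) -> tuple:
    """Pearson r of each row of X, lag-shifted, against b.

    Returns (lags, R) where ``lags`` are integer sample shifts in [-m, m] and
    ``R[p, j] = corr(X[p, t + lags[j]], b[t])`` over the overlapping segment,
    with mean and SD re-estimated per lag (so |r| <= 1 exactly at every lag).
    """
    P, T = X.shape
    b = np.asarray(b, dtype=np.float64)
    lags = np.arange(-m, m + 1)
    if T - m < _MIN_OVERLAP:
        raise ParameterError(
            f"overlap of {T - m} samples at max lag is below the minimum "
            f"of {_MIN_OVERLAP}"
        )
    R = np.empty((P, lags.size))
    X2 = (X.astype(np.float64) ** 2) if X.dtype == np.float64 else X * X
    cb = np.concatenate([[0.0], np.cumsum(b)])
    cb2 = np.concatenate([[0.0], np.cumsum(b * b)])
    for j, k in enumerate(lags):
        if k >= 0:
            Xs = X[:, k:T]
            X2s = X2[:, k:T]
            lo, hi = 0, T - k
        else:
            Xs = X[:, : T + k]
            X2s = X2[:, : T + k]
            lo, hi = -k, T
        n = hi - lo
        sb = cb[hi] - cb[lo]
        sbb = cb2[hi] - cb2[lo]
        bs = b[lo:hi]
        sx = Xs.sum(axis=1, dtype=np.float64)
        sxx = X2s.sum(axis=1, dtype=np.float64)
        sxb = np.asarray(
            Xs @ (bs if X.dtype == np.float64 else bs.astype(X.dtype)),
            dtype=np.float64,
        )
        varx = np.maximum(sxx - sx * sx / n, 0.0)
        varb = max(sbb - sb * sb / n, 0.0)
        den = np.sqrt(varx * varb)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (sxb - sx * sb / n) / den
        r[den == 0] = np.nan
        R[:, j] = np.clip(r, -1.0, 1.0)
    return lags, R


def xcorr_lag(a: Trace, b: Trace, max_lag: float) -> tuple:
    """Lag (s) and value of the peak Pearson cross-correlation of two traces.

    ``r(tau) = corr(a(t + tau), b(t))`` for integer-sample tau in
    [-max_lag, max_lag]; returns the tau maximizing signed r, in seconds, and
    the peak r. If ``b(t) = a(t - d)`` (a leads by d) the returned lag is -d.
    """
    if not np.isclose(a.fs, b.fs):
        raise AlignmentError(f"fs mismatch: {a.fs} vs {b.fs}")
    if a.n != b.n:
        raise AlignmentError(f"length mismatch: {a.n} vs {b.n}")
    m = int(round(max_lag * a.fs))
    if m < 1:
        raise ParameterError(f"max_lag of {max_lag} s covers no samples at {a.fs} Hz")
    lags, R = _pearson_at_lags(a.samples[None, :].astype(np.float64), b.samples, m)
    r = R[0]
    if not np.any(np.isfinite(r)):
        raise DegenerateDataError("cross-correlation undefined (constant input)")
    j = int(np.nanargmax(r))
    return lags[j] / a.fs, float(r[j])


def lag_map(
    stack: WidefieldStack,
    trace: Trace,
    max_lag: float = 2.0,
    r_threshold: float = 0.5,
) -> LagMap:
    """Per-pixel cross-correlation lag map against the photometry trace.

    For each masked pixel the lag maximizing the signed Pearson
    cross-correlation (within ``+/- max_lag`` seconds, integer frames) is
    reported; pixels whose peak correlation is below ``r_threshold`` are
    marked invalid and rendered gray downstream.
    """
    _check_aligned(stack, trace)
    m = int(round(max_lag * stack.fs))
    if m < 1:
        raise ParameterError(
            f"max_lag of {max_lag} s covers no frames at {stack.fs} Hz"
        )
    X = stack.masked_pixels()
    if X.dtype not in (np.float32, np.float64):
        X = X.astype(np.float32)
    lags, R = _pearson_at_lags(X, trace.samples, m)
    finite = np.isfinite(R)
    R_safe = np.where(finite, R, -np.inf)
    j = np.argmax(R_safe, axis=1)
    peak = R_safe[np.arange(R.shape[0]), j]
    ok = np.isfinite(peak)
    lag_s = lags[j] / stack.fs
    lag_img = np.full(stack.mask.shape, np.nan)
    peak_img = np.full(stack.mask.shape, np.nan)
    valid_img = np.zeros(stack.mask.shape, dtype=bool)
    lag_img[stack.mask] = np.where(ok, lag_s, np.nan)
    peak_img[stack.mask] = np.where(ok, peak, np.nan)
    valid_img[stack.mask] = ok & (peak >= r_threshold)
    return LagMap(
        lags=lag_img,
        peak_r=peak_img,
        valid=valid_img,
        mask=stack.mask,
        r_threshold=r_threshold,
        max_lag=max_lag,
    )
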