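"""Widefield cortical movie preprocessing.

Turns a raw H x W x T fluorescence stack into a filtered dF/F stack and a
global cortical trace. The pipeline order is fixed: stimulation-artifact
removal on the raw data (when artifact frames are supplied), then per-pixel
dF/F against a 10-s moving-average baseline, then spatial smoothing with a
3-pixel disc, then the same zero-phase 0.1-12 Hz Chebyshev band-pass that is
applied to the photometry trace. Non-cortical (unmasked) pixels are carried
as zeros and excluded from every statistic.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal

from mesophot.core import (
    BoundaryError,
    NumericalDomainError,
    ParameterError,
    Trace,
    WidefieldStack,
    moving_mean,
)
from mesophot.photometry import _bandpass_sos

# Row-block size for chunked per-pixel temporal operations; bounds peak memory
# on long sessions (a 64 x 64 x 24000 float32 stack is ~400 MB; float64
# temporaries for the full stack would not fit comfortably).
_CHUNK_ROWS = 8


def stack_dff(
    stack: WidefieldStack, window_s: float = 10.0, divide: bool = True
) -> WidefieldStack:
    """Per-pixel dF/F with a moving-average baseline (default 10 s).

    Semantics per pixel match :func:`mesophot.photometry.moving_avg_dff`;
    unmasked pixels are set to zero. Raises
    :class:`~mesophot.core.NumericalDomainError` naming the first offending
    pixel if the baseline is not strictly positive at a masked pixel.
    """
    n = int(round(window_s * stack.fs))
    if n < 1:
        raise ParameterError(
            f"window of {window_s} s covers no frames at fs={stack.fs} Hz"
        )
    frames = stack.frames
    out = np.zeros_like(frames, dtype=np.float32)
    H = frames.shape[0]
    for r0 in range(0, H, _CHUNK_ROWS):
        r1 = min(r0 + _CHUNK_ROWS, H)
        block = frames[r0:r1].astype(np.float64, copy=False)
        f0 = moving_mean(block, n, axis=-1)
        m = stack.mask[r0:r1]
        if divide:
            bad = (f0 <= 0) & m[..., None]
            if bad.any():
                i, j, t = np.argwhere(bad)[0]
                raise NumericalDomainError(
                    f"baseline F0 <= 0 at masked pixel ({i + r0}, {j}), frame {t}"
                )
            d = (block - f0) / f0
        else:
            d = block - f0
        d[~m] = 0.0
        out[r0:r1] = d.astype(np.float32)
    return stack.with_frames(out)


def _disc_kernel(diameter_px: int) -> np.ndarray:
    if diameter_px < 1 or diameter_px % 2 == 0:
        raise ParameterError(f"disc diameter must be odd and >= 1, got {diameter_px}")
    r = diameter_px // 2
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    k = (np.hypot(yy, xx) <= diameter_px / 2).astype(np.float64)
    return k / k.sum()


def spatial_disc_smooth(stack: WidefieldStack, diameter_px: int = 3) -> WidefieldStack:
    """Per-frame smoothing with a normalized moving disc (default diameter 3 px).

    The footprint contains every pixel whose center lies within diameter/2 of
    the kernel center; for diameter 3 that is the full 3x3 neighborhood
    (diagonal distance sqrt(2) <= 1.5). Edges use reflected padding, so a
    constant frame is left unchanged and spatial mass is approximately
    preserved.
    """
    kernel = _disc_kernel(diameter_px)[:, :, None]
    out = np.empty_like(stack.frames, dtype=np.float32)
    ndimage.convolve(
        stack.frames.astype(np.float32, copy=False), kernel.astype(np.float32),
        output=out, mode="reflect",
    )
    return stack.with_frames(out)


def stack_bandpass(
    stack: WidefieldStack, low: float = 0.1, high: float = 12.0
) -> WidefieldStack:
    """Zero-phase Chebyshev I band-pass (order 2, 0.5 dB) along time, per pixel.

    Identical filter and application as the photometry path so that filtering
    introduces no relative lag between modalities. Unmasked pixels are zeroed.
    """
    sos = _bandpass_sos(low, high, stack.fs)
    frames = stack.frames
    out = np.zeros_like(frames, dtype=np.float32)
    H = frames.shape[0]
    for r0 in range(0, H, _CHUNK_ROWS):
        r1 = min(r0 + _CHUNK_ROWS, H)
        y = signal.sosfiltfilt(sos, frames[r0:r1].astype(np.float64, copy=False), axis=-1)
        y[~stack.mask[r0:r1]] = 0.0
        out[r0:r1] = y.astype(np.float32)
    return stack.with_frames(out)


def _artifact_runs(artifact_frames: np.ndarray, pad: int, n_frames: int) -> list:
    """Contiguous artifact runs, extended by ``pad`` frames on each side."""
    idx = np.unique(np.asarray(artifact_frames, dtype=int))
    if idx.size == 0:
        return []
    if idx.min() < 0 or idx.max() >= n_frames:
        raise ParameterError("artifact frames must lie inside the recording")
    runs = []
    start = prev = idx[0]
    for k in idx[1:]:
        if k == prev + 1:
            prev = k
            continue
        runs.append((start, prev))
        start = prev = k
    runs.append((start, prev))
    padded = [(s - pad, e + pad) for s, e in runs]
    # merge runs that overlap after padding
    merged = []
    for s, e in padded:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def remove_stim_artifact(
    stack: WidefieldStack, artifact_frames, pad: int = 1
) -> WidefieldStack:
    """Replace stimulation-artifact frames by per-pixel linear interpolation.

    Each contiguous artifact run, extended by ``pad`` frames on both sides, is
    replaced by the line joining the nearest clean frames. Must run on the raw
    (pre-dF/F) data. A run touching either end of the recording has no clean
    anchor and raises :class:`~mesophot.core.BoundaryError`.
    """
    runs = _artifact_runs(artifact_frames, pad, stack.n_frames)
    if not runs:
        return stack.with_frames(stack.frames.copy())
    frames = stack.frames.copy()
    T = stack.n_frames
    for s, e in runs:
        if s - 1 < 0 or e + 1 >= T:
            raise BoundaryError(
                f"artifact run [{s}, {e}] touches the recording boundary; "
                "no clean frames to interpolate from"
            )
        a = frames[:, :, s - 1]
        b = frames[:, :, e + 1]
        w = (np.arange(s, e + 1) - (s - 1)) / (e + 2 - s)  # in (0, 1)
        frames[:, :, s : e + 1] = (
            a[..., None] * (1 - w) + b[..., None] * w
        ).astype(frames.dtype)
    return stack.with_frames(frames)


def global_signal(stack: WidefieldStack) -> Trace:
    """Global cortical activity: the per-frame spatial mean over masked pixels."""
    g = stack.frames[stack.mask].mean(axis=0, dtype=np.float64)
    return Trace(g, fs=stack.fs, t0=stack.t0)
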