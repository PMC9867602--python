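"""Shared containers and error types.

The two in-memory primitives are :class:`Trace` (a regularly sampled 1-D
signal, e.g. a fiber-photometry channel or the global cortical signal) and
:class:`WidefieldStack` (an H x W x T cortical movie with a binary cortical
mask). Both carry their sample rate so downstream operations can reconcile
the photometry clock (~1 kHz) with the widefield frame clock (40 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np


class MesophotError(Exception):
    """Base class for all package errors."""


class ParameterError(MesophotError, ValueError):
    """An argument is outside its documented domain."""


class AlignmentError(MesophotError, ValueError):
    """Two signals that must share a time base do not."""


class BoundaryError(MesophotError, ValueError):
    """An operation would need samples outside the recording."""


class EmptyEpochError(MesophotError, ValueError):
    """No usable stimulus epochs could be extracted."""


class DegenerateDataError(MesophotError, ValueError):
    """A fit or control signal has no variance to work with."""


class NumericalDomainError(MesophotError, ArithmeticError):
    """A computed quantity left its valid numerical domain (e.g. F0 <= 0)."""


class FormatError(MesophotError, ValueError):
    """An input file does not match the expected on-disk format."""


def _as_float_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ParameterError(f"{name} must be 1-D, got shape {arr.shape}")
    return arr


@dataclass
class Trace:
    """A regularly sampled scalar time series.

    Parameters
    ----------
    samples:
        Fluorescence (or derived) values, one per sample.
    fs:
        Sampling rate in Hz. Must be positive.
    t0:
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = _as_float_vector(self.samples, "samples")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ParameterError(f"fs must be positive and finite, got {self.fs}")
        if self.samples.size < 2:
            raise ParameterError("a Trace needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("Trace samples must be finite")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return (self.n - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray, **kwargs) -> "Trace":
        """Copy of this trace with new sample values (same clock unless overridden)."""
        out = replace(self, samples=np.asarray(samples, dtype=np.float64), **kwargs)
        return out


@dataclass
class WidefieldStack:
    """A cortical movie: H x W x T frames plus frame rate and cortical mask.

    ``frames[i, j, t]`` is the fluorescence of pixel (i, j) at frame t.
    ``mask`` marks cortical pixels; non-cortical pixels are carried as zeros
    by the preprocessing operations and excluded from every statistic.
    """

    frames: np.ndarray
    fs: float
    mask: Optional[np.ndarray] = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ParameterError(
                f"frames must be H x W x T, got shape {self.frames.shape}"
            )
        if self.frames.shape[2] < 2:
            raise ParameterError("a stack needs at least 2 frames")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ParameterError(f"fs must be positive and finite, got {self.fs}")
        if self.mask is None:
            self.mask = np.ones(self.frames.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.frames.shape[:2]:
                raise ParameterError(
                    f"mask shape {self.mask.shape} does not match frame shape "
                    f"{self.frames.shape[:2]}"
                )
        if not self.mask.any():
            raise ParameterError("mask must contain at least one cortical pixel")

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    @property
    def frame_times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.fs

    def masked_pixels(self) -> np.ndarray:
        """Time series of cortical pixels as a (P, T) view-copy."""
        return self.frames[self.mask]

    def with_frames(self, frames: np.ndarray) -> "WidefieldStack":
        return replace(self, frames=frames)


@dataclass
class PhotometryRecording:
    """Paired photometry channels plus stimulus/task events.

    ``f465`` is the calcium-dependent channel, ``f405`` the calcium-insensitive
    isosbestic control used to fit baseline fluorescence. Events are
    ``(time_s, label)`` pairs from TTL timestamps.
    """

    f465: Trace
    f405: Trace
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.f465.n != self.f405.n:
            raise AlignmentError(
                f"channel lengths differ: 465 has {self.f465.n}, 405 has {self.f405.n}"
            )
        if not np.isclose(self.f465.fs, self.f405.fs):
            raise AlignmentError(
                f"channel rates differ: {self.f465.fs} vs {self.f405.fs} Hz"
            )
        t_end = self.f465.t0 + self.f465.duration
        for t, _label in self.events:
            if not (self.f465.t0 <= t <= t_end):
                raise ParameterError(
                    f"event at {t} s lies outside the recording [{self.f465.t0}, {t_end}] s"
                )

    @property
    def fs(self) -> float:
        return self.f465.fs

    @property
    def event_times(self) -> np.ndarray:
        return np.array([t for t, _ in self.events], dtype=np.float64)


def moving_mean(x: np.ndarray, n: int, axis: int = -1) -> np.ndarray:
    """Centered moving mean with a truncated (shrinking) window at the edges.

    The window covers ``n`` samples; at the recording edges it shrinks so the
    mean is defined at every sample (no NaN padding). Computed with cumulative
    sums so the cost is O(N) per series.
    """
    if n < 1:
        raise ParameterError(f"window must cover at least 1 sample, got {n}")
    x = np.moveaxis(np.asarray(x), axis, -1)
    N = x.shape[-1]
    left = (n - 1) // 2
    right = n // 2
    c = np.empty(x.shape[:-1] + (N + 1,), dtype=np.float64)
    c[..., 0] = 0.0
    np.cumsum(x, axis=-1, out=c[..., 1:])
    i = np.arange(N)
    lo = np.clip(i - left, 0, N)
    hi = np.clip(i + right + 1, 0, N)
    out = (c[..., hi] - c[..., lo]) / (hi - lo)
    return np.moveaxis(out, -1, axis)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two equal-length 1-D arrays (float64 path)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise AlignmentError(f"length mismatch: {x.shape} vs {y.shape}")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    if den == 0:
        return np.nan
    return float((xc @ yc) / den)
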