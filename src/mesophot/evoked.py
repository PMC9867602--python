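"""Stimulus-locked epoching, habituation, and activated-area statistics.

Epochs are cut around TTL event times with a 1-s pre-stimulus baseline by
default. Habituation is quantified by comparing the average of the first 10
evoked responses to the average of the last 10. The activated cortical area
is the count of pixels whose trial-averaged response exceeds the baseline
mean + 4 SD (baseline = the 1 s before stimulation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from mesophot.core import (
    EmptyEpochError,
    ParameterError,
    Trace,
    WidefieldStack,
    moving_mean,
)
from mesophot.photometry import zscore_trace


@dataclass
class EpochSet:
    """Stimulus-locked epochs.

    ``epochs`` is (n_trials, pre+post samples) for traces, or
    (n_trials, H, W, pre+post frames) for stacks. ``n_pre`` samples precede
    stimulus onset (the baseline window); the stimulus arrives at sample
    index ``n_pre``. Trials are ordered by time.
    """

    epochs: np.ndarray
    n_pre: int
    fs: float
    event_times: np.ndarray
    n_dropped: int = 0
    mask: Optional[np.ndarray] = None

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_post(self) -> int:
        return self.epochs.shape[-1] - self.n_pre

    def is_stack(self) -> bool:
        return self.epochs.ndim == 4


@dataclass
class EvokedSummary:
    """First-vs-last trial-block comparison for habituation analysis."""

    mean_first: np.ndarray
    mean_last: np.ndarray
    n: int
    amplitude_first: float
    amplitude_last: float
    activated_area_first: Optional[int] = None
    activated_area_last: Optional[int] = None


def extract_epochs(
    data: Trace | WidefieldStack,
    event_times,
    pre_s: float = 1.0,
    post_s: float = 2.0,
) -> EpochSet:
    """Cut one epoch per event, spanning [-pre_s, post_s) around each onset.

    Events whose window would extend past either end of the recording are
    dropped with a warning and counted in ``n_dropped``.
    """
    event_times = np.sort(np.asarray(event_times, dtype=np.float64))
    if isinstance(data, WidefieldStack):
        fs, t0, N = data.fs, data.t0, data.n_frames
        series = data.frames
        mask = data.mask
    else:
        fs, t0, N = data.fs, data.t0, data.n
        series = data.samples
        mask = None
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    if n_pre + n_post < 1:
        raise ParameterError("epoch window covers no samples")
    starts = []
    kept_times = []
    dropped = 0
    for t in event_times:
        i = int(round((t - t0) * fs))
        if i - n_pre < 0 or i + n_post > N:
            dropped += 1
            continue
        starts.append(i - n_pre)
        kept_times.append(t)
    if dropped:
        warnings.warn(
            f"dropped {dropped} event(s) whose epoch window exceeded the recording",
            RuntimeWarning,
        )
    if not starts:
        raise EmptyEpochError("no event window fits inside the recording")
    win = n_pre + n_post
    epochs = np.stack([series[..., s : s + win] for s in starts], axis=0)
    return EpochSet(
        epochs=epochs,
        n_pre=n_pre,
        fs=fs,
        event_times=np.asarray(kept_times),
        n_dropped=dropped,
        mask=mask,
    )


def baseline_normalize(epochs: EpochSet) -> EpochSet:
    """Subtract each epoch's own pre-stimulus mean (per pixel for stacks)."""
    if epochs.n_pre < 1:
        raise ParameterError("no pre-stimulus samples to normalize against")
    base = epochs.epochs[..., : epochs.n_pre].mean(axis=-1, keepdims=True)
    return EpochSet(
        epochs=epochs.epochs - base,
        n_pre=epochs.n_pre,
        fs=epochs.fs,
        event_times=epochs.event_times,
        n_dropped=epochs.n_dropped,
        mask=epochs.mask,
    )


def _peak_amplitude(mean_epoch: np.ndarray, n_pre: int, mask=None) -> float:
    """Peak post-stimulus deviation of a trial-averaged epoch from its baseline."""
    base = mean_epoch[..., :n_pre].mean(axis=-1, keepdims=True)
    post = mean_epoch[..., n_pre:] - base
    if mask is not None and post.ndim == 3:
        post = post[mask]
    return float(post.max())


def trial_average_first_last(
    epochs: EpochSet, n: int = 10, threshold_sd: float = 4.0
) -> EvokedSummary:
    """Average the first n and last n trials and compare their responses.

    Peak amplitudes are measured after subtracting each block's 1-s (pre-window)
    baseline. For stack epochs the activated area of each block average is also
    reported (pixels above baseline mean + ``threshold_sd`` * SD).
    """
    if epochs.n_trials < 2 * n:
        raise ParameterError(
            f"need at least {2 * n} trials for first/last {n}, got {epochs.n_trials}"
        )
    mean_first = epochs.epochs[:n].mean(axis=0)
    mean_last = epochs.epochs[-n:].mean(axis=0)
    amp_first = _peak_amplitude(mean_first, epochs.n_pre, epochs.mask)
    amp_last = _peak_amplitude(mean_last, epochs.n_pre, epochs.mask)
    area_first = area_last = None
    if epochs.is_stack():
        area_first = activated_area(
            mean_first, epochs.n_pre, mask=epochs.mask, threshold_sd=threshold_sd
        )
        area_last = activated_area(
            mean_last, epochs.n_pre, mask=epochs.mask, threshold_sd=threshold_sd
        )
    return EvokedSummary(
        mean_first=mean_first,
        mean_last=mean_last,
        n=n,
        amplitude_first=amp_first,
        amplitude_last=amp_last,
        activated_area_first=area_first,
        activated_area_last=area_last,
    )


def activated_area(
    avg_epoch_stack: np.ndarray,
    n_baseline: int,
    mask: Optional[np.ndarray] = None,
    threshold_sd: float = 4.0,
    mode: str = "peak",
) -> int:
    """Count pixels whose evoked response exceeds baseline mean + 4 SD.

    ``avg_epoch_stack`` is a trial-averaged H x W x F epoch whose first
    ``n_baseline`` frames are the pre-stimulus baseline. Baseline mean and SD
    are per pixel; a pixel with zero baseline variance falls back to the
    global baseline SD (flagged via a warning). ``mode="peak"`` thresholds the
    post-stimulus peak per pixel; ``mode="any"`` counts a pixel if any
    post-stimulus frame exceeds threshold (equivalent for this statistic, kept
    for clarity of intent).
    """
    stack = np.asarray(avg_epoch_stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ParameterError("avg_epoch_stack must be H x W x frames")
    if n_baseline < 1 or n_baseline >= stack.shape[-1]:
        raise ParameterError("baseline window must be non-empty and leave post frames")
    if mode not in ("peak", "any"):
        raise ParameterError(f"unknown mode {mode!r}")
    if mask is None:
        mask = np.ones(stack.shape[:2], dtype=bool)
    base = stack[..., :n_baseline]
    mu = base.mean(axis=-1)
    sd = base.std(axis=-1)
    flat = (sd == 0) & mask
    if flat.any():
        global_sd = base[mask].std()
        warnings.warn(
            f"{int(flat.sum())} masked pixel(s) had zero baseline variance; "
            "using the global baseline SD for them",
            RuntimeWarning,
        )
        sd = np.where(flat, global_sd, sd)
    post = stack[..., n_baseline:]
    exceed = post.max(axis=-1) if mode == "peak" else np.any(
        post > (mu + threshold_sd * sd)[..., None], axis=-1
    )
    if mode == "peak":
        hits = exceed > mu + threshold_sd * sd
    else:
        hits = exceed
    return int(np.count_nonzero(hits & mask))


def behavior_preproc(motion: Trace, window_s: float = 1.0) -> Trace:
    """Condition a FaceMap-style motion trace: 1-s moving average, then z-score."""
    n = int(round(window_s * motion.fs))
    if n < 1:
        raise ParameterError(
            f"window of {window_s} s covers no samples at fs={motion.fs} Hz"
        )
    smoothed = motion.with_samples(moving_mean(motion.samples, n))
    return zscore_trace(smoothed)
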