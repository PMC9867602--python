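"""Synthetic corticostriatal sessions with ground truth.

Emulates the recording regime the analysis expects: a 40-Hz widefield cortical
movie built from planted spatiotemporal motifs (one travelling
anterior-to-posterior "butterfly" sensorimotor pattern and one spatially
disjoint ALM/visual pattern), a ~1-kHz striatal photometry pair whose 465-nm
channel is coupled to chosen motifs with a fixed delay through a 1-s
exponential-decay transient kernel (GCaMP6s-like), a slow sinusoidal baseline
drift shared between the 465 and 405 channels (so the isosbestic fit has
something real to remove), additive Gaussian noise, and an optional
40-stimulus train at 10-s ISI with per-trial geometric habituation and a
one-frame stimulation artifact.

All randomness flows from one seeded generator, split into per-component
sub-streams in a fixed order, so changing the noise of one component never
perturbs another and identical configurations are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from mesophot.core import ParameterError, PhotometryRecording, Trace, WidefieldStack

#: Decay constant (s) of the photometry transient kernel; approximates GCaMP6s
#: off-kinetics. Configurable via SceneConfig.kernel_tau_s.
DEFAULT_KERNEL_TAU_S = 1.0


@dataclass
class MotifSpec:
    """One planted motif: template id, length (frames), rate (events/s), amplitude."""

    template: str = "ap_wave"
    length: int = 40
    rate: float = 0.2
    amplitude: float = 5.0


@dataclass
class PhotometryCoupling:
    """Couples motif ``motif``'s event train into the 465 channel.

    ``delay_ms`` is the corticostriatal delay: each cortical motif onset adds a
    photometry transient ``delay_ms`` later, scaled by ``weight``.
    """

    motif: int = 0
    weight: float = 5.0
    delay_ms: float = 300.0


@dataclass
class StimulusSpec:
    """A periodic sensory-stimulation block (tones or LED flashes).

    ``habituation_decay`` scales trial i's response by decay**i (geometric
    habituation); ``artifact_amplitude`` adds a one-frame full-field spike at
    each stimulus frame for artifact-removal tests.
    """

    n_stimuli: int = 40
    isi_s: float = 10.0
    habituation_decay: float = 1.0
    amplitude: float = 5.0
    artifact_amplitude: float = 0.0
    onset_s: float = 5.0
    response_duration_s: float = 1.0
    photometry_weight: float = 5.0
    photometry_delay_ms: float = 0.0
    response_template: Optional[np.ndarray] = None  # H x W x F, overrides default


@dataclass
class SceneConfig:
    """Full parameterization of a synthetic session."""

    height: int = 64
    width: int = 64
    duration: float = 1200.0
    fs_widefield: float = 40.0
    fs_photometry: float = 1000.0
    motif_specs: list = field(
        default_factory=lambda: [MotifSpec("ap_wave"), MotifSpec("alm_visual")]
    )
    photometry_couplings: list = field(
        default_factory=lambda: [PhotometryCoupling(motif=0)]
    )
    baseline_level: float = 100.0
    drift_amplitude: float = 0.02
    drift_timescale: float = 120.0
    noise_sd_widefield: float = 1.0
    noise_sd_photometry: float = 0.5
    kernel_tau_s: float = DEFAULT_KERNEL_TAU_S
    uncoupled_photometry_sd: float = 0.0
    stimulus: Optional[StimulusSpec] = None
    seed: int = 0

    def validate(self) -> None:
        if self.height < 4 or self.width < 4:
            raise ParameterError("grid must be at least 4 x 4")
        if self.duration <= 0:
            raise ParameterError("duration must be positive")
        if self.fs_widefield <= 0 or self.fs_photometry < self.fs_widefield:
            raise ParameterError(
                "need fs_photometry >= fs_widefield > 0 "
                f"(got {self.fs_photometry}, {self.fs_widefield})"
            )
        for s in self.motif_specs:
            if s.length < 1:
                raise ParameterError(f"motif length must be >= 1, got {s.length}")
            if s.rate < 0 or s.amplitude < 0:
                raise ParameterError("motif rate and amplitude must be nonnegative")
        for c in self.photometry_couplings:
            if not 0 <= c.motif < len(self.motif_specs):
                raise ParameterError(f"coupling refers to unknown motif {c.motif}")
            if not np.isfinite(c.delay_ms):
                raise ParameterError("coupling delay must be finite")
        for name in (
            "baseline_level",
            "drift_amplitude",
            "drift_timescale",
            "noise_sd_widefield",
            "noise_sd_photometry",
            "kernel_tau_s",
            "uncoupled_photometry_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        if self.stimulus is not None:
            st = self.stimulus
            if st.n_stimuli < 1 or st.isi_s <= 0:
                raise ParameterError("stimulus block needs n_stimuli >= 1, isi > 0")
            if st.habituation_decay < 0:
                raise ParameterError("habituation_decay must be nonnegative")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fs_widefield))

    @property
    def n_photometry(self) -> int:
        return int(round(self.duration * self.fs_photometry))


@dataclass
class GroundTruth:
    """Planted truths for parameter-recovery tests."""

    motif_templates: list
    motif_loadings: np.ndarray  # K x T at fs_widefield, nonnegative event trains
    coupling_delays_ms: list
    mask: np.ndarray
    habituation_factors: Optional[np.ndarray] = None
    stimulus_times: Optional[np.ndarray] = None


def default_mask(height: int, width: int) -> np.ndarray:
    """A squircle covering the dorsal-cortex field of view (~85% of pixels)."""
    cy, cx = (height - 1) / 2, (width - 1) / 2
    yy, xx = np.mgrid[0:height, 0:width]
    a, b = height / 2 - 0.5, width / 2 - 0.5
    return ((np.abs(yy - cy) / a) ** 6 + (np.abs(xx - cx) / b) ** 6) <= 1.0


def _blob(h: int, w: int, cy: float, cx: float, radius: float, sigma: float):
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy - cy) ** 2.0 + (xx - cx) ** 2.0
    g = np.exp(-d2 / (2 * sigma**2))
    g[d2 > radius**2] = 0.0
    return g


def _ap_wave_template(h: int, w: int, L: int, amplitude: float) -> np.ndarray:
    """Bilateral sensorimotor blobs travelling anterior (top) to posterior."""
    r = 0.07 * min(h, w)
    sigma = r / 1.5
    y0, y1 = 0.25 * h, 0.72 * h
    xs = (0.28 * w, 0.72 * w)
    out = np.zeros((h, w, L))
    for l in range(L):
        cy = y0 if L == 1 else y0 + (y1 - y0) * l / (L - 1)
        frame = np.zeros((h, w))
        for cx in xs:
            frame += _blob(h, w, cy, cx, r, sigma)
        out[:, :, l] = frame
    peak = out.max()
    if peak > 0:
        out *= amplitude / peak
    return out


def _alm_visual_template(h: int, w: int, L: int, amplitude: float) -> np.ndarray:
    """Anterolateral motor (ALM) plus visual-cortex blobs, spatially disjoint
    from the sensorimotor wave, with a half-sine temporal envelope."""
    r_alm = 0.05 * min(h, w)
    r_vis = 0.07 * min(h, w)
    spatial = (
        _blob(h, w, 0.15 * h, 0.14 * w, r_alm, r_alm / 1.5)
        + _blob(h, w, 0.15 * h, 0.86 * w, r_alm, r_alm / 1.5)
        + _blob(h, w, 0.88 * h, 0.50 * w, r_vis, r_vis / 1.5)
    )
    env = np.sin(np.pi * (np.arange(L) + 0.5) / L)
    out = spatial[:, :, None] * env[None, None, :]
    peak = out.max()
    if peak > 0:
        out *= amplitude / peak
    return out


_TEMPLATES = {"ap_wave": _ap_wave_template, "alm_visual": _alm_visual_template}


def generate_motif_templates(config: SceneConfig) -> list:
    """Render each configured motif spec to a nonnegative H x W x L stack.

    The registry provides "ap_wave" (a travelling bilateral blob whose centroid
    moves strictly anterior to posterior) and "alm_visual" (static ALM and
    visual-cortex blobs, spatially disjoint from the wave). Template maxima
    equal the configured amplitudes.
    """
    config.validate()
    out = []
    for spec in config.motif_specs:
        try:
            fn = _TEMPLATES[spec.template]
        except KeyError:
            raise ParameterError(
                f"unknown template id {spec.template!r}; "
                f"known: {sorted(_TEMPLATES)}"
            ) from None
        out.append(fn(config.height, config.width, spec.length, spec.amplitude))
    return out


def exponential_kernel(tau_s: float, fs: float, n_tau: float = 5.0) -> np.ndarray:
    """Causal single-exponential decay kernel, peak 1 at t = 0."""
    n = max(int(round(n_tau * tau_s * fs)), 1)
    return np.exp(-np.arange(n) / (tau_s * fs))


def _event_train(rng: np.random.Generator, T: int, L: int, rate: float, fs: float):
    """Homogeneous-Poisson event train thinned so instances never overlap.

    Events are unit spikes at motif onsets; a second event cannot start within
    L frames of the previous one, and every instance fits inside the recording.
    """
    h = np.zeros(T)
    draws = rng.random(T) < rate / fs
    last = -L
    for t in np.flatnonzero(draws):
        if t - last >= L and t + L <= T:
            h[t] = 1.0
            last = t
    return h


def _drift(n: int, fs: float, config: SceneConfig) -> np.ndarray:
    if config.drift_amplitude == 0:
        return np.zeros(n)
    t = np.arange(n) / fs
    return config.drift_amplitude * np.sin(2 * np.pi * t / config.drift_timescale)


def _base_session(config: SceneConfig):
    """Common machinery for spontaneous and evoked sessions."""
    config.validate()
    T = config.n_frames
    for spec in config.motif_specs:
        if spec.length > T:
            raise ParameterError(
                f"duration of {config.duration} s ({T} frames) cannot contain a "
                f"{spec.length}-frame motif"
            )
    H, W = config.height, config.width
    rng = np.random.default_rng(config.seed)
    rng_load, rng_wf, rng_465, rng_405, rng_unc = rng.spawn(5)

    templates = generate_motif_templates(config)
    K = len(templates)
    loadings = np.zeros((K, T))
    for k, spec in enumerate(config.motif_specs):
        loadings[k] = _event_train(rng_load, T, spec.length, spec.rate, config.fs_widefield)

    drift_w = _drift(T, config.fs_widefield, config)
    frames = np.empty((H, W, T), dtype=np.float32)
    frames[:] = (config.baseline_level * (1.0 + drift_w)).astype(np.float32)
    for k, tpl in enumerate(templates):
        tpl32 = tpl.astype(np.float32)
        Lk = tpl.shape[2]
        for t in np.flatnonzero(loadings[k]):
            frames[:, :, t : t + Lk] += tpl32
    if config.noise_sd_widefield > 0:
        frames += config.noise_sd_widefield * rng_wf.standard_normal(
            (H, W, T), dtype=np.float32
        )

    # photometry channels at fs_photometry
    Tp = config.n_photometry
    drift_p = config.baseline_level * _drift(Tp, config.fs_photometry, config)
    kern = exponential_kernel(config.kernel_tau_s, config.fs_photometry)
    signal = np.zeros(Tp)
    for c in config.photometry_couplings:
        for t in np.flatnonzero(loadings[c.motif]):
            t_s = t / config.fs_widefield + c.delay_ms / 1000.0
            i0 = int(round(t_s * config.fs_photometry))
            if i0 >= Tp:
                continue
            seg = kern[: Tp - i0] if i0 >= 0 else kern[-i0 : Tp - i0]
            start = max(i0, 0)
            signal[start : start + seg.size] += c.weight * seg
    f465 = config.baseline_level + drift_p + signal
    f405 = config.baseline_level + drift_p.copy()
    if config.uncoupled_photometry_sd > 0:
        # optional striatal component not derived from cortex (e.g. thalamic);
        # smoothed noise with ~1 s autocorrelation
        raw = rng_unc.standard_normal(Tp)
        k1 = exponential_kernel(1.0, config.fs_photometry)
        unc = np.convolve(raw, k1)[:Tp]
        unc *= config.uncoupled_photometry_sd / max(unc.std(), 1e-12)
        f465 = f465 + unc
    if config.noise_sd_photometry > 0:
        f465 = f465 + config.noise_sd_photometry * rng_465.standard_normal(Tp)
        f405 = f405 + config.noise_sd_photometry * rng_405.standard_normal(Tp)

    mask = default_mask(H, W)
    truth = GroundTruth(
        motif_templates=templates,
        motif_loadings=loadings,
        coupling_delays_ms=[c.delay_ms for c in config.photometry_couplings],
        mask=mask,
    )
    return frames, f465, f405, mask, truth


def generate_spontaneous_session(config: SceneConfig):
    """A resting-state session: motifs, coupled photometry, drift, noise.

    Returns ``(WidefieldStack, PhotometryRecording, GroundTruth)``. The stack
    is ``baseline * (1 + drift) + sum_k template_k (*) loading_k + noise``; the
    465 channel is baseline + coupled delayed transients + shared drift +
    noise; the 405 channel is baseline + shared drift + independent noise
    (calcium-insensitive). Identical configs (including seed) produce
    bit-identical output.
    """
    if config.stimulus is not None:
        raise ParameterError(
            "config has a stimulus block; use generate_evoked_session"
        )
    frames, f465, f405, mask, truth = _base_session(config)
    stack = WidefieldStack(frames, fs=config.fs_widefield, mask=mask)
    rec = PhotometryRecording(
        Trace(f465, fs=config.fs_photometry),
        Trace(f405, fs=config.fs_photometry),
        events=[],
    )
    return stack, rec, truth


def default_response_template(
    h: int, w: int, n_frames: int, amplitude: float
) -> np.ndarray:
    """Elliptical sensory-evoked response: ~50-pixel footprint at 64 x 64,
    fast rise and exponential decay."""
    cy, cx = 0.45 * h, 0.32 * w
    ry, rx = 0.078 * h, 0.047 * w
    yy, xx = np.mgrid[0:h, 0:w]
    footprint = (((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2) <= 1.0
    t = np.arange(n_frames)
    n_rise = max(int(round(0.1 * n_frames)), 1)
    env = np.where(
        t < n_rise, (t + 1) / n_rise, np.exp(-(t - n_rise) / (0.35 * n_frames))
    )
    return amplitude * footprint[:, :, None] * env[None, None, :]


def generate_evoked_session(config: SceneConfig):
    """A sensory-stimulation session with habituating evoked responses.

    At each stimulus time the response template, scaled by
    ``habituation_decay**trial``, is added to the stack, a matching transient
    (delayed by ``photometry_delay_ms``) is added to the 465 channel, and
    optionally a one-frame full-field artifact spike is planted at the
    stimulus frame. Stimulus times are recorded in the ground truth and in the
    photometry event table.
    """
    if config.stimulus is None:
        raise ParameterError("config has no stimulus block")
    st = config.stimulus
    stim_times = st.onset_s + st.isi_s * np.arange(st.n_stimuli)
    if stim_times[-1] + st.response_duration_s > config.duration:
        raise ParameterError(
            f"{st.n_stimuli} stimuli at {st.isi_s}-s ISI (last at "
            f"{stim_times[-1]:.1f} s) exceed the {config.duration}-s session"
        )
    frames, f465, f405, mask, truth = _base_session(config)
    fs_w, fs_p = config.fs_widefield, config.fs_photometry
    T, Tp = config.n_frames, config.n_photometry
    nF = max(int(round(st.response_duration_s * fs_w)), 1)
    if st.response_template is not None:
        resp = np.asarray(st.response_template, dtype=np.float64)
        if resp.shape[:2] != (config.height, config.width):
            raise ParameterError("response template spatial shape mismatch")
        nF = resp.shape[2]
    else:
        resp = default_response_template(config.height, config.width, nF, st.amplitude)
    resp32 = resp.astype(np.float32)
    factors = st.habituation_decay ** np.arange(st.n_stimuli)
    kern = exponential_kernel(config.kernel_tau_s, fs_p)
    for i, t_s in enumerate(stim_times):
        f0 = int(round(t_s * fs_w))
        if f0 + nF > T:
            raise ParameterError("response window exceeds the recording")
        frames[:, :, f0 : f0 + nF] += np.float32(factors[i]) * resp32
        if st.artifact_amplitude != 0:
            frames[:, :, f0] += np.float32(st.artifact_amplitude)
        i0 = int(round((t_s + st.photometry_delay_ms / 1000.0) * fs_p))
        if i0 < Tp:
            seg = kern[: Tp - i0]
            f465[i0 : i0 + seg.size] += factors[i] * st.photometry_weight * seg
    truth.habituation_factors = factors
    truth.stimulus_times = stim_times
    stack = WidefieldStack(frames, fs=fs_w, mask=mask)
    rec = PhotometryRecording(
        Trace(f465, fs=fs_p),
        Trace(f405, fs=fs_p),
        events=[(float(t), "stim") for t in stim_times],
    )
    return stack, rec, truth
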