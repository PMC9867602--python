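"""Session orchestration: configuration, staging, and reporting.

Ties the stages into one pipeline: photometry and widefield preprocessing,
correlation / partial-correlation / lag maps, motif discovery with
motif-photometry cross-correlation, and (when events are present) evoked
analysis. Every tunable the analysis uses (10-s dF/F window, 3-px disc,
0.1-12 Hz band, order-8 anti-alias, L = 40 frames, r-threshold 0.5, 4-SD
activation threshold, first/last n = 10) is a named configuration key.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

import mesophot
from mesophot import io as mio
from mesophot import plotting
from mesophot.core import (
    AlignmentError,
    FormatError,
    PhotometryRecording,
    Trace,
    WidefieldStack,
)
from mesophot.evoked import extract_epochs, trial_average_first_last
from mesophot.maps import correlation_map, lag_map, partial_correlation_map
from mesophot.motifs import (
    motif_map_similarity,
    motif_photometry_xcorr,
    seqnmf_fit,
)
from mesophot.photometry import (
    bandpass_filter,
    isosbestic_dff,
    moving_avg_dff,
    resample_trace,
    zscore_trace,
)
from mesophot.synthetic import (
    MotifSpec,
    PhotometryCoupling,
    SceneConfig,
    StimulusSpec,
    generate_evoked_session,
    generate_spontaneous_session,
)
from mesophot.widefield import (
    global_signal,
    remove_stim_artifact,
    spatial_disc_smooth,
    stack_bandpass,
    stack_dff,
)

log = logging.getLogger("mesophot")

DEFAULT_CONFIG: dict = {
    "session": {"fs_widefield": 40.0},
    "photometry": {"method": "moving_average", "window_s": 10.0, "band": [0.1, 12.0]},
    "widefield": {
        "window_s": 10.0,
        "disc_diameter_px": 3,
        "band": [0.1, 12.0],
        "remove_artifacts": False,
        "artifact_pad_frames": 1,
    },
    "maps": {"max_lag_s": 2.0, "r_threshold": 0.5},
    "motifs": {"enabled": True, "K": 8, "L": 40, "lam": 1e-4, "n_iter": 100, "seed": 0},
    "evoked": {"pre_s": 1.0, "post_s": 2.0, "n_first_last": 10, "threshold_sd": 4.0},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: Optional[str] = None) -> dict:
    """Defaults, optionally overridden by a TOML file with per-stage tables."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path, "rb") as f:
        user = tomllib.load(f)
    return _deep_merge(DEFAULT_CONFIG, user)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def scene_from_config(table: dict) -> SceneConfig:
    """Build a SceneConfig from a ``[synthetic]`` TOML table."""
    t = dict(table)
    motifs = [MotifSpec(**m) for m in t.pop("motifs", [])]
    couplings = [PhotometryCoupling(**c) for c in t.pop("couplings", [])]
    stim = t.pop("stimulus", None)
    cfg = SceneConfig(**t)
    if motifs:
        cfg.motif_specs = motifs
    if couplings or motifs:
        cfg.photometry_couplings = couplings
    if stim is not None:
        cfg.stimulus = StimulusSpec(**stim)
    cfg.validate()
    return cfg


@dataclass
class SessionBundle:
    """One session's raw inputs plus resolved config and provenance."""

    stack: WidefieldStack
    photometry: PhotometryRecording
    behavior: Optional[object] = None
    config: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))
    provenance: list = field(default_factory=list)

    def record(self, stage: str, **params) -> None:
        self.provenance.append({"stage": stage, **params})


def save_synthetic_session(outdir, stack, rec, truth) -> None:
    """Write a generated session in the package's on-disk formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.save_stack_hdf5(outdir / "movie.h5", stack)
    mio.save_mask_tiff(outdir / "mask.tif", stack.mask)
    mio.save_photometry_csv(outdir / "photometry.csv", rec)
    mio.save_events_csv(outdir / "events.csv", rec.events)
    mio.save_ground_truth_hdf5(outdir / "ground_truth.h5", truth)


def load_session(paths: dict, config: Optional[dict] = None) -> SessionBundle:
    """Load and validate a session from a dict of file paths.

    ``paths`` keys: ``movie`` (HDF5 or multi-page TIFF), optional ``mask``
    (single-page TIFF), ``photometry`` (CSV), optional ``events`` (CSV),
    optional ``behavior`` (CSV). Events outside the recording are rejected
    with counts.
    """
    config = config or copy.deepcopy(DEFAULT_CONFIG)
    movie = Path(paths["movie"])
    mask = mio.load_mask_tiff(paths["mask"]) if paths.get("mask") else None
    if movie.suffix in (".h5", ".hdf5"):
        stack = mio.load_stack_hdf5(movie)
        if mask is not None:
            stack = WidefieldStack(stack.frames, fs=stack.fs, mask=mask, t0=stack.t0)
    elif movie.suffix in (".tif", ".tiff"):
        stack = mio.load_stack_tiff(
            movie, fs=float(config["session"]["fs_widefield"]), mask=mask
        )
    else:
        raise FormatError(f"unsupported movie format: {movie.suffix}")
    events = mio.load_events_csv(paths["events"]) if paths.get("events") else []
    rec = mio.load_photometry_csv(paths["photometry"])
    t_end = rec.f465.t0 + rec.f465.duration
    inside = [(t, l) for t, l in events if rec.f465.t0 <= t <= t_end]
    n_rejected = len(events) - len(inside)
    if n_rejected:
        log.warning("rejected %d event(s) outside the recording", n_rejected)
    rec = PhotometryRecording(rec.f465, rec.f405, events=inside)
    behavior = mio.load_behavior_csv(paths["behavior"]) if paths.get("behavior") else None
    bundle = SessionBundle(stack=stack, photometry=rec, behavior=behavior, config=config)
    bundle.record("load_session", n_events=len(inside), n_events_rejected=n_rejected)
    return bundle


# ------------------------------------------------------------------ stages

def preprocess_photometry(bundle: SessionBundle) -> Trace:
    """dF/F -> band-pass -> resample to the widefield clock -> z-score."""
    cfg = bundle.config["photometry"]
    rec = bundle.photometry
    if cfg["method"] == "isosbestic":
        dff = isosbestic_dff(rec.f465, rec.f405)
    else:
        dff = moving_avg_dff(rec.f465, window_s=cfg["window_s"])
    low, high = cfg["band"]
    filtered = bandpass_filter(dff, low, high)
    res = resample_trace(filtered, bundle.stack.fs)
    T = bundle.stack.n_frames
    if res.n < T or res.n > T + 1:
        raise AlignmentError(
            f"resampled photometry has {res.n} samples but the stack has {T} frames"
        )
    out = zscore_trace(Trace(res.samples[:T], fs=res.fs, t0=res.t0))
    bundle.record("preprocess_photometry", method=cfg["method"], band=[low, high])
    return out


def preprocess_widefield(bundle: SessionBundle) -> WidefieldStack:
    """(artifact removal) -> dF/F -> disc smooth -> band-pass, in that order."""
    cfg = bundle.config["widefield"]
    stack = bundle.stack
    if cfg["remove_artifacts"] and bundle.photometry.events:
        frames_idx = np.round(
            (bundle.photometry.event_times - stack.t0) * stack.fs
        ).astype(int)
        stack = remove_stim_artifact(stack, frames_idx, pad=cfg["artifact_pad_frames"])
        bundle.record("remove_stim_artifact", n_events=len(frames_idx))
    stack = stack_dff(stack, window_s=cfg["window_s"])
    stack = spatial_disc_smooth(stack, diameter_px=cfg["disc_diameter_px"])
    low, high = cfg["band"]
    stack = stack_bandpass(stack, low, high)
    bundle.record(
        "preprocess_widefield",
        order=["dff", "disc_smooth", "bandpass"],
        window_s=cfg["window_s"],
        disc_diameter_px=cfg["disc_diameter_px"],
        band=[low, high],
    )
    return stack


def compute_maps(bundle: SessionBundle, stack_proc, trace_proc):
    cfg = bundle.config["maps"]
    gsig = zscore_trace(global_signal(stack_proc))
    cmap = correlation_map(stack_proc, trace_proc)
    pmap = partial_correlation_map(stack_proc, trace_proc, gsig)
    lmap = lag_map(
        stack_proc,
        trace_proc,
        max_lag=cfg["max_lag_s"],
        r_threshold=cfg["r_threshold"],
    )
    bundle.record("maps", **cfg)
    return gsig, cmap, pmap, lmap


def compute_motifs(bundle: SessionBundle, stack_proc, trace_proc, cmap):
    cfg = bundle.config["motifs"]
    X = np.clip(stack_proc.masked_pixels(), 0, None)
    motifs = seqnmf_fit(
        X,
        K=cfg["K"],
        L=cfg["L"],
        lam=cfg["lam"],
        n_iter=cfg["n_iter"],
        seed=cfg["seed"],
        fs=stack_proc.fs,
        mask=stack_proc.mask,
    )
    xc = motif_photometry_xcorr(
        motifs, trace_proc, max_lag=bundle.config["maps"]["max_lag_s"]
    )
    sim = motif_map_similarity(motifs, cmap)
    bundle.record("motifs", **{k: v for k, v in cfg.items() if k != "enabled"})
    return motifs, xc, sim


def compute_evoked(bundle: SessionBundle, stack_proc, trace_proc):
    cfg = bundle.config["evoked"]
    times = bundle.photometry.event_times
    ep_stack = extract_epochs(stack_proc, times, pre_s=cfg["pre_s"], post_s=cfg["post_s"])
    ep_trace = extract_epochs(trace_proc, times, pre_s=cfg["pre_s"], post_s=cfg["post_s"])
    summary_stack = trial_average_first_last(
        ep_stack, n=cfg["n_first_last"], threshold_sd=cfg["threshold_sd"]
    )
    summary_trace = trial_average_first_last(ep_trace, n=cfg["n_first_last"])
    bundle.record("evoked", **cfg)
    return ep_stack, summary_stack, summary_trace


def run_full_pipeline(bundle: SessionBundle, outdir) -> dict:
    """Execute preprocessing -> maps -> motifs -> (evoked), write artifacts.

    Returns the machine-readable summary that is also written to
    ``summary.json``: mean lag over valid pixels, per-motif peaks / lags /
    similarities, and evoked summaries. Re-running with an identical bundle
    and config reproduces the summary bit-identically (the only stochastic
    stage, motif initialization, is seeded from the config).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log")
    log.addHandler(handler)
    summary: dict = {
        "config_hash": config_hash(bundle.config),
        "version": mesophot.__version__,
    }
    try:
        t_start = time.time()
        trace_proc = preprocess_photometry(bundle)
        stack_proc = preprocess_widefield(bundle)
        log.info("preprocessing done in %.1f s", time.time() - t_start)

        gsig, cmap, pmap, lmap = compute_maps(bundle, stack_proc, trace_proc)
        mio.save_maps_hdf5(
            outdir / "maps.h5",
            correlation=cmap.values,
            partial_correlation=pmap.values,
            lag_s=lmap.lags,
            lag_peak_r=lmap.peak_r,
            lag_valid=lmap.valid,
        )
        plotting.render_map_png(
            outdir / "correlation_map.png", cmap.values, valid=cmap.mask,
            title="full correlation", vmin=-1, vmax=1,
        )
        plotting.render_map_png(
            outdir / "partial_correlation_map.png", pmap.values, valid=pmap.mask,
            title="partial correlation", vmin=-1, vmax=1,
        )
        plotting.render_map_png(
            outdir / "lag_map.png", lmap.lags, valid=lmap.valid,
            title="lag (s), gray = r < 0.5", cmap="coolwarm",
        )
        valid_lags = lmap.lags[lmap.valid]
        summary["maps"] = {
            "n_valid_pixels": int(lmap.valid.sum()),
            "mean_valid_lag_s": float(valid_lags.mean()) if valid_lags.size else None,
            "median_valid_lag_s": float(np.median(valid_lags)) if valid_lags.size else None,
        }

        if bundle.config["motifs"]["enabled"]:
            motifs, xc, sim = compute_motifs(bundle, stack_proc, trace_proc, cmap)
            mio.save_motifs_hdf5(outdir / "motifs.h5", motifs)
            active = motifs.active()
            for k in range(motifs.K):
                if active[k]:
                    plotting.motif_montage_png(outdir / f"motif_{k}.png", motifs, k)
            summary["motifs"] = [
                {
                    "motif": r.motif,
                    "lag_s": None if r.degenerate else round(float(r.lag_s), 9),
                    "peak_r": None if r.degenerate else round(float(r.peak_r), 9),
                    "map_similarity": round(float(sim[r.motif]), 9),
                    "active": bool(active[r.motif]),
                }
                for r in xc
            ]

        if bundle.photometry.events:
            ep_stack, ev_stack, ev_trace = compute_evoked(bundle, stack_proc, trace_proc)
            summary["evoked"] = {
                "n_epochs": ep_stack.n_trials,
                "n_dropped": ep_stack.n_dropped,
                "stack": {
                    "amplitude_first": round(ev_stack.amplitude_first, 9),
                    "amplitude_last": round(ev_stack.amplitude_last, 9),
                    "activated_area_first": ev_stack.activated_area_first,
                    "activated_area_last": ev_stack.activated_area_last,
                },
                "trace": {
                    "amplitude_first": round(ev_trace.amplitude_first, 9),
                    "amplitude_last": round(ev_trace.amplitude_last, 9),
                },
            }
        else:
            log.info("no events in session; evoked stage skipped")
            summary["evoked"] = None

        summary["provenance"] = bundle.provenance
        mio.write_json(outdir / "summary.json", summary)
        log.info("pipeline finished in %.1f s", time.time() - t_start)
    except Exception as exc:  # annotate with the failing stage
        stage = bundle.provenance[-1]["stage"] if bundle.provenance else "start"
        raise type(exc)(f"[after stage {stage}] {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return summary
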