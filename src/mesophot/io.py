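"""File I/O: TIFF movies and masks, HDF5 stacks/maps/motifs, CSV traces/events.

On-disk conventions
-------------------
* movies: multi-page TIFF (pages = frames) or HDF5 dataset ``"stack"`` shaped
  H x W x T with attribute ``"fs_hz"`` (and a ``"mask"`` dataset);
* masks: single-page TIFF of 0/255 or 0/1;
* photometry: CSV with required header ``time_s,f465,f405``;
* events: CSV ``time_s,label``;
* behavior: CSV ``time_s,motion_roi,pupil_diameter``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from mesophot.core import (
    FormatError,
    PhotometryRecording,
    Trace,
    WidefieldStack,
)
from mesophot.synthetic import GroundTruth

PHOTOMETRY_HEADER = ["time_s", "f465", "f405"]
EVENTS_HEADER = ["time_s", "label"]
BEHAVIOR_HEADER = ["time_s", "motion_roi", "pupil_diameter"]


def _infer_fs(time_s: np.ndarray) -> float:
    dt = np.diff(time_s)
    if dt.size == 0 or np.any(dt <= 0):
        raise FormatError("time_s must be strictly increasing")
    return 1.0 / float(np.median(dt))


# ---------------------------------------------------------------- stacks

def save_stack_hdf5(path, stack: WidefieldStack) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("stack", data=stack.frames)
        d.attrs["fs_hz"] = stack.fs
        d.attrs["t0_s"] = stack.t0
        f.create_dataset("mask", data=stack.mask.astype(np.uint8))


def load_stack_hdf5(path) -> WidefieldStack:
    with h5py.File(path, "r") as f:
        if "stack" not in f:
            raise FormatError(f"{path}: expected an HDF5 dataset named 'stack'")
        d = f["stack"]
        if "fs_hz" not in d.attrs:
            raise FormatError(f"{path}: 'stack' is missing the 'fs_hz' attribute")
        frames = d[()]
        fs = float(d.attrs["fs_hz"])
        t0 = float(d.attrs.get("t0_s", 0.0))
        mask = f["mask"][()].astype(bool) if "mask" in f else None
    return WidefieldStack(frames, fs=fs, mask=mask, t0=t0)


def save_stack_tiff(path, stack: WidefieldStack) -> None:
    """Multi-page TIFF, one page per frame; fs stored in the software tag."""
    pages = np.moveaxis(stack.frames, -1, 0)
    tifffile.imwrite(path, pages, metadata={"fs_hz": stack.fs})


def load_stack_tiff(path, fs: float, mask=None) -> WidefieldStack:
    pages = tifffile.imread(path)
    if pages.ndim != 3:
        raise FormatError(f"{path}: expected a multi-page TIFF movie")
    return WidefieldStack(np.moveaxis(pages, 0, -1), fs=fs, mask=mask)


def save_mask_tiff(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, (mask.astype(np.uint8) * 255))


def load_mask_tiff(path) -> np.ndarray:
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise FormatError(f"{path}: mask must be a single-page TIFF")
    vals = np.unique(img)
    if not np.all(np.isin(vals, [0, 1, 255])):
        raise FormatError(f"{path}: mask must be binary 0/1 or 0/255, got {vals[:5]}")
    return img > 0


# ------------------------------------------------------------- photometry

def save_photometry_csv(path, rec: PhotometryRecording) -> None:
    df = pd.DataFrame(
        {
            "time_s": rec.f465.times,
            "f465": rec.f465.samples,
            "f405": rec.f405.samples,
        }
    )
    df.to_csv(path, index=False)


def load_photometry_csv(path, events=None) -> PhotometryRecording:
    df = pd.read_csv(path)
    if list(df.columns) != PHOTOMETRY_HEADER:
        raise FormatError(
            f"{path}: expected header {','.join(PHOTOMETRY_HEADER)!r}, "
            f"got {','.join(map(str, df.columns))!r}"
        )
    t = df["time_s"].to_numpy(dtype=np.float64)
    fs = _infer_fs(t)
    return PhotometryRecording(
        Trace(df["f465"].to_numpy(np.float64), fs=fs, t0=float(t[0])),
        Trace(df["f405"].to_numpy(np.float64), fs=fs, t0=float(t[0])),
        events=list(events) if events else [],
    )


def save_events_csv(path, events) -> None:
    pd.DataFrame(events, columns=EVENTS_HEADER).to_csv(path, index=False)


def load_events_csv(path) -> list:
    df = pd.read_csv(path)
    if list(df.columns) != EVENTS_HEADER:
        raise FormatError(
            f"{path}: expected header {','.join(EVENTS_HEADER)!r}, "
            f"got {','.join(map(str, df.columns))!r}"
        )
    return [(float(t), str(l)) for t, l in zip(df["time_s"], df["label"])]


def load_behavior_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != BEHAVIOR_HEADER:
        raise FormatError(
            f"{path}: expected header {','.join(BEHAVIOR_HEADER)!r}, "
            f"got {','.join(map(str, df.columns))!r}"
        )
    return df


# ------------------------------------------------------------ ground truth

def save_ground_truth_hdf5(path, truth: GroundTruth) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("templates")
        for k, tpl in enumerate(truth.motif_templates):
            g.create_dataset(str(k), data=tpl)
        f.create_dataset("loadings", data=truth.motif_loadings)
        f.create_dataset("coupling_delays_ms", data=np.asarray(truth.coupling_delays_ms))
        f.create_dataset("mask", data=truth.mask.astype(np.uint8))
        if truth.habituation_factors is not None:
            f.create_dataset("habituation_factors", data=truth.habituation_factors)
        if truth.stimulus_times is not None:
            f.create_dataset("stimulus_times", data=truth.stimulus_times)


def load_ground_truth_hdf5(path) -> GroundTruth:
    with h5py.File(path, "r") as f:
        templates = [f["templates"][k][()] for k in sorted(f["templates"], key=int)]
        kwargs = {}
        if "habituation_factors" in f:
            kwargs["habituation_factors"] = f["habituation_factors"][()]
        if "stimulus_times" in f:
            kwargs["stimulus_times"] = f["stimulus_times"][()]
        return GroundTruth(
            motif_templates=templates,
            motif_loadings=f["loadings"][()],
            coupling_delays_ms=list(f["coupling_delays_ms"][()]),
            mask=f["mask"][()].astype(bool),
            **kwargs,
        )


# ------------------------------------------------------------------ maps

def save_maps_hdf5(path, **named_images) -> None:
    """Write named 2-D images (correlation map values, lags, validity...)."""
    with h5py.File(path, "w") as f:
        for name, img in named_images.items():
            f.create_dataset(name, data=np.asarray(img))


def save_motifs_hdf5(path, motifs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=motifs.W)
        f.create_dataset("H", data=motifs.H)
        f.create_dataset("objective", data=motifs.objective_trace)
        if motifs.mask is not None:
            f.create_dataset("mask", data=motifs.mask.astype(np.uint8))
        f.attrs.update(L=motifs.L, lam=motifs.lam, seed=motifs.seed, fs=motifs.fs)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
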