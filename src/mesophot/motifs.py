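"""Convolutional (sequential) NMF motif discovery.

Decomposes a nonnegative pixels x time matrix X into K spatiotemporal motifs
W (P x K x L) and temporal loadings H (K x T) such that X is approximated by
the convolutional reconstruction

    Xhat[:, t] = sum_k sum_l W[:, k, l] * H[k, t - l].

Fitting uses multiplicative updates that are exact Lee-Seung steps on the
linearized problem (H update with W fixed, W update with H fixed), so at
lambda = 0 the Frobenius objective is non-increasing across iterations. A
cross-factor orthogonality penalty (weight ``lam``) discourages distinct
motifs from explaining the same data at nearby times: it penalizes

    lam * sum_{k != k'} [ (W (*) X) S H^T ]_{k k'}

where (W (*) X) is the transposed convolution of the data with the motifs and
S a temporal moving-sum of width 2L - 1.

The heavy lifting is two dense matrix products of size (P x T) x (K L) per
iteration, so fitting a 10-minute 64 x 64 session is feasible on one core.
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
)
from mesophot.maps import xcorr_lag, CorrelationMap
from mesophot.photometry import zscore_trace

_EPS = 1e-30


@dataclass
class MotifSet:
    """Result of a convolutional NMF fit.

    ``W`` is P x K x L (masked pixels, motifs, frames per motif), normalized so
    each motif's maximum is 1 with the scale absorbed into the loadings ``H``
    (K x T). ``objective_trace`` holds the penalized objective after each
    iteration (element 0 is the value at initialization).
    """

    W: np.ndarray
    H: np.ndarray
    L: int
    lam: float
    objective_trace: np.ndarray
    seed: int
    fs: float = 40.0
    mask: Optional[np.ndarray] = None

    @property
    def K(self) -> int:
        return self.W.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.W.shape[0]

    def loading_energy(self) -> np.ndarray:
        return (self.H**2).sum(axis=1)

    def active(self, rel_threshold: float = 1e-6) -> np.ndarray:
        """Motifs whose loading energy is at least ``rel_threshold`` of the max.

        Empty motifs stay in the set but are dropped from reports.
        """
        e = self.loading_energy()
        top = e.max()
        if top == 0:
            return np.zeros(self.K, dtype=bool)
        return e >= rel_threshold * top

    def max_projection(self) -> np.ndarray:
        """Per-motif temporal max-projection over the L frames: (P, K)."""
        return self.W.max(axis=2)


def _stack_loadings(H: np.ndarray, L: int) -> np.ndarray:
    """(K*L, T) matrix with row (k, l) holding H[k] delayed by l frames."""
    K, T = H.shape
    Hs = np.zeros((K, L, T), dtype=H.dtype)
    for l in range(L):
        Hs[:, l, l:] = H[:, : T - l]
    return Hs.reshape(K * L, T)


def _unstack_sum(C: np.ndarray, K: int, L: int, T: int) -> np.ndarray:
    """Transposed-convolution gather: out[k, t] = sum_l C[(k, l), t + l]."""
    C3 = C.reshape(K, L, T)
    out = np.zeros((K, T), dtype=C.dtype)
    for l in range(L):
        out[:, : T - l] += C3[:, l, l:]
    return out


def _moving_sum(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving sum of width n along the last axis, truncated at edges."""
    N = x.shape[-1]
    left = (n - 1) // 2
    c = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,), dtype=np.float64), np.cumsum(x, axis=-1)],
        axis=-1,
    )
    i = np.arange(N)
    lo = np.clip(i - left, 0, N)
    hi = np.clip(i + n // 2 + 1, 0, N)
    return (c[..., hi] - c[..., lo]).astype(x.dtype)


def seqnmf_fit(
    X: np.ndarray,
    K: int,
    L: int,
    lam: float = 0.0,
    n_iter: int = 100,
    seed: int = 0,
    fs: float = 40.0,
    mask: Optional[np.ndarray] = None,
) -> MotifSet:
    """Fit K motifs of length L frames to a nonnegative pixels x time matrix.

    Parameters
    ----------
    X:
        P x T nonnegative data (masked, rectified dF/F flattened to
        pixels x time). The fit runs in ``X``'s floating dtype; pass float32
        for long sessions to halve time and memory.
    K, L:
        Number of motifs and motif length in frames (L = 40 is 1 s at 40 Hz).
    lam:
        Cross-factor orthogonality penalty weight; 0 disables the penalty.
    n_iter, seed:
        Multiplicative-update count and RNG seed for the nonnegative random
        initialization. Identical inputs give identical results.
    """
    X = np.asarray(X)
    if X.ndim != 2:
        raise ParameterError(f"X must be pixels x time, got shape {X.shape}")
    if np.any(X < 0):
        raise ParameterError("X must be nonnegative (rectify dF/F first)")
    if K < 1 or L < 1 or n_iter < 1:
        raise ParameterError("K, L and n_iter must all be >= 1")
    P, T = X.shape
    if K * L > T:
        raise ParameterError(f"K*L = {K * L} exceeds T = {T}; nothing to fit")
    dtype = X.dtype if X.dtype in (np.float32, np.float64) else np.dtype(np.float64)
    X = X.astype(dtype, copy=False)
    eps = dtype.type(_EPS)
    lam_t = dtype.type(lam)

    rng = np.random.default_rng(seed)
    xmax = float(X.max())
    W = (xmax * rng.random((P, K, L))).astype(dtype)
    H = (xmax / max(np.sqrt(K * L), 1.0) * rng.random((K, T))).astype(dtype)

    norm_x2 = float(np.einsum("pt,pt->", X, X, dtype=np.float64))
    off_diag = (np.ones((K, K)) - np.eye(K)).astype(dtype)
    smooth_w = 2 * L - 1

    def objective(Wf: np.ndarray, Hs: np.ndarray, num_w: np.ndarray, HH: np.ndarray) -> float:
        cross = float(np.einsum("pq,pq->", Wf, num_w, dtype=np.float64))
        norm_hat2 = float(np.einsum("pq,pq->", Wf, Wf @ HH, dtype=np.float64))
        obj = norm_x2 - 2.0 * cross + norm_hat2
        if lam > 0:
            WX = _unstack_sum(Wf.T @ X, K, L, T)
            WXS = _moving_sum(WX, smooth_w)
            obj += lam * float(np.sum(off_diag * (WXS @ H.T)))
        return obj

    Wf = W.reshape(P, K * L)
    trace = np.empty(n_iter + 1, dtype=np.float64)
    Hs = _stack_loadings(H, L)
    trace[0] = objective(Wf, Hs, X @ Hs.T, Hs @ Hs.T)

    for it in range(1, n_iter + 1):
        # --- H update (Lee-Seung on the linear operator h -> W (*) h)
        C = Wf.T @ X
        num_h = _unstack_sum(C, K, L, T)
        G = Wf.T @ Wf
        den_h = _unstack_sum(G @ _stack_loadings(H, L), K, L, T)
        if lam > 0:
            WXS = _moving_sum(num_h, smooth_w)
            den_h = den_h + lam_t * (off_diag @ WXS)
        H *= num_h / (den_h + eps)

        # --- W update (Lee-Seung with H fixed)
        Hs = _stack_loadings(H, L)
        num_w = X @ Hs.T
        HH = Hs @ Hs.T
        den_w = Wf @ HH
        if lam > 0:
            HSs = _stack_loadings(_moving_sum(H, smooth_w), L)
            crossw = (X @ HSs.T).reshape(P, K, L)
            den_pen = crossw.sum(axis=1, keepdims=True) - crossw
            den_w = den_w + lam_t * den_pen.reshape(P, K * L)
        Wf *= num_w / (den_w + eps)

        trace[it] = objective(Wf, Hs, num_w, HH)

    W = Wf.reshape(P, K, L)
    scale = W.max(axis=(0, 2))
    nz = scale > 0
    W[:, nz, :] /= scale[nz][None, :, None]
    H[nz] *= scale[nz][:, None]
    return MotifSet(
        W=W, H=H, L=L, lam=lam, objective_trace=trace, seed=seed, fs=fs, mask=mask
    )


def reconstruct(motifs: MotifSet) -> np.ndarray:
    """Convolutional reconstruction sum_k sum_l W[:,k,l] H[k, t-l] as P x T."""
    K, T = motifs.H.shape
    Wf = motifs.W.reshape(motifs.n_pixels, K * motifs.L)
    return Wf @ _stack_loadings(motifs.H, motifs.L)


@dataclass
class MotifTraceXCorr:
    """Cross-correlation of one motif's loading with the photometry trace."""

    motif: int
    lag_s: float
    peak_r: float
    degenerate: bool = False


def motif_photometry_xcorr(
    motifs: MotifSet, trace: Trace, max_lag: float = 2.0
) -> list:
    """Peak cross-correlation lag of each motif loading vs the striatal trace.

    Both signals are z-scored; the lag convention matches
    :func:`mesophot.maps.xcorr_lag` (negative lag: motif/cortex leads).
    Results are sorted by peak descending; motifs with constant (e.g. all-zero)
    loadings, or a constant trace, are flagged degenerate and sorted last.
    """
    K, T = motifs.H.shape
    if trace.n != T:
        raise AlignmentError(
            f"trace length {trace.n} does not match loading length {T}"
        )
    if not np.isclose(trace.fs, motifs.fs):
        raise AlignmentError(f"trace fs {trace.fs} != motif fs {motifs.fs}")
    trace_degenerate = np.ptp(trace.samples) == 0
    zt = zscore_trace(trace)
    results = []
    for k in range(K):
        h = motifs.H[k]
        if trace_degenerate or np.ptp(h) == 0:
            results.append(MotifTraceXCorr(k, np.nan, np.nan, degenerate=True))
            continue
        zh = zscore_trace(Trace(h, fs=motifs.fs, t0=trace.t0))
        lag, peak = xcorr_lag(zh, zt, max_lag)
        results.append(MotifTraceXCorr(k, lag, peak))
    results.sort(
        key=lambda r: (r.degenerate, -(r.peak_r if np.isfinite(r.peak_r) else -np.inf))
    )
    return results


def motif_map_similarity(motifs: MotifSet, cmap: CorrelationMap) -> np.ndarray:
    """Pearson r between each motif's spatial footprint and a correlation map.

    The footprint is the motif's temporal max-projection; the comparison runs
    over masked pixels. Separates map-like motifs (e.g. the bilateral
    sensorimotor pattern of the corticostriatal correlation map) from others.
    """
    if motifs.mask is None:
        raise ParameterError("MotifSet has no mask; cannot align with the map")
    if motifs.mask.shape != cmap.mask.shape or not np.array_equal(
        motifs.mask, cmap.mask
    ):
        raise AlignmentError("motif and map masks differ")
    mvals = cmap.values[cmap.mask]
    if np.ptp(mvals[np.isfinite(mvals)]) == 0:
        raise DegenerateDataError("correlation map is constant; similarity undefined")
    proj = motifs.max_projection()  # (P, K)
    mv = mvals - np.nanmean(mvals)
    mv = np.nan_to_num(mv)
    out = np.empty(motifs.K)
    mden = float(mv @ mv)
    for k in range(motifs.K):
        p = proj[:, k].astype(np.float64)
        pc = p - p.mean()
        den = np.sqrt(float(pc @ pc) * mden)
        out[k] = np.nan if den == 0 else float(pc @ mv) / den
    return out
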