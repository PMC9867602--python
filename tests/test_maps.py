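"""Correlation maps, partial correlation, cross-correlation lag estimation."""

import numpy as np
import pytest

import mesophot as mp
from mesophot.core import AlignmentError, DegenerateDataError, pearson_r


def _stack_from_rows(rows, fs=40.0, mask=None):
    """Stack whose pixel (i, j) carries rows[i*W+j]."""
    P, T = rows.shape
    side = int(np.sqrt(P))
    return mp.WidefieldStack(rows.reshape(side, side, T), fs=fs, mask=mask)


class TestCorrelationMap:
    def test_perfect_and_anticorrelated_pixels(self, rng):
        x = rng.standard_normal(500)
        rows = rng.standard_normal((4, 500))
        rows[1] = x
        rows[2] = -x
        stack = _stack_from_rows(rows)
        cmap = mp.correlation_map(stack, mp.Trace(x, fs=40.0))
        flat = cmap.values.ravel()
        assert np.isclose(flat[1], 1.0)
        assert np.isclose(flat[2], -1.0)

    def test_noisy_linear_pixel_matches_closed_form_expectation(self, rng):
        T = 20000
        a, sd_t, sd_n = 0.7, 1.0, 0.5
        t = rng.standard_normal(T) * sd_t
        rows = np.vstack([a * t + rng.standard_normal(T) * sd_n for _ in range(4)])
        stack = _stack_from_rows(rows)
        cmap = mp.correlation_map(stack, mp.Trace(t, fs=40.0))
        expected = a * sd_t / np.sqrt(a**2 * sd_t**2 + sd_n**2)
        se = (1 - expected**2) / np.sqrt(T)
        for r in cmap.values.ravel():
            # direct-formula oracle agrees with the map machinery
            assert abs(r - expected) < 3 * se
        i, j = 1, 1
        assert np.isclose(
            cmap.values[i, j],
            pearson_r(stack.frames[i, j], t),
            atol=1e-10,
        )

    def test_length_mismatch_raises(self, small_stack):
        with pytest.raises(AlignmentError):
            mp.correlation_map(small_stack, mp.Trace(np.zeros(99) + 1.0, fs=40.0))


class TestPartialCorrelationMap:
    def test_pixel_equal_to_global_is_flagged_zero(self, rng):
        g = rng.standard_normal(400)
        rows = rng.standard_normal((4, 400))
        rows[0] = g
        stack = _stack_from_rows(rows)
        trace = mp.Trace(rng.standard_normal(400), fs=40.0)
        pmap = mp.partial_correlation_map(stack, trace, mp.Trace(g, fs=40.0))
        assert pmap.values.ravel()[0] == 0.0
        assert pmap.degenerate.ravel()[0]

    def test_reduces_to_full_r_when_control_uncorrelated(self):
        # orthogonal designs: global exactly uncorrelated with pixel and trace
        T = 400
        w = 2 * np.pi * np.arange(T) / T
        pixel = np.sin(3 * w)
        trace = np.sin(3 * w) + np.sin(5 * w)
        glob = np.sin(11 * w)
        rows = np.vstack([pixel] * 4)
        stack = _stack_from_rows(rows)
        full = mp.correlation_map(stack, mp.Trace(trace, fs=40.0))
        part = mp.partial_correlation_map(
            stack, mp.Trace(trace, fs=40.0), mp.Trace(glob, fs=40.0)
        )
        assert np.allclose(part.values, full.values, atol=1e-12)

    def test_closed_form_equals_residual_regression_oracle(self, rng):
        T = 300
        rows = rng.standard_normal((9, T))
        trace = rng.standard_normal(T)
        glob = rng.standard_normal(T)
        stack = _stack_from_rows(rows)
        pmap = mp.partial_correlation_map(
            stack, mp.Trace(trace, fs=40.0), mp.Trace(glob, fs=40.0)
        )

        def residual(y, z):
            zc = np.column_stack([z, np.ones_like(z)])
            beta, *_ = np.linalg.lstsq(zc, y, rcond=None)
            return y - zc @ beta

        rt = residual(trace, glob)
        for p in range(9):
            oracle = pearson_r(residual(rows[p], glob), rt)
            assert np.isclose(pmap.values.ravel()[p], oracle, atol=1e-10)

    def test_constant_global_raises(self, small_stack, rng):
        trace = mp.Trace(rng.standard_normal(small_stack.n_frames), fs=40.0)
        with pytest.raises(DegenerateDataError):
            mp.partial_correlation_map(
                small_stack, trace, mp.Trace(np.full(small_stack.n_frames, 1.0), fs=40.0)
            )


class TestXcorrLag:
    def test_self_correlation_peaks_at_zero(self, rng):
        a = mp.Trace(rng.standard_normal(1000), fs=40.0)
        lag, peak = mp.xcorr_lag(a, a, max_lag=1.0)
        assert lag == 0.0 and np.isclose(peak, 1.0)

    def test_constructed_12_sample_delay(self, rng):
        x = rng.standard_normal(2000)
        a = mp.Trace(x, fs=40.0)
        b = mp.Trace(np.roll(x, 12), fs=40.0)  # b(t) = a(t - 12 samples)
        lag, peak = mp.xcorr_lag(a, b, max_lag=1.0)
        assert np.isclose(lag, -0.300)
        assert peak > 0.98

    def test_matches_exhaustive_search_oracle(self, rng):
        x = rng.standard_normal(600)
        y = 0.6 * np.roll(x, -7) + 0.4 * rng.standard_normal(600)
        a, b = mp.Trace(x, fs=40.0), mp.Trace(y, fs=40.0)
        lag, peak = mp.xcorr_lag(a, b, max_lag=0.5)
        # oracle: recompute Pearson at every integer lag with numpy.corrcoef
        best = (None, -np.inf)
        T = 600
        for k in range(-20, 21):
            if k >= 0:
                r = np.corrcoef(x[k:], y[: T - k])[0, 1]
            else:
                r = np.corrcoef(x[: T + k], y[-k:])[0, 1]
            if r > best[1]:
                best = (k / 40.0, r)
        assert lag == best[0]
        assert np.isclose(peak, best[1], atol=1e-12)

    def test_antisymmetry_under_swap(self, rng):
        x = rng.standard_normal(800)
        y = np.roll(x, 5) + 0.1 * rng.standard_normal(800)
        a, b = mp.Trace(x, fs=40.0), mp.Trace(y, fs=40.0)
        lag_ab, _ = mp.xcorr_lag(a, b, max_lag=0.5)
        lag_ba, _ = mp.xcorr_lag(b, a, max_lag=0.5)
        assert abs(lag_ab + lag_ba) <= 1 / 40.0 + 1e-12


class TestLagMap:
    def test_two_planted_regions_read_exact_lags(self, rng):
        T = 2000
        base = rng.standard_normal(T + 100)
        trace = base[50 : 50 + T]
        rows = 0.01 * rng.standard_normal((16, T))
        # region A leads by 0.3 s (12 frames), region B by 0.4 s (16 frames)
        for p in range(4):
            rows[p] += base[50 + 12 : 50 + 12 + T]
        for p in range(4, 8):
            rows[p] += base[50 + 16 : 50 + 16 + T]
        stack = _stack_from_rows(rows)
        lmap = mp.lag_map(stack, mp.Trace(trace, fs=40.0), max_lag=1.0)
        lags = lmap.lags.ravel()
        assert np.allclose(lags[:4], -0.3)
        assert np.allclose(lags[4:8], -0.4)
        assert np.all(lmap.valid.ravel()[:8])

    def test_pure_noise_marked_invalid(self, rng):
        rows = rng.standard_normal((16, 1200))
        stack = _stack_from_rows(rows)
        trace = mp.Trace(rng.standard_normal(1200), fs=40.0)
        lmap = mp.lag_map(stack, trace, max_lag=2.0, r_threshold=0.5)
        assert not lmap.valid.any()

    def test_single_pixel_mask_reduces_to_xcorr_lag(self, rng):
        rows = rng.standard_normal((16, 500))
        mask = np.zeros((4, 4), dtype=bool)
        mask[2, 1] = True
        stack = _stack_from_rows(rows, mask=mask)
        trace = mp.Trace(0.8 * rows[9] + 0.2 * rng.standard_normal(500), fs=40.0)
        lmap = mp.lag_map(stack, trace, max_lag=0.5, r_threshold=0.5)
        lag, peak = mp.xcorr_lag(mp.Trace(rows[9], fs=40.0), trace, max_lag=0.5)
        assert lmap.lags[2, 1] == lag
        assert np.isclose(lmap.peak_r[2, 1], peak, atol=1e-5)

    def test_lags_are_frame_multiples(self, rng):
        rows = rng.standard_normal((16, 800))
        stack = _stack_from_rows(rows)
        trace = mp.Trace(rows[3] + 0.5 * rng.standard_normal(800), fs=40.0)
        lmap = mp.lag_map(stack, trace, max_lag=1.0)
        finite = lmap.lags[np.isfinite(lmap.lags)]
        assert np.allclose(finite * 40.0, np.round(finite * 40.0), atol=1e-9)

    def test_footprint_contrast_on_synthetic_session(self):
        # a static coupled motif: every footprint pixel expresses the full
        # motif time course, so the zero-lag correlation map carries the
        # spatial footprint (a travelling wave disperses pixel onsets and is
        # the lag map's job instead)
        cfg = mp.SceneConfig(
            height=16, width=16, duration=300.0,
            motif_specs=[mp.MotifSpec("alm_visual", length=40, rate=0.2)],
            photometry_couplings=[mp.PhotometryCoupling(0, delay_ms=300.0)],
            seed=11,
        )
        stack, rec, truth = mp.generate_spontaneous_session(cfg)
        trace = mp.zscore_trace(
            mp.Trace(
                mp.resample_trace(
                    mp.bandpass_filter(mp.moving_avg_dff(rec.f465)), 40.0
                ).samples[: stack.n_frames],
                fs=40.0,
            )
        )
        proc = mp.stack_bandpass(mp.spatial_disc_smooth(mp.stack_dff(stack)))
        cmap = mp.correlation_map(proc, trace)
        proj = truth.motif_templates[0].max(axis=2)
        footprint = proj > 0.1 * proj.max()
        inside = cmap.values[footprint & stack.mask]
        outside = cmap.values[~footprint & stack.mask]
        assert np.nanmean(inside) - np.nanmean(outside) > 0.3
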