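"""Synthetic-session generator: templates, determinism, planted structure."""

import numpy as np
import pytest

import mesophot as mp
from mesophot.core import ParameterError
from tests.conftest import make_scene


class TestTemplates:
    @pytest.mark.parametrize("hw", [16, 64])
    def test_travelling_blob_centroid_strictly_increases(self, hw):
        cfg = make_scene(height=hw, width=hw,
                         motif_specs=[mp.MotifSpec("ap_wave", length=40)],
                         photometry_couplings=[])
        (tpl,) = mp.generate_motif_templates(cfg)
        rows = np.arange(hw, dtype=float)
        cents = [
            (rows @ tpl[:, :, l].sum(axis=1)) / tpl[:, :, l].sum()
            for l in range(40)
        ]
        assert np.all(np.diff(cents) > 0)

    def test_nonnegative_and_peak_equals_amplitude(self):
        cfg = make_scene(
            motif_specs=[mp.MotifSpec("ap_wave", amplitude=2.5),
                         mp.MotifSpec("alm_visual", amplitude=7.0)],
            photometry_couplings=[],
        )
        ap, alm = mp.generate_motif_templates(cfg)
        for tpl, amp in ((ap, 2.5), (alm, 7.0)):
            assert np.all(tpl >= 0)
            assert np.isclose(tpl.max(), amp)

    @pytest.mark.parametrize("hw", [16, 32, 64])
    def test_sensorimotor_and_alm_visual_are_disjoint(self, hw):
        cfg = make_scene(height=hw, width=hw,
                         motif_specs=[mp.MotifSpec("ap_wave"),
                                      mp.MotifSpec("alm_visual")],
                         photometry_couplings=[])
        ap, alm = mp.generate_motif_templates(cfg)
        assert float((ap.max(axis=2) * alm.max(axis=2)).sum()) == 0.0

    def test_unknown_template_id_rejected(self):
        cfg = make_scene(motif_specs=[mp.MotifSpec("no_such_pattern")],
                         photometry_couplings=[])
        with pytest.raises(ParameterError, match="no_such_pattern"):
            mp.generate_motif_templates(cfg)


class TestSpontaneousSession:
    def test_empty_scene_is_constant_baseline(self):
        cfg = make_scene(motif_specs=[], photometry_couplings=[],
                         noise_sd_widefield=0.0, noise_sd_photometry=0.0,
                         drift_amplitude=0.0, duration=30.0)
        stack, rec, _ = mp.generate_spontaneous_session(cfg)
        assert np.all(stack.frames == np.float32(cfg.baseline_level))
        assert np.all(rec.f465.samples == cfg.baseline_level)
        assert np.all(rec.f405.samples == cfg.baseline_level)

    def test_seed_determinism(self):
        cfg = make_scene(duration=30.0)
        s1, r1, t1 = mp.generate_spontaneous_session(cfg)
        s2, r2, t2 = mp.generate_spontaneous_session(make_scene(duration=30.0))
        assert np.array_equal(s1.frames, s2.frames)
        assert np.array_equal(r1.f465.samples, r2.f465.samples)
        assert np.array_equal(r1.f405.samples, r2.f405.samples)
        assert np.array_equal(t1.motif_loadings, t2.motif_loadings)

    def test_linearity_in_motif_amplitude(self):
        base = dict(duration=60.0, noise_sd_widefield=0.0,
                    noise_sd_photometry=0.0, drift_amplitude=0.0,
                    photometry_couplings=[])
        cfg1 = make_scene(motif_specs=[mp.MotifSpec("ap_wave", length=20,
                                                    amplitude=3.0)], **base)
        cfg2 = make_scene(motif_specs=[mp.MotifSpec("ap_wave", length=20,
                                                    amplitude=6.0)], **base)
        s1, _, _ = mp.generate_spontaneous_session(cfg1)
        s2, _, _ = mp.generate_spontaneous_session(cfg2)
        dev1 = s1.frames.astype(np.float64) - cfg1.baseline_level
        dev2 = s2.frames.astype(np.float64) - cfg2.baseline_level
        assert np.allclose(dev2, 2 * dev1, atol=1e-4)

    def test_isosbestic_channel_uncorrelated_with_loadings(self):
        cfg = make_scene(duration=600.0)  # 10 min
        _, rec, truth = mp.generate_spontaneous_session(cfg)
        f405_40 = mp.resample_trace(rec.f405, 40.0).samples
        occ = truth.motif_loadings[0][: f405_40.size]
        r = np.corrcoef(f405_40[: occ.size], occ)[0, 1]
        assert abs(r) < 0.1

    def test_coupling_delay_visible_in_cross_correlation(self):
        cfg = make_scene(duration=300.0, noise_sd_widefield=0.0,
                         noise_sd_photometry=0.0)
        stack, rec, truth = mp.generate_spontaneous_session(cfg)
        g = mp.zscore_trace(mp.global_signal(stack))
        p40 = mp.resample_trace(rec.f465, 40.0)
        p = mp.zscore_trace(mp.Trace(p40.samples[: stack.n_frames], fs=40.0))
        lag, peak = mp.xcorr_lag(g, p, max_lag=2.0)
        # oracle: direct sliding Pearson over all integer lags
        T = stack.n_frames
        best = (None, -np.inf)
        for k in range(-80, 81):
            if k >= 0:
                r = np.corrcoef(g.samples[k:], p.samples[: T - k])[0, 1]
            else:
                r = np.corrcoef(g.samples[: T + k], p.samples[-k:])[0, 1]
            if r > best[1]:
                best = (k / 40.0, r)
        assert lag == best[0]
        assert np.isclose(lag, -0.300, atol=1e-9)

    def test_too_short_duration_rejected(self):
        cfg = make_scene(duration=0.25)  # 10 frames < 20-frame motif
        with pytest.raises(ParameterError):
            mp.generate_spontaneous_session(cfg)

    def test_invariants_validated(self):
        with pytest.raises(ParameterError):
            make_scene(fs_photometry=20.0).validate()  # below widefield rate
        with pytest.raises(ParameterError):
            make_scene(noise_sd_widefield=-1.0).validate()


class TestEvokedSession:
    def _evoked_cfg(self, **stim_overrides):
        stim = dict(n_stimuli=20, isi_s=5.0, habituation_decay=1.0,
                    amplitude=5.0)
        stim.update(stim_overrides)
        return make_scene(
            duration=120.0, motif_specs=[], photometry_couplings=[],
            noise_sd_widefield=0.0, noise_sd_photometry=0.0,
            drift_amplitude=0.0, stimulus=mp.StimulusSpec(**stim),
        )

    def test_schedule_recorded_and_emitted(self):
        cfg = self._evoked_cfg()
        stack, rec, truth = mp.generate_evoked_session(cfg)
        assert truth.stimulus_times.size == 20
        assert np.allclose(np.diff(truth.stimulus_times), 5.0)
        assert len(rec.events) == 20

    def test_no_habituation_first_equals_last(self):
        stack, _, truth = mp.generate_evoked_session(self._evoked_cfg())
        resp = stack.frames.astype(np.float64) - 100.0
        amps = [resp[:, :, int(t * 40) : int(t * 40) + 40].max()
                for t in truth.stimulus_times]
        assert np.isclose(np.mean(amps[:10]), np.mean(amps[-10:]), rtol=1e-6)

    def test_geometric_habituation_matches_direct_sums(self):
        cfg = self._evoked_cfg(habituation_decay=0.9, n_stimuli=40, isi_s=2.5)
        stack, _, truth = mp.generate_evoked_session(cfg)
        resp = stack.frames.astype(np.float64) - 100.0
        amps = np.array([resp[:, :, int(t * 40) : int(t * 40) + 40].max()
                         for t in truth.stimulus_times])
        ratio = amps[-10:].mean() / amps[:10].mean()
        expected = sum(0.9 ** (t - 1) for t in range(31, 41)) / sum(
            0.9 ** (t - 1) for t in range(1, 11)
        )
        assert np.isclose(ratio, expected, rtol=1e-4)
        assert np.allclose(truth.habituation_factors, 0.9 ** np.arange(40))

    def test_zero_artifact_amplitude_changes_nothing(self):
        s0, _, _ = mp.generate_evoked_session(self._evoked_cfg(artifact_amplitude=0.0))
        s1, _, _ = mp.generate_evoked_session(self._evoked_cfg())
        assert np.array_equal(s0.frames, s1.frames)

    def test_artifact_spike_is_one_frame(self):
        s, _, truth = mp.generate_evoked_session(
            self._evoked_cfg(artifact_amplitude=50.0)
        )
        s0, _, _ = mp.generate_evoked_session(self._evoked_cfg())
        diff = s.frames.astype(np.float64) - s0.frames.astype(np.float64)
        hit_frames = np.flatnonzero(np.abs(diff).max(axis=(0, 1)) > 0)
        assert np.array_equal(hit_frames,
                              np.round(truth.stimulus_times * 40).astype(int))

    def test_overlong_schedule_rejected(self):
        with pytest.raises(ParameterError):
            mp.generate_evoked_session(self._evoked_cfg(n_stimuli=100, isi_s=10.0))

    def test_spontaneous_generator_rejects_stimulus_config(self):
        with pytest.raises(ParameterError):
            mp.generate_spontaneous_session(self._evoked_cfg())
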