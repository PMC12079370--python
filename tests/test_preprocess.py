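"""QC and signal-conditioning contracts."""

import numpy as np
import pytest

from classrsa import preprocess as pp
from classrsa.synth import global_series, inject_artifacts, make_event_set
from classrsa.types import ConfigError, EventSet, Recording

from conftest import make_cohort


def flat_recording(c=4, t=3000, fs=10.0, value=0.0):
    return Recording(data=np.full((c, t), value), fs=fs)


class TestDetectArtifacts:
    def test_constant_signal_no_artifacts(self):
        qc = pp.detect_artifacts(flat_recording())
        assert qc.artifact_fraction.sum() == 0
        assert not qc.bad_channels.any()

    def test_planted_six_percent_spikes_flag_channel_bad(self, small_cohort):
        _, _, students, _ = small_cohort
        rec = students[0]
        # isolated one-sample spikes: dense wide artifacts inflate the
        # window SD enough to hide themselves from the 3 SD rule
        n_spikes = int(np.ceil(0.06 * rec.n_samples))
        spiked, mask = inject_artifacts(rec, n_spikes, 30.0, seed=1,
                                        channel=0, spike_width_s=0.1)
        assert mask[0].mean() >= 0.06
        qc = pp.detect_artifacts(spiked)
        assert qc.bad_channels[0]
        assert not qc.bad_channels[1:].any()
        # flagged samples should cover most of the planted ones
        hit = (qc.artifact_mask[0] & mask[0]).sum() / mask[0].sum()
        assert hit > 0.5

    def test_subject_excluded_above_30_percent_bad(self, rng):
        # 8 of 22 channels bad (36%) -> excluded
        data = rng.standard_normal((22, 2000)) * 0.01
        rec = Recording(data=data, fs=10.0)
        for c in range(8):
            idx = rng.choice(2000, size=150, replace=False)
            rec.data[c, idx] += 0.01 * 30.0 * rng.choice([-1, 1],
                                                         size=150)
        qc = pp.detect_artifacts(rec)
        assert qc.bad_channels.sum() >= 8
        assert qc.exclude_subject

    def test_window_longer_than_recording_errors(self):
        with pytest.raises(ConfigError):
            pp.detect_artifacts(flat_recording(t=50), window_s=10)


class TestTrimSteadyState:
    def test_600s_phase_keeps_570(self):
        rec = Recording(data=np.random.default_rng(0).normal(
            size=(2, 6000)), fs=10.0)
        out = pp.trim_steady_state(rec, 15.0)
        assert out.n_samples == 5700
        assert out.phases["session"] == (0.0, 570.0)

    def test_event_onsets_rereferenced(self):
        rec = Recording(data=np.zeros((1, 2000)), fs=10.0)
        ev = EventSet([20.0, 60.0], [50.0, 100.0], ["a", "b"],
                      np.ones((2, 3)))
        _, ev2 = pp.trim_steady_state(rec, 15.0, ev)
        assert ev2.onsets[0] == pytest.approx(5.0)
        assert ev2.offsets[1] == pytest.approx(85.0)

    def test_short_phase_errors(self):
        rec = Recording(data=np.zeros((1, 250)), fs=10.0)
        with pytest.raises(ConfigError):
            pp.trim_steady_state(rec, 15.0)


class TestRemoveGlobalPCA:
    def test_identical_channels_fully_removed(self):
        base = np.sin(np.linspace(0, 40, 2000))
        rec = Recording(data=np.tile(base, (5, 1)) * np.arange(1, 6)[:, None],
                        fs=10.0)
        out = pp.remove_global_pca(rec)
        assert np.abs(out.data - out.data.mean(axis=1, keepdims=True)
                      ).max() < 1e-9

    def test_injected_global_component_removed(self):
        cfg, _, students, truth = make_cohort(rho=0.3, seed=21,
                                              n_students=1, n_channels=12,
                                              global_amp=2.0)
        rec = students[0]
        g = truth.global_series
        out = pp.remove_global_pca(rec)
        for c in range(rec.n_channels):
            r = np.corrcoef(out.data[c], g)[0, 1]
            assert abs(r) < 0.1

    def test_needs_two_good_channels(self):
        rec = Recording(data=np.zeros((1, 100)), fs=10.0)
        with pytest.raises(ConfigError):
            pp.remove_global_pca(rec)


class TestBandpass:
    def test_1hz_tone_attenuated_20db(self):
        # tone amplitude read off the 1 Hz Fourier bin (total variance of
        # the output also carries the slow filtfilt edge transient)
        t = np.arange(0, 600, 0.1)
        rec = Recording(data=np.sin(2 * np.pi * 1.0 * t)[None, :], fs=10.0)
        out = pp.bandpass(rec)
        bin_1hz = int(1.0 * 600)
        a_in = np.abs(np.fft.rfft(rec.data[0]))[bin_1hz]
        a_out = np.abs(np.fft.rfft(out.data[0]))[bin_1hz]
        assert 20 * np.log10(a_out / a_in) <= -20

    def test_01hz_tone_preserved(self):
        t = np.arange(0, 600, 0.1)
        rec = Recording(data=np.sin(2 * np.pi * 0.1 * t)[None, :], fs=10.0)
        out = pp.bandpass(rec)
        mid = slice(500, 5500)
        ratio = np.std(out.data[0, mid]) / np.std(rec.data[0, mid])
        assert 0.9 <= ratio <= 1.1

    def test_constant_rejected(self):
        out = pp.bandpass(flat_recording(value=3.5))
        assert np.abs(out.data).max() < 1e-8

    def test_invalid_band_errors(self):
        with pytest.raises(ConfigError):
            pp.bandpass(flat_recording(), lo=0.01, hi=6.0)


class TestZscore:
    def test_mean_zero_sd_one(self, small_cohort):
        _, _, students, _ = small_cohort
        out = pp.zscore(students[0])
        np.testing.assert_allclose(out.data.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(out.data.std(axis=1), 1, atol=1e-10)

    def test_affine_invariance(self, small_cohort):
        _, _, students, _ = small_cohort
        rec = students[0]
        scaled = rec.with_data(rec.data * 7.0 - 3.0)
        np.testing.assert_allclose(pp.zscore(rec).data,
                                   pp.zscore(scaled).data, atol=1e-10)

    def test_idempotence(self, small_cohort):
        _, _, students, _ = small_cohort
        once = pp.zscore(students[0])
        twice = pp.zscore(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_constant_channel_zeroed_and_flagged(self):
        data = np.random.default_rng(0).normal(size=(3, 500))
        data[2] = 4.2
        out = pp.zscore(Recording(data=data, fs=10.0))
        assert np.all(out.data[2] == 0)
        assert out.qc is not None and out.qc.bad_channels[2]


class TestPipeline:
    def test_end_to_end_finite_zscored_and_events_preserved(self):
        cfg, ev, students, truth = make_cohort(rho=0.5, seed=31,
                                               n_students=1, n_channels=6,
                                               global_amp=1.0)
        rec, ev2, qc = pp.preprocess_pipeline(students[0],
                                              event_set=ev)
        assert np.all(np.isfinite(rec.data))
        assert ev2.n_events == ev.n_events
        assert np.all(np.diff(ev2.onsets) > 0)
        np.testing.assert_allclose(ev2.onsets, ev.onsets - 15.0)
        good = ~qc.bad_channels
        np.testing.assert_allclose(rec.data[good].mean(axis=1), 0,
                                   atol=1e-9)

    def test_embedded_structure_survives_conditioning(self):
        """The RSA-recoverable structure must not be destroyed by the
        pipeline's own filters (global_amp=0, independent channels)."""
        from classrsa import rsa
        cfg, ev, students, truth = make_cohort(rho=0.9, seed=41,
                                               n_students=6, n_channels=6,
                                               duration_range=(10, 40))
        before = rsa.channel_mean_rsa(students, ev, truth.knowledge_matrix,
                                      1)
        cleaned, evs = [], None
        for r in students:
            rc, evs, _ = pp.preprocess_pipeline(r, event_set=ev)
            cleaned.append(rc)
        after = rsa.channel_mean_rsa(cleaned, evs, truth.knowledge_matrix, 1)
        assert after > 0
        assert abs(after - before) / before < 0.2
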