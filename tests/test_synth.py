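"""The synthetic cohort generator: construction rules and parameter
recovery oracles."""

import numpy as np
import pytest

from classrsa import rsa
from classrsa.knowledge import cosine_knowledge_matrix
from classrsa.synth import (SynthConfig, double_gamma_hrf, inject_artifacts,
                            make_event_set, simulate_cohort, simulate_recall,
                            simulate_recording, topic_basis)
from classrsa.types import ConfigError

from conftest import make_cohort


class TestMakeEventSet:
    def test_26_events_within_duration_bounds(self):
        ev = make_event_set(26, 8, (6, 200), seed=3)
        assert ev.n_events == 26
        assert np.all(ev.durations >= 6) and np.all(ev.durations <= 200)
        # contiguous tiling of the session
        np.testing.assert_allclose(ev.onsets[1:], ev.offsets[:-1])

    def test_infinite_concentration_gives_all_ones_matrix(self):
        ev = make_event_set(5, 8, (6, 20), concentration=np.inf, seed=0)
        km = cosine_knowledge_matrix(ev)
        np.testing.assert_allclose(km.values, 1.0)

    def test_seed_determinism(self):
        a = make_event_set(10, 8, (6, 60), seed=42)
        b = make_event_set(10, 8, (6, 60), seed=42)
        np.testing.assert_array_equal(a.onsets, b.onsets)
        np.testing.assert_array_equal(a.topic_vectors, b.topic_vectors)

    def test_invalid_durations_error(self):
        with pytest.raises(ConfigError):
            make_event_set(5, 8, (-1, 10))
        with pytest.raises(ConfigError):
            make_event_set(2, 8, (6, 10))


class TestSimulateRecording:
    def test_rho1_noiseless_pair_matches_analytic_overlap(self,
                                                          noiseless_pair):
        """At rho=1 with no noise the inter-subject pair matrix must equal
        the correlation of the topic-basis mixtures computed directly from
        the mixing weights (independent construction, plain corrcoef)."""
        cfg, ev, students, truth = noiseless_pair
        pm = rsa.pair_brain_matrix(students[0], students[1], ev,
                                   cfg.embed_channel)
        basis = topic_basis(cfg, ev)
        w = ev.topic_vectors
        lengths = np.round(ev.durations * cfg.fs).astype(int)
        m = ev.n_events
        expected = np.zeros((m, m))
        for a in range(m):
            for b in range(m):
                ln = min(lengths[a], lengths[b])
                sa = w[a] @ basis[:, :ln]
                sb = w[b] @ basis[:, :ln]
                expected[a, b] = np.corrcoef(sa, sb)[0, 1]
        expected = (expected + expected.T) / 2
        np.testing.assert_allclose(pm.values[pm.mask], expected[pm.mask],
                                   atol=1e-6)

    def test_rho0_embed_channel_uncorrelated(self):
        cfg, ev, students, truth = make_cohort(rho=0.0, seed=5,
                                               n_students=8, n_events=8)
        rs = [rsa.pair_brain_matrix(students[i], students[j], ev, 1)
              for i, j in [(0, 1), (2, 3), (4, 5), (6, 7)]]
        cells = np.concatenate([p.values[p.mask] for p in rs])
        assert abs(cells.mean()) < 3 * cells.std() / np.sqrt(cells.size)

    def test_teacher_lead_shifts_signal_earlier(self):
        cfg, ev, students, teacher, truth = make_cohort(
            rho=1.0, seed=9, n_students=1, with_teacher=True,
            teacher_lead=8.0, noise_ar=0.0)
        fs = cfg.fs
        i0 = int(round(ev.onsets[0] * fs))
        ln = int(round(ev.durations[0] * fs))
        student_sig = students[0].data[1, i0:i0 + ln]
        shifted = teacher.data[1, i0 - 80:i0 - 80 + ln]
        np.testing.assert_allclose(shifted, student_sig, atol=1e-10)

    def test_teacher_lead_beyond_pad_errors(self):
        cfg = SynthConfig(teacher_lead=50.0, pad_s=30.0)
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_boundary_transient_raises_post_offset_mean(self):
        cfg, ev, students, truth = make_cohort(rho=0.0, seed=2,
                                               n_students=1,
                                               boundary_amp=3.0,
                                               noise_ar=0.0)
        x = students[0].data[1]
        fs = cfg.fs
        offs = np.round(ev.offsets * fs).astype(int)
        post = np.mean([x[o:o + 150].mean() for o in offs[:-1]])
        hrf = double_gamma_hrf(fs)
        assert post == pytest.approx(3.0 * hrf[:150].mean(), rel=0.3)

    def test_determinism(self):
        _, _, s1, _ = make_cohort(seed=77, n_students=2)
        _, _, s2, _ = make_cohort(seed=77, n_students=2)
        np.testing.assert_array_equal(s1[0].data, s2[0].data)

    def test_invalid_rho_errors(self):
        with pytest.raises(ConfigError):
            SynthConfig(embed_strength=1.5).validate()


class TestInjectArtifacts:
    def test_zero_spikes_identity(self, small_cohort):
        _, _, students, _ = small_cohort
        rec, mask = inject_artifacts(students[0], 0, 10.0, seed=0)
        np.testing.assert_array_equal(rec.data, students[0].data)
        assert not mask.any()

    def test_single_spike_mask_localized(self, small_cohort):
        _, _, students, _ = small_cohort
        rec, mask = inject_artifacts(students[0], 1, 10.0, seed=4, channel=0)
        assert mask[0].sum() == 5                  # 0.5 s at 10 Hz
        assert mask[1:].sum() == 0
        changed = rec.data[0] != students[0].data[0]
        np.testing.assert_array_equal(changed, mask[0])

    def test_too_many_spikes_error(self, small_cohort):
        _, _, students, _ = small_cohort
        with pytest.raises(ConfigError):
            inject_artifacts(students[0], students[0].n_samples, 10.0)


class TestSimulateRecall:
    def test_full_recall_no_distortion_equals_knowledge(self):
        ev = make_event_set(6, 8, (6, 20), seed=1)
        km = cosine_knowledge_matrix(ev)
        rec = simulate_recall(ev, 1.0, 0.0, seed=0)[0]
        assert rec.matrix.mask.all()
        np.testing.assert_allclose(rec.matrix.values, km.values, atol=1e-12)

    def test_zero_recall_empty_mask(self):
        ev = make_event_set(6, 8, (6, 20), seed=1)
        rec = simulate_recall(ev, 0.0, 0.0, seed=0)[0]
        assert rec.n_recalled == 0
        assert not rec.matrix.mask.any()

    def test_mask_is_recalled_outer_product(self):
        ev = make_event_set(8, 8, (6, 20), seed=2)
        rec = simulate_recall(ev, 0.5, 0.2, seed=3)[0]
        np.testing.assert_array_equal(
            rec.matrix.mask, np.outer(rec.recalled, rec.recalled))

    def test_invalid_probability_errors(self):
        ev = make_event_set(5, 8, (6, 20), seed=1)
        with pytest.raises(ConfigError):
            simulate_recall(ev, 1.5, 0.0)


class TestGeneratorInvariants:
    def test_rsa_monotone_in_rho(self):
        """Mean recovered RSA r on the embed channel is non-decreasing in
        the embedded-correlation strength (small Monte-Carlo version; the
        full grid runs in the acceptance suite)."""
        means = []
        for rho in (0.0, 0.5, 1.0):
            rs = []
            for seed in range(4):
                _, ev, students, truth = make_cohort(
                    rho=rho, seed=800 + seed, n_students=8, n_events=12)
                rs.append(rsa.channel_mean_rsa(students, ev,
                                               truth.knowledge_matrix, 1))
            means.append(np.mean(rs))
        assert means[0] < means[1] < means[2]

    def test_non_embed_channels_centered_at_zero(self):
        rs = []
        for seed in range(6):
            _, ev, students, truth = make_cohort(rho=0.8, seed=900 + seed,
                                                 n_students=6, n_events=12)
            rs.append(rsa.channel_mean_rsa(students, ev,
                                           truth.knowledge_matrix, 0))
        rs = np.array(rs)
        assert abs(rs.mean()) < 2 * rs.std(ddof=1) / np.sqrt(rs.size)
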