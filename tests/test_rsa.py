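"""Inter-subject event matrices, RSA statistics, permutation inference,
FDR, and the boundary contrast."""

import numpy as np
import pytest
from scipy import stats as sps

from classrsa import rsa
from classrsa.stats import GroupTest
from classrsa.types import ConfigError, EventSet, Recording, SimilarityMatrix

from conftest import make_cohort


def tiling_events(n, dur_s=10.0, start=0.0, k=3):
    onsets = start + np.arange(n) * dur_s
    return EventSet(onsets, onsets + dur_s, [f"E{i}" for i in range(n)],
                    np.ones((n, k)))


class TestExtractEventSeries:
    def test_lengths_match_durations(self, rng):
        rec = Recording(data=rng.standard_normal((2, 1000)), fs=10.0)
        ev = EventSet([10.0, 40.0], [30.0, 65.0], ["a", "b"],
                      np.ones((2, 3)))
        series = rsa.extract_event_series(rec, ev, 0)
        assert [len(s) for s in series] == [200, 250]

    def test_tiling_events_reconstruct_span(self, rng):
        rec = Recording(data=rng.standard_normal((1, 500)), fs=10.0)
        ev = tiling_events(5)
        series = rsa.extract_event_series(rec, ev, 0)
        np.testing.assert_array_equal(np.concatenate(series),
                                      rec.data[0, :500])

    def test_event_beyond_end_errors(self, rng):
        rec = Recording(data=rng.standard_normal((1, 100)), fs=10.0)
        ev = EventSet([5.0], [20.0], ["a"], np.ones((1, 2)))
        with pytest.raises(ConfigError):
            rsa.extract_event_series(rec, ev, 0)


class TestTruncatedCorr:
    def test_matches_naive_loops(self, rng):
        lengths = np.array([50, 80, 30, 64])
        lmax = 80
        e = np.zeros((4, lmax))
        f = np.zeros((4, lmax))
        for i, ln in enumerate(lengths):
            e[i, :ln] = rng.standard_normal(ln)
            f[i, :ln] = rng.standard_normal(ln)
        ours = rsa.truncated_corr(e, lengths, f, lengths)
        for a in range(4):
            for b in range(4):
                ln = min(lengths[a], lengths[b])
                ref = np.corrcoef(e[a, :ln], f[b, :ln])[0, 1]
                assert ours[a, b] == pytest.approx(ref, abs=1e-12)

    def test_short_or_constant_cells_nan(self):
        e = np.array([[1.0, 2.0, 0.0, 0.0], [3.0, 3.0, 3.0, 3.0]])
        lengths = np.array([2, 4])
        c = rsa.truncated_corr(e, lengths)
        assert np.isnan(c[0, 0])          # 2 samples < minimum
        assert np.isnan(c[1, 1])          # zero variance


class TestPairBrainMatrix:
    def test_self_pair_diagonal_one(self, small_cohort):
        cfg, ev, students, _ = small_cohort
        sl = rsa.EventSlicer(ev, cfg.fs, students[0].n_samples)
        d = np.diag(rsa.truncated_corr(sl.slice(students[0].data[1]),
                                       sl.lengths))
        np.testing.assert_allclose(d, 1.0, atol=1e-10)

    def test_symmetric_by_construction(self, small_cohort):
        cfg, ev, students, _ = small_cohort
        pm = rsa.pair_brain_matrix(students[0], students[1], ev, 1)
        np.testing.assert_array_equal(pm.values, pm.values.T)
        np.testing.assert_array_equal(pm.mask, pm.mask.T)


class TestSubjectBrainMatrix:
    def test_n2_equals_single_pair(self, noiseless_pair):
        cfg, ev, students, _ = noiseless_pair
        sm = rsa.subject_brain_matrix(0, students, ev, 1)
        pm = rsa.pair_brain_matrix(students[0], students[1], ev, 1)
        np.testing.assert_allclose(sm.values[sm.mask], pm.values[pm.mask])

    def test_invariant_to_cohort_order(self, small_cohort):
        cfg, ev, students, _ = small_cohort
        a = rsa.subject_brain_matrix(0, students, ev, 1)
        reordered = [students[0]] + students[1:][::-1]
        b = rsa.subject_brain_matrix(0, reordered, ev, 1)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_cellwise_mean_of_hand_matrices(self):
        mats = np.stack([np.full((4, 4), v) for v in (0.1, 0.4, 0.7)])
        # subjects 0..2, pairs (0,1),(0,2),(1,2); subject 0 owns pairs 0,1
        subj = rsa.subject_matrices_from_pairs(mats, 3)
        np.testing.assert_allclose(subj[0], (0.1 + 0.4) / 2)
        np.testing.assert_allclose(subj[2], (0.4 + 0.7) / 2)

    def test_single_subject_errors(self, small_cohort):
        cfg, ev, students, _ = small_cohort
        with pytest.raises(ConfigError):
            rsa.subject_brain_matrix(0, students[:1], ev, 1)


class TestRSACorrelation:
    def test_identity_and_reversal(self):
        km = SimilarityMatrix(np.array([[1, .2, .5], [.2, 1, .8],
                                        [.5, .8, 1.]]))
        assert rsa.rsa_correlation(km, km) == pytest.approx(1.0)
        rev = SimilarityMatrix(1 - km.values)
        assert rsa.rsa_correlation(rev, km) == pytest.approx(-1.0)

    def test_4x4_hand_rank_oracle(self, rng):
        a_vals = rng.uniform(-1, 1, size=(4, 4))
        a_vals = (a_vals + a_vals.T) / 2
        b_vals = rng.uniform(-1, 1, size=(4, 4))
        b_vals = (b_vals + b_vals.T) / 2
        a, b = SimilarityMatrix(a_vals), SimilarityMatrix(b_vals)
        il = np.tril_indices(4, -1)
        ra = sps.rankdata(a_vals[il])
        rb = sps.rankdata(b_vals[il])
        expected = np.corrcoef(ra, rb)[0, 1]
        assert rsa.rsa_correlation(a, b) == pytest.approx(expected)

    def test_invariant_to_monotone_transform(self, small_cohort):
        cfg, ev, students, truth = small_cohort
        bm = rsa.subject_brain_matrix(0, students, ev, 1)
        km = truth.knowledge_matrix
        base = rsa.rsa_correlation(bm, km)
        warped = SimilarityMatrix(np.tanh(3 * bm.values), mask=bm.mask,
                                  kind="brain")
        assert rsa.rsa_correlation(warped, km) == pytest.approx(base)
        km_warp = SimilarityMatrix(np.exp(km.values) / np.e)
        assert rsa.rsa_correlation(bm, km_warp) == pytest.approx(base)


class TestPermutationNull:
    def test_p_formula_bounds(self, small_cohort):
        cfg, ev, students, truth = small_cohort
        emp, null, p = rsa.permutation_null(students[:4], ev,
                                            truth.knowledge_matrix, 1,
                                            n_perm=19, seed=3)
        assert 1 / 20 <= p <= 1.0
        assert p == pytest.approx((1 + np.sum(null >= emp)) / 20)

    def test_unknown_method_errors(self, small_cohort):
        cfg, ev, students, truth = small_cohort
        with pytest.raises(ConfigError):
            rsa.permutation_null(students, ev, truth.knowledge_matrix, 1,
                                 n_perm=5, method="bogus")

    def test_surrogates_destroy_embedded_structure(self, small_cohort):
        cfg, ev, students, truth = small_cohort
        emp, null, p = rsa.permutation_null(students, ev,
                                            truth.knowledge_matrix, 1,
                                            n_perm=60, seed=5)
        assert emp > null.mean() + 2 * null.std()


class TestFDR:
    def test_single_p(self):
        q, flags = rsa.fdr_correct([0.01])
        assert q[0] == pytest.approx(0.01)
        assert flags[0]

    def test_hand_step_up_22_channels(self):
        p = np.arange(1, 23) * 0.01
        q, flags = rsa.fdr_correct(p)
        # hand BH: q_i = min over j>=i of p_j * n / j (sorted order)
        n = 22
        hand = np.minimum.accumulate((p * n / np.arange(1, 23))[::-1])[::-1]
        np.testing.assert_allclose(q, hand, atol=1e-12)
        assert flags.sum() == (p <= (np.arange(1, 23) / n) * 0.05).nonzero(
            )[0].max() + 1 if flags.any() else True

    def test_all_ones_no_flags(self):
        q, flags = rsa.fdr_correct(np.ones(5))
        assert not flags.any()

    def test_invalid_p_errors(self):
        with pytest.raises(ConfigError):
            rsa.fdr_correct([0.0, 0.5])


class TestBoundaryEffect:
    def test_constant_signal_zero_difference(self):
        rec = Recording(data=np.full((1, 4000), 2.0), fs=10.0)
        ev = tiling_events(5, dur_s=40.0, start=30.0)
        b, nb = rsa.boundary_effect(rec, ev, 0, window_s=15, hrf_shift_s=6)
        assert b == pytest.approx(nb)

    def test_short_events_excluded_from_nonboundary_only(self):
        rec = Recording(data=np.zeros((1, 3000)), fs=10.0)
        onsets = np.array([30.0, 40.0, 90.0])
        offsets = np.array([40.0, 90.0, 140.0])
        ev = EventSet(onsets, offsets, ["a", "b", "c"], np.ones((3, 2)))
        x = rec.data[0]
        x[:] = 0.0
        res = rsa.group_boundary_effect([rec, rec, rec], ev, 0, window_s=15)
        assert res.n_nonboundary_events == 2       # the 10 s event drops out

    def test_no_eligible_events_errors(self):
        rec = Recording(data=np.zeros((1, 200)), fs=10.0)
        ev = EventSet([2.0], [8.0], ["a"], np.ones((1, 2)))
        with pytest.raises(ConfigError):
            rsa.boundary_effect(rec, ev, 0, window_s=15)

    def test_group_test_matches_textbook(self):
        d = [0.2, -0.1, 0.4, 0.3]
        res = rsa.group_boundary_test(d)
        assert isinstance(res, GroupTest)
        ref = sps.ttest_1samp(d, 0.0)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_degenerate_differences_flagged(self):
        res = rsa.group_boundary_test([1.0, 1.0, 1.0])
        assert res.degenerate
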