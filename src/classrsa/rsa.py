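"""Inter-subject event-level RSA, permutation nulls, FDR, boundary effect.

The brain representation of knowledge structure is built from *inter-subject*
event-pair correlations: for participants i and j, cell (m, n) is the mean of
corr(i's event-m series, j's event-n series) and corr(j's event m, i's event
n), which symmetrizes the matrix and avoids the aliasing effect of within-
subject hemodynamic autocorrelation. Event pairs of unequal duration are
truncated to the shorter series, anchored at event onset. Each subject's
brain matrix is the average of their N-1 pair matrices; RSA is the Spearman
correlation between the strictly-lower triangles of the brain and knowledge
matrices (on the intersection of their masks), averaged across subjects.

Significance comes from surrogate permutations of every subject's channel
time series (phase randomization by default) with
p = (1 + #{null >= empirical}) / (1 + n_perm), BH-FDR corrected across
channels at q < 0.05.

The heavy lifting is a closed-form batched computation of all truncated
event-pair correlations from one Gram matrix plus prefix sums of the
zero-padded event series; the test suite checks it cell-by-cell against
naive np.corrcoef loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import nulls, stats
from .types import ConfigError, EventSet, Recording, SimilarityMatrix

MIN_EVENT_SAMPLES = 3


# ---------------------------------------------------------------------------
# Event extraction


class EventSlicer:
    """Precomputed sample-index grid turning a 1-D series into a zero-padded
    (M, Lmax) event matrix; re-used across thousands of surrogates."""

    def __init__(self, event_set: EventSet, fs: float, n_samples: int,
                 shift_s: float = 0.0, strict: bool = True):
        i0 = np.round((event_set.onsets - shift_s) * fs).astype(int)
        i1 = np.round((event_set.offsets - shift_s) * fs).astype(int)
        outside = (i0 < 0) | (i1 > n_samples)
        if strict and outside.any():
            raise ConfigError("event (possibly lag-shifted) outside the "
                              "recording span")
        # non-strict: events overrunning the span are dropped whole (their
        # rows stay zero and their cells end up masked), not zero-padded
        self.valid = ~outside
        self.lengths = np.where(self.valid, i1 - i0, 0)
        i0 = np.clip(i0, 0, n_samples - 1)
        lmax = int(max(self.lengths.max(), 1))
        self.idx = np.minimum(i0[:, None] + np.arange(lmax)[None, :],
                              n_samples - 1)
        self.pad = np.arange(lmax)[None, :] < self.lengths[:, None]

    def slice(self, series: np.ndarray) -> np.ndarray:
        return np.where(self.pad, series[self.idx], 0.0)

    def slice_batch(self, series: np.ndarray) -> np.ndarray:
        """(N, T) series -> (N, M, Lmax) zero-padded event stacks."""
        return np.where(self.pad[None], series[:, self.idx], 0.0)


def extract_event_series(recording: Recording, event_set: EventSet,
                         channel: int) -> list[np.ndarray]:
    """One 1-D series per event from ``channel``; lengths = duration x fs."""
    fs = recording.fs
    out = []
    for on, off in zip(event_set.onsets, event_set.offsets):
        i0, i1 = int(round(on * fs)), int(round(off * fs))
        if i0 < 0 or i1 > recording.n_samples:
            raise ConfigError(f"event ({on}, {off}) s outside recording span")
        out.append(recording.data[channel, i0:i1].copy())
    return out


# ---------------------------------------------------------------------------
# Truncated pairwise correlations


def truncated_corr(e: np.ndarray, len_e: np.ndarray,
                   f: Optional[np.ndarray] = None,
                   len_f: Optional[np.ndarray] = None,
                   min_len: int = MIN_EVENT_SAMPLES) -> np.ndarray:
    """All-pairs Pearson correlations between zero-padded rows of ``e`` and
    ``f``, each pair truncated to the shorter row's prefix.

    Zero padding makes the Gram matrix equal the truncated cross-products;
    prefix sums supply the truncated means and variances. Cells shorter than
    ``min_len`` samples, or with zero variance, are NaN.
    """
    if f is None:
        f, len_f = e, len_e
    le = np.asarray(len_e, dtype=int)
    lf = np.asarray(len_f, dtype=int)
    if le.max(initial=0) > e.shape[1] or lf.max(initial=0) > f.shape[1]:
        raise ConfigError("row lengths exceed the padded width")
    lmax = max(e.shape[1], f.shape[1])
    if e.shape[1] < lmax:
        e = np.pad(e, ((0, 0), (0, lmax - e.shape[1])))
    if f.shape[1] < lmax:
        f = np.pad(f, ((0, 0), (0, lmax - f.shape[1])))
    el = np.minimum.outer(le, lf).astype(float)           # (R1, R2)
    p = e @ f.T
    ce, cqe = np.cumsum(e, axis=1), np.cumsum(e * e, axis=1)
    cf, cqf = np.cumsum(f, axis=1), np.cumsum(f * f, axis=1)
    use_e = le[:, None] <= lf[None, :]    # row of e is the shorter one
    se = np.where(use_e, ce[:, -1][:, None], ce[:, lf - 1])
    qe = np.where(use_e, cqe[:, -1][:, None], cqe[:, lf - 1])
    sf = np.where(use_e, cf[:, le - 1].T, cf[:, -1][None, :])
    qf = np.where(use_e, cqf[:, le - 1].T, cqf[:, -1][None, :])
    ve = qe - se * se / el
    vf = qf - sf * sf / el
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (p - se * sf / el) / np.sqrt(ve * vf)
    c[(el < min_len) | (ve <= 0) | (vf <= 0)] = np.nan
    return c


def pair_brain_matrix(rec_i: Recording, rec_j: Recording,
                      event_set: EventSet, channel: int) -> SimilarityMatrix:
    """Symmetric inter-subject event matrix for one participant pair."""
    sl = EventSlicer(event_set, rec_i.fs, min(rec_i.n_samples,
                                              rec_j.n_samples))
    ei = sl.slice(rec_i.data[channel])
    ej = sl.slice(rec_j.data[channel])
    c = truncated_corr(ei, sl.lengths, ej, sl.lengths)
    sym = (c + c.T) / 2.0
    mask = np.isfinite(sym)
    np.fill_diagonal(mask, False)                 # diagonal ignored
    return SimilarityMatrix(np.where(mask, sym, 0.0), mask=mask, kind="brain")


def cohort_pair_matrices(event_stacks: np.ndarray,
                         lengths: np.ndarray) -> np.ndarray:
    """Symmetrized pair matrices (G, M, M) for all subject pairs (i < j) from
    stacked (N, M, Lmax) event matrices, via one Gram-matrix pass."""
    n, m, _ = event_stacks.shape
    x = event_stacks.reshape(n * m, -1)
    c = truncated_corr(x, np.tile(lengths, n))
    blocks = c.reshape(n, m, n, m).swapaxes(1, 2)       # (N, N, M, M)
    ii, jj = np.triu_indices(n, k=1)
    b = blocks[ii, jj]
    return (b + b.transpose(0, 2, 1)) / 2.0


def subject_matrices_from_pairs(pair_mats: np.ndarray,
                                n_subjects: int) -> np.ndarray:
    """Per-subject (N, M, M) brain matrices: mean of each subject's N-1 pair
    matrices (NaN cells ignored cellwise)."""
    if n_subjects < 2:
        raise ConfigError("need at least 2 subjects")
    m = pair_mats.shape[1]
    ii, jj = np.triu_indices(n_subjects, k=1)
    ok = np.isfinite(pair_mats)
    vals = np.where(ok, pair_mats, 0.0)
    acc = np.zeros((n_subjects, m, m))
    cnt = np.zeros((n_subjects, m, m))
    np.add.at(acc, ii, vals)
    np.add.at(acc, jj, vals)
    np.add.at(cnt, ii, ok)
    np.add.at(cnt, jj, ok)
    with np.errstate(invalid="ignore"):
        out = acc / cnt
    out[cnt == 0] = np.nan
    return out


def subject_brain_matrix(subject: int, recordings: Sequence[Recording],
                         event_set: EventSet, channel: int
                         ) -> SimilarityMatrix:
    """Mean of one subject's pair matrices with every other cohort member."""
    n = len(recordings)
    if n < 2:
        raise ConfigError("need a cohort of at least 2")
    mats = [pair_brain_matrix(recordings[subject], recordings[j], event_set,
                              channel)
            for j in range(n) if j != subject]
    m = mats[0].n
    acc = np.zeros((m, m))
    cnt = np.zeros((m, m))
    for sm in mats:
        acc[sm.mask] += sm.values[sm.mask]
        cnt += sm.mask
    with np.errstate(invalid="ignore"):
        vals = acc / cnt
    mask = cnt > 0
    np.fill_diagonal(mask, False)
    return SimilarityMatrix(np.where(mask, vals, 0.0), mask=mask,
                            kind="brain")


# ---------------------------------------------------------------------------
# RSA statistics


def rsa_correlation(brain: SimilarityMatrix, knowledge: SimilarityMatrix,
                    min_cells: int = 3) -> float:
    """Spearman rho over jointly masked strictly-lower-triangle cells."""
    return stats.spearman_masked(brain, knowledge, min_cells=min_cells)


def _subject_matrices_fused(event_stacks: np.ndarray,
                            lengths: np.ndarray) -> np.ndarray:
    """Per-subject (N, M, M) brain matrices straight from one Gram pass:
    symmetrized pair blocks summed over partners, self-block excluded."""
    n, m, _ = event_stacks.shape
    c = truncated_corr(event_stacks.reshape(n * m, -1), np.tile(lengths, n))
    blocks = c.reshape(n, m, n, m).swapaxes(1, 2)       # (N, N, M, M)
    sym = (blocks + blocks.transpose(0, 1, 3, 2)) / 2.0
    ok = np.isfinite(sym)
    vals = np.where(ok, sym, 0.0)
    diag = np.arange(n)
    acc = vals.sum(axis=1) - vals[diag, diag]
    cnt = ok.sum(axis=1) - ok[diag, diag]
    with np.errstate(invalid="ignore"):
        out = acc / cnt
    out[cnt == 0] = np.nan
    return out


def _mean_rsa_from_stacks(event_stacks: np.ndarray, lengths: np.ndarray,
                          knowledge: SimilarityMatrix) -> float:
    """Cross-subject mean Spearman r for one channel; fast path used by the
    permutation loop (falls back to masked per-subject Spearman on NaNs)."""
    n = event_stacks.shape[0]
    subj = _subject_matrices_fused(event_stacks, lengths)
    rows, cols = np.tril_indices(knowledge.n, k=-1)
    ok = knowledge.mask[rows, cols]
    vecs = subj[:, rows[ok], cols[ok]]
    kv = knowledge.values[rows[ok], cols[ok]]
    if np.all(np.isfinite(vecs)):
        rs = stats.spearman_rows(vecs, np.broadcast_to(kv, vecs.shape))
    else:
        rs = []
        for i in range(n):
            mask = np.zeros_like(knowledge.mask)
            fin = np.isfinite(subj[i])
            bm = SimilarityMatrix(np.where(fin, subj[i], 0.0),
                                  mask=fin, kind="brain")
            rs.append(rsa_correlation(bm, knowledge))
        rs = np.array(rs)
    return float(np.mean(rs))


def channel_mean_rsa(recordings: Sequence[Recording], event_set: EventSet,
                     knowledge: SimilarityMatrix, channel: int) -> float:
    """Empirical cross-subject mean RSA r for one channel."""
    sl = EventSlicer(event_set, recordings[0].fs,
                     min(r.n_samples for r in recordings))
    stacks = np.stack([sl.slice(r.data[channel]) for r in recordings])
    return _mean_rsa_from_stacks(stacks, sl.lengths, knowledge)


def permutation_null(recordings: Sequence[Recording], event_set: EventSet,
                     knowledge: SimilarityMatrix, channel: int,
                     n_perm: int = 1000, method: str = "phase_randomize",
                     seed: int | np.random.SeedSequence = 0,
                     dtype=np.float64):
    """Surrogate null of the cross-subject mean RSA r for one channel.

    Every subject's full channel series is surrogate-transformed per
    iteration (independent draws per subject), the whole matrix pipeline is
    recomputed, and the one-tailed p follows the (1 + #) / (1 + n) rule.
    ``dtype=np.float32`` halves the cost of the Gram-matrix passes (the
    statistic is a rank correlation, insensitive at that precision).
    Returns (empirical_r, null_array, p).
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    if method not in nulls.METHODS:
        raise ConfigError(f"unknown surrogate method {method!r}")
    rng = np.random.default_rng(seed)
    n_samples = min(r.n_samples for r in recordings)
    sl = EventSlicer(event_set, recordings[0].fs, n_samples)
    series = np.stack([r.data[channel, :n_samples] for r in recordings]
                      ).astype(dtype)
    emp = _mean_rsa_from_stacks(sl.slice_batch(series), sl.lengths,
                                knowledge)
    null = np.empty(n_perm)
    for it in range(n_perm):
        if method == "phase_randomize":
            surr = nulls.phase_randomize(series, rng).astype(dtype)
        else:
            surr = np.stack([nulls.surrogate(s, method, rng)
                             for s in series]).astype(dtype)
        null[it] = _mean_rsa_from_stacks(sl.slice_batch(surr), sl.lengths,
                                         knowledge)
    return emp, null, nulls.permutation_pvalue(emp, null)


def fdr_correct(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up: returns (q_values, significant flags)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ConfigError("p-values must lie in (0, 1]")
    flags, qvals, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, flags


@dataclass
class RSAResult:
    channels: np.ndarray
    r: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": self.channels, "r": self.r,
                             "p": self.p, "q": self.q,
                             "significant": self.significant})


def rsa_analysis(recordings: Sequence[Recording], event_set: EventSet,
                 knowledge: SimilarityMatrix,
                 channels: Optional[Sequence[int]] = None,
                 n_perm: int = 1000, method: str = "phase_randomize",
                 q: float = 0.05,
                 seed: int | np.random.SeedSequence = 0) -> RSAResult:
    """Per-channel mean RSA r with permutation p and BH-FDR q across
    channels."""
    if channels is None:
        channels = range(recordings[0].n_channels)
    channels = np.asarray(list(channels))
    ss = np.random.SeedSequence(seed) if isinstance(seed, (int, np.integer)) \
        else seed
    kids = ss.spawn(len(channels))
    rs, ps = [], []
    for k, ch in enumerate(channels):
        emp, _, p = permutation_null(recordings, event_set, knowledge,
                                     int(ch), n_perm=n_perm, method=method,
                                     seed=kids[k])
        rs.append(emp)
        ps.append(p)
    qvals, flags = fdr_correct(np.array(ps), q=q)
    return RSAResult(channels=channels, r=np.array(rs), p=np.array(ps),
                     q=qvals, significant=flags)


# ---------------------------------------------------------------------------
# Boundary effect


@dataclass
class BoundaryResult:
    boundary_mean: np.ndarray        # per subject, z-units
    nonboundary_mean: np.ndarray
    difference: np.ndarray           # boundary - non-boundary
    group: Optional[stats.GroupTest] = None
    n_boundary_windows: int = 0
    n_nonboundary_events: int = 0


def boundary_effect(recording: Recording, event_set: EventSet, channel: int,
                    window_s: float = 15.0, hrf_shift_s: float = 6.0):
    """Boundary vs non-boundary mean activity for one subject.

    The boundary pattern averages the ``window_s`` seconds following each
    event offset; the non-boundary pattern averages the middle ``window_s``
    of each event. Both windows are shifted later by ``hrf_shift_s`` to
    account for the hemodynamic delay. Events shorter than the window are
    dropped from the non-boundary set only; windows overrunning the next
    event are kept (boundaries slide regardless); windows overrunning the
    recording end are dropped. Returns (boundary_mean, nonboundary_mean).
    """
    fs = recording.fs
    w = int(round(window_s * fs))
    shift = int(round(hrf_shift_s * fs))
    x = recording.data[channel]
    b_vals, nb_vals = [], []
    for on, off, dur in zip(event_set.onsets, event_set.offsets,
                            event_set.durations):
        b0 = int(round(off * fs)) + shift
        if b0 + w <= recording.n_samples:
            b_vals.append(x[b0:b0 + w].mean())
        if dur >= window_s:
            mid = (on + off) / 2.0
            n0 = int(round((mid - window_s / 2.0) * fs)) + shift
            if n0 >= 0 and n0 + w <= recording.n_samples:
                nb_vals.append(x[n0:n0 + w].mean())
    if not b_vals or not nb_vals:
        raise ConfigError("no eligible events for the boundary contrast")
    return float(np.mean(b_vals)), float(np.mean(nb_vals))


def group_boundary_effect(recordings: Sequence[Recording],
                          event_set: EventSet, channel: int,
                          window_s: float = 15.0,
                          hrf_shift_s: float = 6.0) -> BoundaryResult:
    """Per-subject boundary contrast plus the paired group test."""
    b, nb = [], []
    for rec in recordings:
        bi, nbi = boundary_effect(rec, event_set, channel, window_s,
                                  hrf_shift_s)
        b.append(bi)
        nb.append(nbi)
    b, nb = np.array(b), np.array(nb)
    res = BoundaryResult(boundary_mean=b, nonboundary_mean=nb,
                         difference=b - nb,
                         n_boundary_windows=len(b),
                         n_nonboundary_events=int(
                             np.sum(event_set.durations >= window_s)))
    if len(b) >= 3:
        res.group = group_boundary_test(res.difference)
    return res


def group_boundary_test(differences) -> stats.GroupTest:
    """Paired t on boundary vs non-boundary means, as a one-sample t on the
    per-subject differences, with Cohen's d and 95% CI."""
    return stats.one_sample_test(differences, 0.0)
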