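"""Time-lagged teacher-student representational synchronization.

For each (teacher channel, student channel, lag) grid cell, the teacher's
time series is shifted by the lag before event extraction (positive lag =
teacher precedes the students), the teacher's event-pair matrix is built
with the same inter-subject correlation machinery — teacher vs each
student, averaged over students — and Spearman-correlated with the
student-cohort mean brain matrix on that student channel. Significance is a
surrogate permutation of the students' signals with BH-FDR across the full
grid (all channel pairs x all lags).

A teacher-autocorrelation variant of the teacher matrix (the teacher's own
event pairs) is available behind ``against="self"`` but is non-default:
within-subject hemodynamic autocorrelation aliases into such a matrix, which
is exactly what the inter-subject construction avoids.

Lag grid convention: lags below 6 s in magnitude are excluded by the default
grid (the reported synchronization window is 6-14 s in 2 s steps, both
directions); the grid is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import nulls, stats
from .rsa import EventSlicer, fdr_correct, truncated_corr
from .types import ConfigError, EventSet, Recording, SimilarityMatrix


def default_lags(lo: float = 6.0, hi: float = 14.0, step: float = 2.0,
                 both_directions: bool = True) -> np.ndarray:
    """Lag grid {+lo..+hi} (and mirrored negatives) in ``step`` s steps."""
    pos = np.arange(lo, hi + step / 2, step)
    if not both_directions:
        return pos
    return np.concatenate([-pos[::-1], pos])


def _sym_mean_teacher_matrix(et: np.ndarray, lengths_t: np.ndarray,
                             valid_t: np.ndarray,
                             student_stacks: np.ndarray,
                             lengths_s: np.ndarray) -> SimilarityMatrix:
    """Teacher event matrix: teacher-vs-each-student correlations averaged
    over students, symmetrized; invalid (lag-truncated) events masked out."""
    n, m, _ = student_stacks.shape
    acc = np.zeros((m, m))
    cnt = np.zeros((m, m))
    for i in range(n):
        c = truncated_corr(et, lengths_t, student_stacks[i], lengths_s)
        c = (c + c.T) / 2.0
        ok = np.isfinite(c)
        acc[ok] += c[ok]
        cnt += ok
    with np.errstate(invalid="ignore"):
        vals = acc / cnt
    mask = (cnt > 0) & np.outer(valid_t, valid_t)
    np.fill_diagonal(mask, False)
    return SimilarityMatrix(np.where(mask, vals, 0.0), mask=mask,
                            kind="brain")


def lagged_teacher_matrix(teacher: Recording, students: Sequence[Recording],
                          event_set: EventSet, teacher_channel: int,
                          student_channel: int, lag_s: float,
                          against: str = "cohort") -> SimilarityMatrix:
    """Teacher's event-pair matrix at one lag.

    Positive ``lag_s`` means the teacher's activity precedes the students':
    the teacher's series is read ``lag_s`` seconds earlier than each event's
    nominal span. Events whose shifted window leaves the recording are
    dropped (masked), not zero-padded.
    """
    fs = teacher.fs
    sl_t = EventSlicer(event_set, fs, teacher.n_samples, shift_s=lag_s,
                       strict=False)
    et = sl_t.slice(teacher.data[teacher_channel])
    if against == "self":
        c = truncated_corr(et, sl_t.lengths)
        sym = (c + c.T) / 2.0
        mask = np.isfinite(sym) & np.outer(sl_t.valid, sl_t.valid)
        np.fill_diagonal(mask, False)
        return SimilarityMatrix(np.where(mask, sym, 0.0), mask=mask,
                                kind="brain")
    if against != "cohort":
        raise ConfigError("against must be 'cohort' or 'self'")
    n_samples = min(r.n_samples for r in students)
    sl_s = EventSlicer(event_set, fs, n_samples)
    stacks = np.stack([sl_s.slice(r.data[student_channel])
                       for r in students])
    return _sym_mean_teacher_matrix(et, sl_t.lengths, sl_t.valid, stacks,
                                    sl_s.lengths)


def _cohort_mean_matrix(stacks: np.ndarray,
                        lengths: np.ndarray) -> SimilarityMatrix:
    """Cross-student mean brain matrix on one channel (mean of per-student
    matrices, equivalently of all symmetrized pair matrices)."""
    from .rsa import cohort_pair_matrices
    pair_mats = cohort_pair_matrices(stacks, lengths)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(pair_mats, axis=0)
    mask = np.isfinite(mean)
    np.fill_diagonal(mask, False)
    return SimilarityMatrix(np.where(mask, mean, 0.0), mask=mask,
                            kind="brain")


@dataclass
class SyncResult:
    table: pd.DataFrame          # t_ch, s_ch, lag_s, r, p, q, significant

    def peak(self) -> pd.Series:
        return self.table.loc[self.table["r"].idxmax()]

    def to_frame(self) -> pd.DataFrame:
        return self.table


def sync_grid(teacher: Recording, students: Sequence[Recording],
              event_set: EventSet,
              teacher_channels: Optional[Sequence[int]] = None,
              student_channels: Optional[Sequence[int]] = None,
              lags_s: Optional[np.ndarray] = None,
              n_perm: int = 0, method: str = "phase_randomize",
              q: float = 0.05,
              seed: int | np.random.SeedSequence = 0) -> SyncResult:
    """Spearman r over the (teacher ch x student ch x lag) grid, with an
    optional student-signal surrogate permutation test and BH-FDR across the
    whole grid. ``n_perm=0`` skips inference (r only, p/q NaN).
    """
    if len(students) < 2:
        raise ConfigError("need a teacher plus at least 2 students")
    if teacher_channels is None:
        teacher_channels = range(teacher.n_channels)
    if student_channels is None:
        student_channels = range(students[0].n_channels)
    teacher_channels = list(teacher_channels)
    student_channels = list(student_channels)
    lags = default_lags() if lags_s is None else np.asarray(lags_s,
                                                            dtype=float)
    fs = teacher.fs
    n_samples = min(r.n_samples for r in students)
    sl_s = EventSlicer(event_set, fs, n_samples)
    series_s = {ch: np.stack([r.data[ch, :n_samples] for r in students])
                for ch in student_channels}

    def grid_r(student_series: dict) -> np.ndarray:
        stacks = {ch: np.stack([sl_s.slice(x) for x in student_series[ch]])
                  for ch in student_channels}
        cohort = {ch: _cohort_mean_matrix(stacks[ch], sl_s.lengths)
                  for ch in student_channels}
        out = np.empty((len(teacher_channels), len(student_channels),
                        len(lags)))
        for il, lag in enumerate(lags):
            sl_t = EventSlicer(event_set, fs, teacher.n_samples,
                               shift_s=float(lag), strict=False)
            for it, tch in enumerate(teacher_channels):
                et = sl_t.slice(teacher.data[tch])
                for isc, sch in enumerate(student_channels):
                    tm = _sym_mean_teacher_matrix(et, sl_t.lengths,
                                                  sl_t.valid, stacks[sch],
                                                  sl_s.lengths)
                    try:
                        out[it, isc, il] = stats.spearman_masked(
                            tm, cohort[sch])
                    except ConfigError:
                        out[it, isc, il] = np.nan
        return out

    emp = grid_r(series_s)
    p = np.full(emp.shape, np.nan)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(emp.shape)
        for _ in range(n_perm):
            surr = {ch: np.stack([nulls.surrogate(x, method, rng)
                                  for x in series_s[ch]])
                    for ch in student_channels}
            exceed += grid_r(surr) >= emp
        p = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for it, tch in enumerate(teacher_channels):
        for isc, sch in enumerate(student_channels):
            for il, lag in enumerate(lags):
                rows.append({"t_ch": tch, "s_ch": sch, "lag_s": float(lag),
                             "r": emp[it, isc, il], "p": p[it, isc, il]})
    table = pd.DataFrame(rows)
    if n_perm > 0:
        qvals, flags = fdr_correct(table["p"].to_numpy(), q=q)
        table["q"] = qvals
        table["significant"] = flags
    else:
        table["q"] = np.nan
        table["significant"] = False
    return SyncResult(table=table)


def peak_lag(result: SyncResult) -> float:
    """Lag (s) of the grid-wide maximum correlation."""
    return float(result.peak()["lag_s"])
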