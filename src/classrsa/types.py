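"""Core containers shared across the analysis stages.

Conventions: time in seconds, 0-based sample indexing, half-open event
intervals [onset, offset). Similarity matrices are event x event with an
explicit boolean availability mask (True = cell usable); symmetry is
required wherever both of a cell and its transpose are masked in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np


class ConfigError(ValueError):
    """Invalid configuration or degenerate input."""


# ---------------------------------------------------------------------------
# Events


@dataclass
class EventSet:
    """Ordered, non-overlapping knowledge events with semantic vectors.

    Parameters
    ----------
    onsets, offsets : arrays of seconds, half-open intervals [onset, offset).
    event_ids : per-event identifiers (kept through recall subsetting so that
        recalled-event matrices stay index-aligned with the original events).
    topic_vectors : (M, K) nonnegative semantic vectors, or None when events
        carry timing only.
    phase : label of the teaching phase the events belong to.
    """

    onsets: np.ndarray
    offsets: np.ndarray
    event_ids: np.ndarray
    topic_vectors: Optional[np.ndarray] = None
    phase: str = "lecturing"

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.event_ids = np.asarray(self.event_ids)
        if self.onsets.shape != self.offsets.shape or self.onsets.ndim != 1:
            raise ConfigError("onsets/offsets must be matching 1-D arrays")
        if np.any(self.offsets <= self.onsets):
            bad = np.nonzero(self.offsets <= self.onsets)[0].tolist()
            raise ConfigError(f"events with non-positive duration at rows {bad}")
        if np.any(np.diff(self.onsets) < 0):
            raise ConfigError("events must be ordered by onset")
        if np.any(self.onsets[1:] < self.offsets[:-1] - 1e-9):
            bad = np.nonzero(self.onsets[1:] < self.offsets[:-1] - 1e-9)[0]
            raise ConfigError(f"overlapping events at rows {bad.tolist()}")
        if self.topic_vectors is not None:
            tv = np.asarray(self.topic_vectors, dtype=float)
            if tv.shape[0] != self.n_events:
                raise ConfigError("one topic vector per event required")
            if not np.all(np.isfinite(tv)):
                raise ConfigError("topic vectors must be finite")
            if np.any(np.all(tv == 0, axis=1)):
                bad = np.nonzero(np.all(tv == 0, axis=1))[0]
                ids = self.event_ids[bad].tolist()
                raise ConfigError(f"all-zero topic vector for events {ids}")
            self.topic_vectors = tv

    @property
    def n_events(self) -> int:
        return int(self.onsets.size)

    @property
    def durations(self) -> np.ndarray:
        return self.offsets - self.onsets

    def shifted(self, dt_s: float) -> "EventSet":
        """Re-reference event times by ``dt_s`` seconds (e.g. after trimming)."""
        return replace(self, onsets=self.onsets + dt_s, offsets=self.offsets + dt_s)

    def subset(self, keep: np.ndarray) -> "EventSet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.nonzero(keep)[0]
        tv = None if self.topic_vectors is None else self.topic_vectors[keep]
        return EventSet(self.onsets[keep], self.offsets[keep], self.event_ids[keep],
                        tv, self.phase)


# ---------------------------------------------------------------------------
# Similarity matrices


@dataclass
class SimilarityMatrix:
    """Symmetric event x event similarity with an availability mask.

    kind is one of {"knowledge", "brain", "predicted", "recalled"}; the unit
    diagonal is enforced for knowledge matrices only (brain matrices ignore
    their diagonal by construction).
    """

    values: np.ndarray
    mask: Optional[np.ndarray] = None
    kind: str = "knowledge"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ConfigError("similarity matrix must be square")
        if self.mask is None:
            self.mask = np.ones(v.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != v.shape:
                raise ConfigError("mask shape must match values")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def lower_triangle(self, with_mask: "SimilarityMatrix | None" = None):
        """Strictly-lower-triangle values present in this (and optionally a
        second) matrix's mask. Returns (values, flat row/col indices)."""
        rows, cols = np.tril_indices(self.n, k=-1)
        ok = self.mask[rows, cols]
        if with_mask is not None:
            if with_mask.n != self.n:
                raise ConfigError("matrices must share event dimension")
            ok = ok & with_mask.mask[rows, cols]
        return self.values[rows[ok], cols[ok]], (rows[ok], cols[ok])

    def symmetrized(self) -> "SimilarityMatrix":
        return replace(self, values=(self.values + self.values.T) / 2.0,
                       mask=self.mask & self.mask.T)


# ---------------------------------------------------------------------------
# Recordings


@dataclass
class QCReport:
    """Per-channel artifact summary and the resulting exclusion decisions."""

    artifact_fraction: np.ndarray          # (C,), fraction of flagged samples
    bad_channels: np.ndarray               # (C,) bool
    artifact_mask: np.ndarray              # (C, T) bool, True = artifact sample
    exclude_subject: bool = False
    bad_channel_threshold: float = 0.05
    subject_threshold: float = 0.30

    @property
    def bad_fraction(self) -> float:
        return float(np.mean(self.bad_channels))


@dataclass
class Recording:
    """One participant's channel x time HbO matrix at a fixed sampling rate."""

    data: np.ndarray                       # (C, T)
    fs: float
    subject_id: str = "s0"
    role: str = "student"                  # {"student", "teacher"}
    channel_labels: Optional[list] = None
    phases: dict = field(default_factory=dict)   # name -> (start_s, end_s)
    qc: Optional[QCReport] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigError("recording data must be (channels, time)")
        if self.fs <= 0:
            raise ConfigError("sampling rate must be positive")
        if self.role not in ("student", "teacher"):
            raise ConfigError(f"unknown role {self.role!r}")
        if self.channel_labels is None:
            self.channel_labels = [f"CH{i + 1}" for i in range(self.n_channels)]
        if not self.phases:
            self.phases = {"session": (0.0, self.duration_s)}

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def with_data(self, data: np.ndarray, **kw) -> "Recording":
        return replace(self, data=np.asarray(data, dtype=float), **kw)

    def sample_index(self, t_s: float) -> int:
        return int(round(t_s * self.fs))


# ---------------------------------------------------------------------------
# Recall


@dataclass
class RecallRecord:
    """One student's binary recall vector plus the similarity matrix of the
    events they actually recalled (masked to recalled x recalled cells)."""

    student_id: str
    recalled: np.ndarray                   # (M,) bool
    matrix: SimilarityMatrix               # kind="recalled"

    def __post_init__(self) -> None:
        self.recalled = np.asarray(self.recalled, dtype=bool)
        if self.matrix.n != self.recalled.size:
            raise ConfigError("recall matrix must cover all original events")

    @property
    def n_recalled(self) -> int:
        return int(self.recalled.sum())
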