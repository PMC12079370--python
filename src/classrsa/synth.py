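"""Synthetic classroom fNIRS cohorts with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume, so every stage can be tested by parameter recovery:

- a session tiled by ordered knowledge events whose semantic topic vectors
  (Dirichlet draws) define a cosine knowledge matrix;
- on one designated channel (``embed_channel``) each event carries a mixture
  of K shared, smooth topic-basis time courses weighted by that event's
  topic vector, so the expected inter-subject correlation between two
  events' signals increases with their semantic cosine similarity; the
  mixing strength ``embed_strength`` (rho) sets the shared-signal variance
  fraction;
- every channel carries unit-variance AR(1) noise plus a shared global
  "physiological" time course with per-channel random gain (what the PCA
  step is meant to remove);
- a canonical double-gamma hemodynamic transient of amplitude
  ``boundary_amp`` is added at each event offset on the embed channel
  (a channel-specific neural boundary response, deliberately not a global
  spatial component);
- a teacher recording carries the same embedded event structure shifted
  *earlier* by ``teacher_lead`` seconds, so lag-resolved synchronization
  analyses should peak at a positive lag equal to the lead.

Topic bases are defined on event-local time (time since event onset) and
shared across events and participants; that is what makes the truncated
inter-subject event-pair correlations track the mixing-weight overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as spsig

from .knowledge import cosine_knowledge_matrix
from .types import ConfigError, EventSet, RecallRecord, Recording, SimilarityMatrix

# Internal sub-stream tags so basis / global / subject noise are independent.
_BASIS_TAG = 101
_GLOBAL_TAG = 211
_SUBJECT_TAG = 307


@dataclass
class SynthConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the classroom study the generator emulates: 10 Hz HbO
    sampling, 22 channels, ~21 students, 26 lecture events of 6-200 s.
    """

    n_students: int = 21
    n_channels: int = 22
    n_events: int = 26
    n_topics: int = 8
    fs: float = 10.0
    duration_range: tuple = (6.0, 200.0)
    concentration: float = 0.3
    embed_channel: int = 2
    embed_strength: float = 0.5          # rho, shared-signal variance fraction
    boundary_amp: float = 1.0            # z-units at the transient peak
    boundary_location: str = "offset"    # "offset" | "middle" (control)
    teacher_lead: float = 8.0            # seconds the teacher precedes students
    noise_ar: float = 0.8                # AR(1) coefficient of channel noise
    global_amp: float = 1.0              # z-units of the shared component
    student_distortion: float = 0.0      # per-student topic-vector resampling
    pad_s: float = 30.0                  # silence before/after the event span
    basis_cutoff_hz: float = 0.2         # low-pass cutoff of topic bases
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if not (0.0 <= self.embed_strength <= 1.0):
            raise ConfigError("embed_strength must lie in [0, 1]")
        if not (0.0 <= self.noise_ar < 1.0):
            raise ConfigError("noise_ar must lie in [0, 1)")
        lo, hi = self.duration_range
        if lo < 6.0 or hi < lo:
            raise ConfigError("duration_range must satisfy 6 <= min <= max")
        if not (0 <= self.embed_channel < self.n_channels):
            raise ConfigError("embed_channel out of range")
        if self.teacher_lead < 0:
            raise ConfigError("teacher_lead must be non-negative")
        if self.teacher_lead > self.pad_s:
            raise ConfigError(
                "teacher_lead exceeds the leading pad; the shifted embedded "
                "signal would fall outside the recording")


@dataclass
class GroundTruth:
    """What the generator knows and the analyses are asked to recover."""

    event_set: EventSet
    knowledge_matrix: SimilarityMatrix
    config: SynthConfig
    basis: np.ndarray                            # (K, Lmax) topic bases
    global_series: np.ndarray                    # (T,) shared component
    student_vectors: Optional[np.ndarray] = None  # (N, M, K) distorted weights
    artifact_masks: dict = field(default_factory=dict)   # subject -> (C, T) bool
    recall_truth: dict = field(default_factory=dict)     # subject -> (M,) bool


# ---------------------------------------------------------------------------
# Events and semantics


def _distort_vectors(vectors: np.ndarray, distortion: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Dirichlet resampling around each vector; distortion 0 is the identity,
    larger values concentrate less (alpha = v / distortion)."""
    if distortion == 0:
        return vectors.copy()
    if distortion < 0:
        raise ConfigError("distortion must be non-negative")
    alpha = np.maximum(vectors, 1e-8) / distortion
    return np.vstack([rng.dirichlet(a) for a in alpha])


def make_event_set(n_events: int, n_topics: int,
                   duration_range: tuple = (6.0, 200.0),
                   concentration: float = 0.3,
                   seed: int | np.random.SeedSequence = 0,
                   start_s: float = 0.0,
                   phase: str = "lecturing") -> EventSet:
    """Ordered non-overlapping events tiling the session from ``start_s``.

    Durations are drawn log-uniformly within ``duration_range`` (for the
    default 6-200 s range this gives a mean near 55 s, matching the skewed
    durations of hand-segmented lecture events). Per-event topic vectors are
    Dirichlet draws with symmetric ``concentration``; ``concentration=inf``
    yields identical (uniform) vectors for every event.
    """
    if n_events < 3:
        raise ConfigError("need at least 3 events")
    lo, hi = duration_range
    if lo <= 0 or hi < lo:
        raise ConfigError("durations must be positive with min <= max")
    rng = np.random.default_rng(seed)
    durations = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_events))
    offsets = start_s + np.cumsum(durations)
    onsets = offsets - durations
    if np.isinf(concentration):
        vectors = np.full((n_events, n_topics), 1.0 / n_topics)
    else:
        if concentration <= 0:
            raise ConfigError("concentration must be positive")
        vectors = rng.dirichlet(np.full(n_topics, concentration),
                                size=n_events)
    ids = np.array([f"E{i + 1:02d}" for i in range(n_events)])
    return EventSet(onsets, offsets, ids, vectors, phase=phase)


# ---------------------------------------------------------------------------
# Signal building blocks


def double_gamma_hrf(fs: float, duration_s: float = 30.0,
                     peak_s: float = 6.0, undershoot_s: float = 16.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1."""
    t = np.arange(0, duration_s, 1.0 / fs)
    from scipy.stats import gamma as gamma_dist
    h = (gamma_dist.pdf(t, peak_s) - gamma_dist.pdf(t, undershoot_s) / ratio)
    return h / h.max()


def _smooth_noise(shape, cutoff_hz: float, fs: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Low-pass-filtered white noise, z-scored per row: smooth series that
    survive a 0.01-0.5 Hz band-pass."""
    w = rng.standard_normal(shape)
    b, a = spsig.butter(3, cutoff_hz / (fs / 2.0), btype="low")
    s = spsig.filtfilt(b, a, w, axis=-1)
    s = s - s.mean(axis=-1, keepdims=True)
    sd = s.std(axis=-1, keepdims=True)
    return s / np.where(sd == 0, 1.0, sd)


def _ar1_noise(shape, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary unit-variance AR(1) noise."""
    w = rng.standard_normal(shape) * np.sqrt(max(1.0 - phi * phi, 1e-12))
    return spsig.lfilter([1.0], [1.0, -phi], w, axis=-1)


def topic_basis(config: SynthConfig, event_set: EventSet) -> np.ndarray:
    """The K shared topic-basis time courses on event-local time, (K, Lmax).

    Deterministic in ``config.seed`` alone, so separately simulated
    recordings of the same cohort share the same bases.
    """
    lmax = int(np.ceil(event_set.durations.max() * config.fs)) + 1
    rng = np.random.default_rng([config.seed, _BASIS_TAG])
    return _smooth_noise((config.n_topics, lmax), config.basis_cutoff_hz,
                         config.fs, rng)


def global_series(config: SynthConfig, n_samples: int) -> np.ndarray:
    """Shared slow 'physiological' component, deterministic in config.seed."""
    rng = np.random.default_rng([config.seed, _GLOBAL_TAG])
    return _smooth_noise((1, n_samples), 0.1, config.fs, rng)[0]


def _event_sample_bounds(event_set: EventSet, fs: float):
    i0 = np.round(event_set.onsets * fs).astype(int)
    i1 = np.round(event_set.offsets * fs).astype(int)
    return i0, i1


def embedded_event_signal(event_set: EventSet, basis: np.ndarray,
                          weights: np.ndarray, fs: float,
                          n_samples: int, shift_s: float = 0.0) -> np.ndarray:
    """Concatenated per-event basis mixtures, z-scored within each event.

    ``shift_s > 0`` places each event's signal earlier by that many seconds
    (the teacher lead). Samples outside every event stay zero.
    """
    out = np.zeros(n_samples)
    i0, i1 = _event_sample_bounds(event_set, fs)
    dshift = int(round(shift_s * fs))
    for m in range(event_set.n_events):
        ln = i1[m] - i0[m]
        s = weights[m] @ basis[:, :ln]
        sd = s.std()
        s = (s - s.mean()) / (sd if sd > 0 else 1.0)
        a = i0[m] - dshift
        if a < 0 or a + ln > n_samples:
            raise ConfigError("shifted event signal falls outside recording")
        out[a:a + ln] = s
    return out


# ---------------------------------------------------------------------------
# Recordings


def simulate_recording(event_set: EventSet, config: SynthConfig,
                       role: str = "student",
                       seed: int | np.random.SeedSequence = 0,
                       weights: Optional[np.ndarray] = None) -> Recording:
    """One participant's channel x time HbO recording.

    The embed channel carries sqrt(rho) * (event basis mixture) +
    sqrt(1-rho) * AR(1) noise; all channels carry AR(1) noise plus the shared
    global component with per-channel gain in [0.5, 1.5]; boundary transients
    sit on the embed channel at event offsets. ``role="teacher"`` shifts the
    embedded component earlier by ``teacher_lead`` seconds. ``weights``
    overrides the event topic vectors (used for per-student distortion).
    """
    config.validate()
    fs = config.fs
    n_samples = int(np.ceil((event_set.offsets[-1] + config.pad_s) * fs))
    if event_set.onsets[0] < config.pad_s - 1e-9:
        raise ConfigError("event span must start at or after pad_s")
    if config.teacher_lead * fs >= n_samples:
        raise ConfigError("teacher_lead exceeds recording length")

    rng = np.random.default_rng(seed if not isinstance(seed, (int, np.integer))
                                else [int(seed), _SUBJECT_TAG])
    basis = topic_basis(config, event_set)
    if weights is None:
        weights = event_set.topic_vectors
    shift = config.teacher_lead if role == "teacher" else 0.0
    s = embedded_event_signal(event_set, basis, weights, fs, n_samples,
                              shift_s=shift)

    rho = config.embed_strength
    data = _ar1_noise((config.n_channels, n_samples), config.noise_ar, rng)
    ch = config.embed_channel
    data[ch] = np.sqrt(rho) * s + np.sqrt(1.0 - rho) * data[ch]

    if config.global_amp != 0:
        g = global_series(config, n_samples)
        gains = rng.uniform(0.5, 1.5, size=config.n_channels)
        data += config.global_amp * gains[:, None] * g[None, :]

    if config.boundary_amp != 0:
        if config.boundary_location not in ("offset", "middle"):
            raise ConfigError("boundary_location must be 'offset' or "
                              "'middle'")
        h = config.boundary_amp * double_gamma_hrf(fs)
        i0_, i1 = _event_sample_bounds(event_set, fs)
        if config.boundary_location == "middle":
            i1 = (i0_ + i1) // 2          # control: transient mid-event
        for off in i1:
            a = off - int(round(shift * fs))
            seg = min(len(h), n_samples - a)
            if seg > 0:
                data[ch, a:a + seg] += h[:seg]

    sid = f"{'t' if role == 'teacher' else 's'}{rng.integers(1e6):06d}"
    return Recording(data=data, fs=fs, subject_id=sid, role=role,
                     phases={event_set.phase: (0.0, n_samples / fs)})


def simulate_cohort(config: SynthConfig, with_teacher: bool = False):
    """Events + student recordings (+ teacher) + ground truth for one cohort.

    One config seed fans out deterministically to per-subject child streams.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    kids = ss.spawn(config.n_students + 2)
    event_set = make_event_set(config.n_events, config.n_topics,
                               config.duration_range, config.concentration,
                               seed=kids[0], start_s=config.pad_s)
    km = cosine_knowledge_matrix(event_set)

    svecs = np.empty((config.n_students, config.n_events, config.n_topics))
    students = []
    for i in range(config.n_students):
        rng_i = np.random.default_rng(kids[i + 2])
        svecs[i] = _distort_vectors(event_set.topic_vectors,
                                    config.student_distortion, rng_i)
        rec = simulate_recording(event_set, config, role="student",
                                 seed=kids[i + 2], weights=svecs[i])
        rec.subject_id = f"s{i + 1:02d}"
        students.append(rec)

    teacher = None
    if with_teacher:
        teacher = simulate_recording(event_set, config, role="teacher",
                                     seed=kids[1])
        teacher.subject_id = "t01"

    n_samples = students[0].n_samples
    truth = GroundTruth(event_set=event_set, knowledge_matrix=km,
                        config=config,
                        basis=topic_basis(config, event_set),
                        global_series=global_series(config, n_samples),
                        student_vectors=svecs)
    if with_teacher:
        return event_set, students, teacher, truth
    return event_set, students, truth


# ---------------------------------------------------------------------------
# Artifacts


def inject_artifacts(recording: Recording, n_spikes: int, spike_amp: float,
                     seed: int | np.random.SeedSequence = 0,
                     channel: Optional[int] = None,
                     spike_width_s: float = 0.5):
    """Add square motion spikes and return (recording, truth mask).

    ``spike_amp`` is in units of the target channel's SD. With ``channel``
    None each spike lands on a random channel.
    """
    rng = np.random.default_rng(seed)
    width = max(1, int(round(spike_width_s * recording.fs)))
    mask = np.zeros(recording.data.shape, dtype=bool)
    if n_spikes == 0:
        return recording.with_data(recording.data.copy()), mask
    if n_spikes * width > recording.n_samples:
        raise ConfigError("spikes would cover more than the whole recording")
    data = recording.data.copy()
    baseline_sd = recording.data.std(axis=1)     # pre-injection scale
    # non-overlapping placement so n_spikes * width samples are hit exactly
    slots = rng.choice(recording.n_samples // width, size=n_spikes,
                       replace=False)
    for t0 in slots * width:
        c = channel if channel is not None else int(
            rng.integers(recording.n_channels))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        data[c, t0:t0 + width] += sign * spike_amp * baseline_sd[c]
        mask[c, t0:t0 + width] = True
    return recording.with_data(data), mask


# ---------------------------------------------------------------------------
# Recall


def simulate_recall(event_set: EventSet, recall_probs, distortion: float = 0.0,
                    seed: int | np.random.SeedSequence = 0,
                    n_students: Optional[int] = None) -> list[RecallRecord]:
    """Per-student binary recall vectors and recalled-event matrices.

    ``recall_probs`` is a scalar (shared probability, ``n_students`` sets the
    cohort size) or one probability per student. Each student's recalled
    similarity matrix is the cosine matrix of their (optionally distorted)
    topic vectors, masked to recalled x recalled event pairs.
    """
    probs = np.atleast_1d(np.asarray(recall_probs, dtype=float))
    if np.any((probs < 0) | (probs > 1)):
        raise ConfigError("recall probabilities must lie in [0, 1]")
    if probs.size == 1:
        if n_students is None:
            n_students = 1
        probs = np.full(n_students, probs[0])
    ss = np.random.SeedSequence(seed) if isinstance(seed, (int, np.integer)) \
        else seed
    kids = ss.spawn(probs.size)
    m = event_set.n_events
    records = []
    for i, p in enumerate(probs):
        rng = np.random.default_rng(kids[i])
        recalled = rng.random(m) < p
        vecs = _distort_vectors(event_set.topic_vectors, distortion, rng)
        sub = EventSet(event_set.onsets, event_set.offsets,
                       event_set.event_ids, vecs, phase="recalling")
        full = cosine_knowledge_matrix(sub)
        cell_mask = np.outer(recalled, recalled)
        mat = SimilarityMatrix(np.where(cell_mask, full.values, 0.0),
                               mask=cell_mask, kind="recalled")
        records.append(RecallRecord(student_id=f"s{i + 1:02d}",
                                    recalled=recalled, matrix=mat))
    return records
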