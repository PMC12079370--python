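"""Quality control and signal conditioning of HbO recordings.

Stage order is fixed: artifact detection on the raw pre-trim data ->
steady-state trim -> artifact interpolation -> spatial-PCA global-noise
removal -> zero-phase band-pass -> per-channel z-scoring. QC decisions
depend only on the raw data, so conditioning can never unflag a bad channel.

Numerical rules mirror standard wearable-fNIRS practice: artifacts are
samples beyond mean +/- 3 SD within 10 s windows; a channel is bad when more
than 5% of its samples are artifacts; a participant is excluded when more
than 30% of channels are bad; the first and last 15 s of each phase are
dropped; spatial principal components are removed up to 80% cumulative
variance; the band-pass is a zero-phase 3rd-order Butterworth at
0.01-0.5 Hz (phase distortion would bias the lag analyses downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as spsig

from .types import ConfigError, EventSet, QCReport, Recording


@dataclass
class PreprocessConfig:
    window_s: float = 10.0
    k_sd: float = 3.0
    bad_channel_threshold: float = 0.05
    subject_threshold: float = 0.30
    trim_s: float = 15.0
    pca_var_threshold: float = 0.80
    band_lo_hz: float = 0.01
    band_hi_hz: float = 0.5
    zscore_per_phase: bool = True
    window_stride_s: Optional[float] = None   # None = non-overlapping
    stages: tuple = ("detect", "trim", "interpolate", "pca", "bandpass",
                     "zscore")
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Artifact detection


def detect_artifacts(recording: Recording, window_s: float = 10.0,
                     k: float = 3.0, bad_channel_threshold: float = 0.05,
                     subject_threshold: float = 0.30,
                     stride_s: Optional[float] = None) -> QCReport:
    """Sliding-window outlier QC.

    Mean and SD are computed within ``window_s`` windows (non-overlapping by
    default; ``stride_s`` makes them overlap); samples beyond mean +/- k SD
    in their window are artifacts. A channel is bad when its artifact
    fraction exceeds ``bad_channel_threshold`` of the whole time course; the
    subject-exclusion flag trips when the bad-channel fraction exceeds
    ``subject_threshold``.
    """
    w = int(round(window_s * recording.fs))
    if w < 2 or w > recording.n_samples:
        raise ConfigError("QC window must fit inside the recording")
    stride = w if stride_s is None else max(1, int(round(stride_s
                                                         * recording.fs)))
    data = recording.data
    mask = np.zeros(data.shape, dtype=bool)
    for t0 in range(0, recording.n_samples, stride):
        seg = slice(t0, min(t0 + w, recording.n_samples))
        x = data[:, seg]
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            out = np.abs(x - mu) > k * sd
        # (near-)constant windows carry no artifact information
        out[sd[:, 0] <= 1e-12 * np.maximum(np.abs(mu[:, 0]), 1.0)] = False
        mask[:, seg] |= out
        if seg.stop == recording.n_samples:
            break
    frac = mask.mean(axis=1)
    bad = frac > bad_channel_threshold
    return QCReport(artifact_fraction=frac, bad_channels=bad,
                    artifact_mask=mask,
                    exclude_subject=bool(bad.mean() > subject_threshold),
                    bad_channel_threshold=bad_channel_threshold,
                    subject_threshold=subject_threshold)


def interpolate_artifacts(recording: Recording,
                          artifact_mask: np.ndarray) -> Recording:
    """Linear interpolation across flagged samples, per channel (the hook
    where a wavelet-based corrector could be substituted)."""
    data = recording.data.copy()
    t = np.arange(recording.n_samples)
    for c in range(recording.n_channels):
        bad = artifact_mask[c]
        if bad.any() and not bad.all():
            data[c, bad] = np.interp(t[bad], t[~bad], data[c, ~bad])
    return recording.with_data(data)


# ---------------------------------------------------------------------------
# Trimming


def trim_steady_state(recording: Recording, trim_s: float = 15.0,
                      event_set: Optional[EventSet] = None):
    """Drop the first and last ``trim_s`` seconds of the recording span and
    re-reference phase windows (and event onsets, if given).

    Returns the trimmed Recording, or (Recording, EventSet) when an event
    set is supplied. Events extending beyond the retained span raise.
    """
    n_trim = int(round(trim_s * recording.fs))
    if recording.n_samples <= 2 * n_trim:
        raise ConfigError(
            f"recording of {recording.duration_s:.1f}s too short to trim "
            f"{trim_s}s from both ends")
    data = recording.data[:, n_trim:recording.n_samples - n_trim]
    phases = {}
    for name, (a, b) in recording.phases.items():
        a2 = max(a - trim_s, 0.0)
        b2 = min(b - trim_s, data.shape[1] / recording.fs)
        if b2 <= a2:
            raise ConfigError(f"phase {name!r} shorter than 2*trim_s")
        phases[name] = (a2, b2)
    qc = recording.qc
    if qc is not None:
        qc = QCReport(artifact_fraction=qc.artifact_fraction,
                      bad_channels=qc.bad_channels,
                      artifact_mask=qc.artifact_mask[:, n_trim:n_trim
                                                     + data.shape[1]],
                      exclude_subject=qc.exclude_subject,
                      bad_channel_threshold=qc.bad_channel_threshold,
                      subject_threshold=qc.subject_threshold)
    out = recording.with_data(data, phases=phases, qc=qc)
    if event_set is None:
        return out
    shifted = event_set.shifted(-trim_s)
    if shifted.onsets[0] < -1e-9 or shifted.offsets[-1] > out.duration_s + 1e-9:
        raise ConfigError("events fall outside the trimmed span")
    return out, shifted


# ---------------------------------------------------------------------------
# Global-component removal


def remove_global_pca(recording: Recording, var_threshold: float = 0.80,
                      good_channels: Optional[np.ndarray] = None) -> Recording:
    """Project out the leading spatial principal components whose cumulative
    explained variance first reaches ``var_threshold``.

    The decomposition is spatial (across this participant's good channels),
    the cited convention for removing global physiological noise such as
    skin blood flow. Bad channels are left untouched.
    """
    if good_channels is None:
        good_channels = np.ones(recording.n_channels, dtype=bool) \
            if recording.qc is None else ~recording.qc.bad_channels
    good = np.asarray(good_channels, dtype=bool)
    if good.sum() < 2:
        raise ConfigError("need at least 2 good channels for PCA")
    x = recording.data[good]                       # (Cg, T)
    mu = x.mean(axis=1, keepdims=True)
    xc = x - mu
    # SVD of (T, Cg): columns of V are spatial components.
    u, s, vt = np.linalg.svd(xc.T, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        return recording.with_data(recording.data.copy())
    cum = np.cumsum(var) / total
    n_remove = int(np.searchsorted(cum, var_threshold) + 1)
    n_remove = min(n_remove, len(s))
    v = vt[:n_remove].T                            # (Cg, n_remove)
    resid = xc - (xc.T @ v @ v.T).T
    data = recording.data.copy()
    data[good] = resid + mu
    return recording.with_data(data)


# ---------------------------------------------------------------------------
# Filtering and scaling


def bandpass(recording: Recording, lo: float = 0.01, hi: float = 0.5,
             order: int = 3) -> Recording:
    """Zero-phase Butterworth band-pass (forward-backward), DC removed."""
    nyq = recording.fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ConfigError(f"band ({lo}, {hi}) invalid for fs={recording.fs}")
    sos = spsig.butter(order, [lo / nyq, hi / nyq], btype="band",
                       output="sos")
    data = spsig.sosfiltfilt(sos, recording.data, axis=-1)
    return recording.with_data(data)


def zscore(recording: Recording, per_phase: bool = True) -> Recording:
    """Each channel to mean 0, SD 1 over each phase span (or the whole
    retained span). Constant channels are zeroed and flagged bad in QC."""
    data = recording.data.copy()
    spans = list(recording.phases.values()) if per_phase \
        else [(0.0, recording.duration_s)]
    constant = np.zeros(recording.n_channels, dtype=bool)
    for a, b in spans:
        i0, i1 = recording.sample_index(a), recording.sample_index(b)
        i1 = min(i1, recording.n_samples)
        seg = data[:, i0:i1]
        mu = seg.mean(axis=1, keepdims=True)
        sd = seg.std(axis=1, keepdims=True)
        flat = sd[:, 0] <= 1e-12 * np.maximum(np.abs(mu[:, 0]), 1.0)
        constant |= flat
        sd[flat] = 1.0
        data[:, i0:i1] = (seg - mu) / sd
        data[flat, i0:i1] = 0.0
    qc = recording.qc
    if qc is not None and constant.any():
        qc.bad_channels = qc.bad_channels | constant
    out = recording.with_data(data)
    if qc is None and constant.any():
        out.qc = QCReport(artifact_fraction=np.zeros(recording.n_channels),
                          bad_channels=constant,
                          artifact_mask=np.zeros(data.shape, dtype=bool))
    return out


# ---------------------------------------------------------------------------
# Full pipeline


def preprocess_pipeline(recording: Recording,
                        config: Optional[PreprocessConfig] = None,
                        event_set: Optional[EventSet] = None):
    """detect -> trim -> interpolate -> PCA -> band-pass -> z-score.

    Returns (Recording, QCReport) or (Recording, EventSet, QCReport) when an
    event set is supplied. ``config.stages`` can drop conditioning stages
    (QC detection always runs); event count and order are preserved.
    """
    cfg = config or PreprocessConfig()
    qc = detect_artifacts(recording, cfg.window_s, cfg.k_sd,
                          cfg.bad_channel_threshold, cfg.subject_threshold,
                          stride_s=cfg.window_stride_s)
    rec = recording.with_data(recording.data.copy(), qc=qc)
    events = event_set
    if "trim" in cfg.stages:
        if events is not None:
            rec, events = trim_steady_state(rec, cfg.trim_s, events)
        else:
            rec = trim_steady_state(rec, cfg.trim_s)
    if "interpolate" in cfg.stages:
        rec = interpolate_artifacts(rec, rec.qc.artifact_mask)
    if "pca" in cfg.stages:
        rec = remove_global_pca(rec, cfg.pca_var_threshold)
    if "bandpass" in cfg.stages:
        rec = bandpass(rec, cfg.band_lo_hz, cfg.band_hi_hz)
    if "zscore" in cfg.stages:
        rec = zscore(rec, per_phase=cfg.zscore_per_phase)
    if event_set is None:
        return rec, qc
    return rec, events, qc
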