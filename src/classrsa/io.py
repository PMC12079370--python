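"""File formats: event tables, recordings, similarity matrices, results.

- Events: tab-separated (onset_s, duration_s, event_id), with an optional
  parallel topic-vector TSV (event_id + one column per topic dimension).
- Recordings: a documented NumPy ``.npz`` archive holding the channel x time
  HbO matrix plus metadata (subject_id, role, fs, channel labels, phase
  windows). Keys are stable and validated on read.
- Similarity matrices: TSV value grid with a parallel ``*.mask.tsv`` 0/1
  grid when any cell is unavailable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ConfigError, EventSet, Recording, SimilarityMatrix

_ARCHIVE_KEYS = ("data", "fs", "subject_id", "role", "channel_labels",
                 "phase_names", "phase_bounds")


# ---------------------------------------------------------------------------
# Events


def write_events(event_set: EventSet, path, vectors_path=None) -> None:
    df = pd.DataFrame({"onset_s": event_set.onsets,
                       "duration_s": event_set.durations,
                       "event_id": event_set.event_ids})
    df.to_csv(path, sep="\t", index=False)
    if vectors_path is not None:
        if event_set.topic_vectors is None:
            raise ConfigError("event set has no topic vectors to write")
        k = event_set.topic_vectors.shape[1]
        vdf = pd.DataFrame(event_set.topic_vectors,
                           columns=[f"topic_{i}" for i in range(k)])
        vdf.insert(0, "event_id", event_set.event_ids)
        vdf.to_csv(vectors_path, sep="\t", index=False)


def read_events(path, vectors_path=None, phase: str = "lecturing") -> EventSet:
    df = pd.read_csv(path, sep="\t")
    required = {"onset_s", "duration_s", "event_id"}
    if not required.issubset(df.columns):
        raise ConfigError(f"event table must have columns {sorted(required)}")
    bad = df.index[df["duration_s"] <= 0].tolist()
    if bad:
        raise ConfigError(f"non-positive durations at rows {bad}")
    onsets = df["onset_s"].to_numpy(dtype=float)
    offsets = onsets + df["duration_s"].to_numpy(dtype=float)
    order = np.argsort(onsets, kind="stable")
    onsets, offsets = onsets[order], offsets[order]
    overlap = np.nonzero(onsets[1:] < offsets[:-1] - 1e-9)[0]
    if overlap.size:
        raise ConfigError(f"overlapping events at rows {overlap.tolist()}")
    ids = df["event_id"].to_numpy()[order]
    vectors = None
    if vectors_path is not None:
        vdf = pd.read_csv(vectors_path, sep="\t")
        vdf = vdf.set_index("event_id").loc[ids]
        vectors = vdf.to_numpy(dtype=float)
    return EventSet(onsets, offsets, ids, vectors, phase=phase)


# ---------------------------------------------------------------------------
# Recordings


def write_recording(recording: Recording, path) -> None:
    phase_names = list(recording.phases.keys())
    phase_bounds = np.array([recording.phases[n] for n in phase_names],
                            dtype=float)
    np.savez(path, data=recording.data, fs=np.float64(recording.fs),
             subject_id=np.str_(recording.subject_id),
             role=np.str_(recording.role),
             channel_labels=np.array(recording.channel_labels),
             phase_names=np.array(phase_names),
             phase_bounds=phase_bounds)


def read_recording(path) -> Recording:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no recording at {path}")
    try:
        with np.load(path, allow_pickle=False) as z:
            missing = [k for k in _ARCHIVE_KEYS if k not in z]
            if missing:
                raise ConfigError(
                    f"recording archive {path} missing keys {missing}")
            phases = {str(n): (float(a), float(b))
                      for n, (a, b) in zip(z["phase_names"],
                                           z["phase_bounds"])}
            return Recording(data=z["data"], fs=float(z["fs"]),
                             subject_id=str(z["subject_id"]),
                             role=str(z["role"]),
                             channel_labels=[str(c) for c in
                                             z["channel_labels"]],
                             phases=phases)
    except ConfigError:
        raise
    except Exception as e:
        raise ConfigError(f"malformed recording archive {path}: {e}") from e


# ---------------------------------------------------------------------------
# Similarity matrices


def write_similarity(matrix: SimilarityMatrix, path) -> None:
    path = Path(path)
    pd.DataFrame(matrix.values).to_csv(path, sep="\t", index=False,
                                       header=False)
    if not matrix.mask.all():
        pd.DataFrame(matrix.mask.astype(int)).to_csv(
            path.with_suffix(path.suffix + ".mask.tsv"), sep="\t",
            index=False, header=False)


def read_similarity(path, kind: str = "knowledge") -> SimilarityMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    mask_path = path.with_suffix(path.suffix + ".mask.tsv")
    mask = None
    if mask_path.exists():
        mask = pd.read_csv(mask_path, sep="\t",
                           header=None).to_numpy(dtype=int).astype(bool)
    return SimilarityMatrix(values, mask=mask, kind=kind)


# ---------------------------------------------------------------------------
# JSON helpers


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
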