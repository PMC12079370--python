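"""Run configuration and end-to-end orchestration.

A run either simulates a synthetic cohort (the default; ground truth is
written alongside results) or ingests recordings from archives, then walks
the stages: preprocess -> knowledge matrix -> per-channel RSA with
permutation inference and FDR -> boundary contrast -> leave-one-dyad-out
decoding and pISC -> (optionally) teacher-student lag grid. One seed in the
config fans out deterministically to per-stage child streams, so a rerun
with the same config is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, decode, io, knowledge, preprocess, rsa, sync
from .synth import SynthConfig, simulate_cohort, simulate_recall
from .types import ConfigError


@dataclass
class RunConfig:
    source: str = "synthetic"                 # "synthetic" | "archive"
    synth: SynthConfig = field(default_factory=SynthConfig)
    recording_paths: list = field(default_factory=list)
    teacher_path: str | None = None
    events_path: str | None = None
    vectors_path: str | None = None
    channels: list | None = None              # None = all
    n_perm: int = 1000
    null_method: str = "phase_randomize"
    q_threshold: float = 0.05
    boundary_window_s: float = 15.0
    hrf_shift_s: float = 6.0
    lags_s: list | None = None
    sync_n_perm: int = 0
    run_sync: bool = False
    recall_prob: float = 0.7
    recall_distortion: float = 0.3
    preprocess: preprocess.PreprocessConfig = field(
        default_factory=preprocess.PreprocessConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth_kw = raw.pop("synth", {})
        pp_kw = raw.pop("preprocess", {})
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.synth = SynthConfig(**synth_kw)
        cfg.preprocess = preprocess.PreprocessConfig(**pp_kw)
        return cfg


def _load_inputs(config: RunConfig):
    if config.source == "synthetic":
        event_set, students, teacher, truth = simulate_cohort(
            config.synth, with_teacher=True)
        return event_set, students, teacher, truth
    if config.source != "archive":
        raise ConfigError("source must be 'synthetic' or 'archive'")
    if not config.recording_paths or config.events_path is None:
        raise ConfigError("archive source needs recording_paths and "
                          "events_path")
    students = [io.read_recording(p) for p in config.recording_paths]
    teacher = (io.read_recording(config.teacher_path)
               if config.teacher_path else None)
    event_set = io.read_events(config.events_path, config.vectors_path)
    return event_set, students, teacher, None


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all configured stages, write result files, return a summary.

    Outputs under ``out_dir``: qc.json, knowledge_matrix.tsv, rsa.tsv,
    boundary.tsv, decoding.tsv, group_stats.json, sync.tsv (if run),
    provenance.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(4)

    event_set, students, teacher, truth = _load_inputs(config)

    # Preprocess (QC exclusions applied before any analysis)
    clean, qc_rows = [], []
    events_pp = None
    for rec in students:
        rec_pp, ev_pp, qc = preprocess.preprocess_pipeline(
            rec, config.preprocess, event_set)
        qc_rows.append({"subject": rec.subject_id,
                        "bad_channels": int(qc.bad_channels.sum()),
                        "mean_artifact_fraction":
                            float(qc.artifact_fraction.mean()),
                        "excluded": qc.exclude_subject})
        if not qc.exclude_subject:
            clean.append(rec_pp)
            events_pp = ev_pp
    io.write_json(qc_rows, out / "qc.json")
    if len(clean) < 3:
        raise ConfigError("fewer than 3 students survive QC")
    teacher_pp = None
    if teacher is not None:
        teacher_pp, _, _ = preprocess.preprocess_pipeline(
            teacher, config.preprocess, event_set)

    # Knowledge structure
    km = knowledge.cosine_knowledge_matrix(event_set)
    io.write_similarity(km, out / "knowledge_matrix.tsv")

    # RSA with permutation inference
    channels = (config.channels if config.channels is not None
                else list(range(clean[0].n_channels)))
    rsa_res = rsa.rsa_analysis(clean, events_pp, km, channels=channels,
                               n_perm=config.n_perm,
                               method=config.null_method,
                               q=config.q_threshold, seed=seeds[0])
    rsa_res.to_frame().to_csv(out / "rsa.tsv", sep="\t", index=False)
    best_ch = int(rsa_res.channels[int(np.argmax(rsa_res.r))])

    # Boundary contrast at the best channel
    bres = rsa.group_boundary_effect(clean, events_pp, best_ch,
                                     window_s=config.boundary_window_s,
                                     hrf_shift_s=config.hrf_shift_s)
    pd.DataFrame({"subject": [r.subject_id for r in clean],
                  "boundary": bres.boundary_mean,
                  "nonboundary": bres.nonboundary_mean,
                  "difference": bres.difference}).to_csv(
        out / "boundary.tsv", sep="\t", index=False)

    # Decoding + pISC at the best channel
    sl = rsa.EventSlicer(events_pp, clean[0].fs,
                         min(r.n_samples for r in clean))
    stacks = np.stack([sl.slice(r.data[best_ch]) for r in clean])
    pair_mats = rsa.cohort_pair_matrices(stacks, sl.lengths)
    dres = decode.decode_and_test(pair_mats, km, len(clean))
    pisc_n = decode.neural_pisc(dres.predicted)
    recalls = simulate_recall(event_set, config.recall_prob,
                              config.recall_distortion, seed=seeds[1],
                              n_students=len(clean)) \
        if config.source == "synthetic" else None
    pisc_b = decode.behavioral_pisc(recalls) if recalls else None
    ddf = pd.DataFrame({"subject": [r.subject_id for r in clean],
                        "z_vs_original": dres.z,
                        "included": dres.included,
                        "pISC_neural": pisc_n})
    if pisc_b is not None:
        ddf["pISC_behavioral"] = pisc_b
    ddf.to_csv(out / "decoding.tsv", sep="\t", index=False)

    summary = {
        "n_students": len(clean),
        "n_events": event_set.n_events,
        "best_channel": best_ch,
        "rsa_best_r": float(np.max(rsa_res.r)),
        "rsa_n_significant": int(rsa_res.significant.sum()),
        "boundary_t": None if bres.group is None else bres.group.t,
        "boundary_p": None if bres.group is None else bres.group.p,
        "decode_t": None if dres.group is None else dres.group.t,
        "decode_p": None if dres.group is None else dres.group.p,
        "mean_neural_pisc": float(np.mean(pisc_n)),
    }

    # Teacher-student synchronization
    if config.run_sync and teacher_pp is not None:
        lags = (np.asarray(config.lags_s, dtype=float)
                if config.lags_s is not None else None)
        sres = sync.sync_grid(teacher_pp, clean, events_pp,
                              teacher_channels=channels,
                              student_channels=channels,
                              lags_s=lags, n_perm=config.sync_n_perm,
                              method=config.null_method,
                              q=config.q_threshold, seed=seeds[2])
        sres.table.to_csv(out / "sync.tsv", sep="\t", index=False)
        summary["sync_peak_lag_s"] = sync.peak_lag(sres)
        summary["sync_peak_r"] = float(sres.peak()["r"])

    provenance = {"classrsa_version": __version__,
                  "numpy_version": np.__version__,
                  "seed": config.seed,
                  "n_perm": config.n_perm,
                  "null_method": config.null_method,
                  "source": config.source}
    io.write_json(provenance, out / "provenance.json")
    io.write_json(summary, out / "group_stats.json")
    return summary
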