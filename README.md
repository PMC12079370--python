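# classrsa

Inter-subject, event-level representational similarity analysis (RSA) for
multi-subject classroom fNIRS, with the full analysis chain around it:
hemodynamic preprocessing and quality control, knowledge-structure
matrices, permutation inference with FDR correction, the event-boundary
contrast, leave-one-dyad-out decoding, inter-subject pattern correlation
(pISC), and time-lagged teacher–student representational synchronization —
plus a synthetic cohort generator with known ground truth that makes every
stage testable by parameter recovery.

It is written for researchers in educational neuroscience / hyperscanning
who have: per-participant channel × time HbO recordings at a fixed sampling
rate, a table of knowledge events (onset, duration) with per-event semantic
vectors from any embedding of their choice, and optionally per-student
recall records and behavioral scores.

## The method in brief

Let S be the M × M knowledge matrix, S_mn = cos(w_m, w_n) over the events'
topic vectors. For each participant pair (i, j) and channel, the brain
matrix is the symmetrized inter-subject event correlation

    B_mn = ½ [ corr(x_i|event m, x_j|event n) + corr(x_j|event m, x_i|event n) ],

unequal event lengths truncated to the shorter series. Each subject's
matrix averages their N−1 pair matrices; RSA is Spearman's rho between the
masked lower triangles of B and S, averaged over subjects per channel.
Significance comes from recomputing the whole pipeline on surrogate time
series (phase randomization by default), p = (1 + #{null ≥ emp})/(1 + n_perm),
Benjamini–Hochberg corrected across channels at q < 0.05. Decoding fits,
for each held-out pair, knowledge ~ intercept + slope · (training-mean
brain similarity) and evaluates the per-student averaged predictions;
synchronization repeats the RSA machinery with the teacher's signal shifted
by lags of ±6–14 s over all channel pairs. See `docs/methods.md` for the
full account, assumptions, and limitations.

## Worked example

```python
import numpy as np
from classrsa.synth import SynthConfig, simulate_cohort
from classrsa import rsa

cfg = SynthConfig(n_students=12, n_channels=4, n_events=20,
                  duration_range=(6, 60), embed_strength=0.5,
                  embed_channel=1, boundary_amp=0.0, global_amp=0.0, seed=5)
event_set, students, truth = simulate_cohort(cfg)

for ch in range(4):
    emp, null, p = rsa.permutation_null(
        students, event_set, truth.knowledge_matrix, ch,
        n_perm=200, seed=7)
    print(f"CH{ch + 1}: r = {emp:+.3f}, p = {p:.3f}")
```

prints

```
CH1: r = -0.001, p = 0.527
CH2: r = +0.497, p = 0.005
CH3: r = -0.026, p = 0.821
CH4: r = -0.030, p = 0.886
```

Channel 2 is the channel the generator embedded the knowledge structure
into (`embed_channel=1`, zero-based): its cross-subject mean RSA r stands
far outside its own permutation null (p = 1/201 ≈ 0.005, the smallest
value 200 permutations can resolve), while the pure-noise channels sit in
the null's bulk. This is the per-channel statistic that, on real
recordings, localizes where a cohort's shared representation of the
lecture's knowledge structure lives.

The same cohort objects feed the other stages:
`classrsa.preprocess.preprocess_pipeline` (QC → trim → interpolate → PCA →
band-pass → z-score), `classrsa.rsa.group_boundary_effect`,
`classrsa.decode.decode_and_test`, `classrsa.decode.neural_pisc` /
`behavioral_pisc`, and `classrsa.sync.sync_grid`.

## Command line

A thin CLI wraps the library for shell use:

```bash
classrsa simulate --config cfg.yaml --out cohort/ --seed 7
classrsa preprocess --in cohort/s01.npz --out clean/s01.npz
classrsa rsa --events cohort/events.tsv --vectors cohort/topic_vectors.tsv \
    --recordings clean/s01.npz --recordings clean/s02.npz ... --out rsa.tsv
classrsa boundary | decode | pisc | sync ...
classrsa run --config run.yaml --out results/ --seed 7
```

Recordings travel as a documented NumPy `.npz` archive (`data` C × T,
`fs`, `subject_id`, `role`, `channel_labels`, `phase_names`,
`phase_bounds`); events as TSV (`onset_s`, `duration_s`, `event_id`) with
an optional parallel topic-vector TSV; matrices as TSV grids with a
parallel `.mask.tsv` where cells are unavailable.

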