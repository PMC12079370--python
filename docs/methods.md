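# Methods

`classrsa` implements the analysis chain used to ask whether a cohort of
students listening to the same lecture carries a shared neural
representation of the lecture's knowledge structure, measured with wearable
fNIRS (10 Hz oxy-hemoglobin time series, 22 channels over prefrontal cortex
and right temporoparietal junction). This note describes the model behind
each stage, the synthetic data the package tests itself against, and the
numerical choices where the design was genuinely open.

## The representational model

A lecture is segmented into M ordered, non-overlapping *knowledge events*,
each carrying a nonnegative K-dimensional semantic topic vector w_m. The
**knowledge matrix** S is the M x M cosine-similarity matrix
S_mn = cos(w_m, w_n); its network view treats events as nodes with edge
weights S_mn and node degree the mean weight of a node's edges.

The **brain activity matrix** for a pair of participants (i, j) on one
channel has entries

    B_mn = [ corr(x_i over event m, x_j over event n)
           + corr(x_j over event m, x_i over event n) ] / 2 ,

the *inter-subject* Pearson correlation of event-locked series, symmetrized
by averaging with the transpose. Using different subjects on the two sides
avoids the aliasing of within-subject hemodynamic autocorrelation into the
event-pair similarity. Events of unequal duration are truncated to the
shorter series, anchored at event onset (a deliberate choice over
time-warping; see Numerical choices). Each subject's matrix is the average
of their N-1 pair matrices.

**RSA** is the Spearman correlation between the strictly-lower triangles of
a subject's brain matrix and the knowledge matrix, restricted to the
intersection of the two availability masks (recall-phase matrices have
holes where event pairs were never co-recalled), averaged across subjects
per channel.

**Inference** is by surrogate permutation: every subject's channel time
series is surrogate-transformed, the entire matrix pipeline is recomputed,
and the one-tailed p is (1 + #{null >= empirical}) / (1 + n_perm) — never
zero by construction. The default surrogate is phase randomization, which
preserves the amplitude spectrum and therefore the autocorrelation of the
smooth hemodynamics (the conservative choice); sample shuffling and
circular shifts are selectable. Across channels (or grid cells) p-values
are Benjamini–Hochberg corrected at q < 0.05.

**Boundary contrast.** Higher-order regions that segment continuous input
into events respond at event offsets. The boundary pattern is the mean
signal over the 15 s following each event offset, the non-boundary pattern
the mean over the middle 15 s of each event; both windows are shifted 6 s
later for the hemodynamic delay (6 s windows for recall-phase events, which
are shorter). Events shorter than the window drop out of the non-boundary
average only. The per-subject difference (boundary minus non-boundary) is
tested with a paired t; a *reversed* effect (negative difference) indicates
event boundaries re-drawn relative to the given segmentation.

**Leave-one-dyad-out decoding.** The G = N(N-1)/2 pair matrices form the
population; for each held-out pair, the other G-1 are averaged cellwise and
an intercept+slope regression of the knowledge values on that training mean
is fit over lower-triangle cells, then applied to the held-out pair's
values. Each student's N-1 predictions are averaged into one predicted
knowledge matrix. Per student, Spearman(predicted, reference) is Fisher-z
transformed (|rho| clipped at 1 - 1e-7) and the z values are tested against
zero; the reference is the taught knowledge matrix, or the structure the
student actually recalled. Students who recalled fewer than three events
are excluded from recall-referenced tests.

**pISC.** Neural pISC is, per student, the Fisher z of the mean Pearson
correlation between their predicted matrix and every other student's
(vectorized strictly-lower triangles) — low pISC means idiosyncratic
constructed structure. Behavioral pISC is the mean Jaccard overlap
|intersection| / |union| of binary recall vectors with all other students;
a pair of empty vectors contributes 0 (no shared recall signal).
Behavior–brain coupling uses partial Pearson correlation (residuals after
linearly removing age/SES-type covariates; one-tailed t with
df = n - k - 2).

**Teacher–student synchronization.** For each (teacher channel, student
channel, lag) cell, the teacher's series is read `lag` seconds earlier than
each event's span (positive lag = teacher precedes), the teacher's event
matrix is built as teacher-vs-each-student inter-subject correlations
averaged over students, and Spearman-correlated with the student-cohort
mean matrix on that channel. The default grid covers lags 6–14 s in 2 s
steps, both directions; inference permutes the students' signals with BH
correction across the whole grid. A teacher-autocorrelation variant of the
teacher matrix exists behind `against="self"` but is non-default because
within-subject autocorrelation aliases into it — precisely what the
inter-subject construction avoids.

## Preprocessing

Stage order is fixed: artifact detection on raw data → steady-state trim →
artifact interpolation → spatial-PCA global-noise removal → band-pass →
z-scoring. QC decisions depend only on raw data.

- *Artifacts*: samples beyond mean ± 3 SD within 10 s windows
  (non-overlapping by default; the stride is configurable because the
  running-window stride is a free choice). A channel is bad above 5%
  artifact fraction; a subject is excluded above 30% bad channels.
  Flagged samples are repaired by linear interpolation — a hook where a
  wavelet-based corrector could be substituted; the QC *rule* is what is
  specified numerically, and it is what the tests pin down. Note a
  structural property of the windowed rule verified in the tests: dense
  wide artifacts inflate their own window's SD enough to escape the 3 SD
  threshold; isolated spikes are what it reliably catches.
- *Trim*: first and last 15 s of each phase dropped; event onsets
  re-referenced.
- *Global noise*: one participant at a time, the leading spatial principal
  components of the good channels are projected out up to 80% cumulative
  variance (the convention for global physiological noise such as skin
  blood flow when no short-separation channels exist). This is aggressive —
  on independent channels it removes most variance — but rank statistics
  downstream are insensitive to a roughly uniform attenuation of event-pair
  correlations, which the test suite verifies (< 20% RSA change on a
  global-free cohort).
- *Band-pass*: zero-phase 3rd-order Butterworth, 0.01–0.5 Hz, applied
  forward–backward; phase distortion would bias the lag analyses.
- *z-scoring*: per channel, per phase span by default (whether scaling is
  per phase or per session is configurable; per phase keeps phases
  comparable when their gains drift).

## The synthetic cohort generator

No public recordings accompany this design, so the generator produces
cohorts with known ground truth, and every downstream stage is tested by
parameter recovery. It emulates:

- **Event structure**: M events tile the session; durations are drawn
  log-uniformly within `duration_range`. For the default (6, 200) s range
  the log-uniform mean is ~55 s, matching the right-skewed durations of
  hand-segmented lecture events (a uniform draw would average ~103 s).
  Topic vectors are Dirichlet(0.3) draws in K = 8 dimensions by default.
- **Embedded representation**: K shared smooth topic-basis time courses
  b_k (low-pass-filtered white noise, 0.2 Hz cutoff — smooth enough to
  survive the 0.01–0.5 Hz band-pass) are defined on *event-local* time and
  shared across events and participants. Event m's signal on the designated
  embed channel is the mixture w_m·b, z-scored per event; the channel is
  sqrt(rho)·signal + sqrt(1-rho)·noise. Because pair matrices truncate to
  the shorter event, two events' series correlate through the basis
  covariance over their common prefix, which increases with cos(w_m, w_n):
  the expected brain matrix tracks the knowledge matrix with strength rho.
- **Identifiability ceiling**: the mapping from cosine similarity to
  expected signal correlation is distorted by the finite effective temporal
  degrees of freedom of the smooth bases over an event window
  (~2 × 0.2 Hz × duration). This distortion is shared across subjects, so
  it does *not* average out with cohort size; it caps the attainable
  RSA/decoding correlation. K = 8 topics keeps the ceiling comfortably
  above the recovery thresholds at desk-scale durations; with hundreds of
  topics and 6 s events the structure would be unrecoverable by
  construction, not by implementation error.
- **Noise**: per-channel unit-variance AR(1) noise (phi = 0.8, a realistic
  autocorrelation for 10 Hz hemodynamics) plus one shared smooth global
  time course with per-channel gain in [0.5, 1.5] (what PCA removal is
  tested against), plus optional square motion spikes with a returned truth
  mask.
- **Boundary transients**: a canonical double-gamma hemodynamic response
  (6 s peak, 16 s undershoot) of amplitude `boundary_amp` at each event
  offset, on the embed channel only — an identical transient on every
  channel would be a global spatial component and would be removed by the
  PCA step, which is not what a channel-specific neural boundary response
  looks like. A `boundary_location="middle"` control plants the same
  transient mid-event, which must reverse the contrast.
- **Teacher**: the same embedded structure shifted *earlier* by
  `teacher_lead` seconds (default 8 s), so the lag grid must peak at
  +lead.
- **Recall**: per-student Bernoulli recall vectors and recalled-event
  cosine matrices masked to recalled × recalled pairs; `distortion`
  resamples topic vectors from a Dirichlet centred on the truth
  (alpha = w / distortion), the simplest controllable divergence between
  recalled and original structure. The same mechanism
  (`student_distortion`) makes each student's *embedded* structure
  idiosyncratic, which lowers neural pISC monotonically.

What the generator does **not** emulate: raw optical densities and the
Beer–Lambert conversion, deoxy-hemoglobin, systemic physiology with
realistic spectra (Mayer waves, respiration), head-motion kinematics, or
semantic spaces of realistic dimensionality. Passing recovery tests
therefore show the *pipeline* is correct and calibrated under the assumed
signal model, not that real classroom recordings contain such signals.

## Numerical choices

- Half-open event intervals [onset, offset), 0-based sample indexing,
  seconds everywhere; sample index = round(t × fs).
- Unequal-length event pairs: truncation to the shorter series anchored at
  onset, rather than resampling to a common length, to avoid interpolation
  artifacts in correlations; cells with fewer than 3 samples or zero
  variance are masked out.
- No hemodynamic shift is applied for RSA event extraction; the 6 s shift
  applies to the boundary windows only (both are configurable).
- Boundary windows overrunning the *next event* are kept (windows slide
  regardless of the following event); windows overrunning the recording
  end are dropped.
- Permutation p-values use (1 + #{null ≥ emp}) / (1 + n_perm). For
  circular-shift nulls on a single series, offsets are drawn without
  replacement while n_perm ≤ length, so requesting as many permutations as
  rotations reproduces the exhaustive null exactly.
- Fisher z inputs are clipped at |rho| ≤ 1 - 1e-7.
- The batched truncated-correlation engine computes all event-pair
  correlations of a cohort from one Gram matrix of zero-padded series plus
  prefix sums (zero padding makes the padded dot product equal the
  truncated cross-product); it is verified cell-by-cell against naive
  `np.corrcoef` loops. Permutation loops may run it in float32; all
  downstream statistics are rank-based and insensitive at that precision.
- One run seed fans out to per-stage child streams via
  `numpy.random.SeedSequence.spawn`, so reruns are bit-identical.

## Monte-Carlo problem sizes

Simulation-backed tests state their sizes explicitly; the defaults are the
package's desk-scale study conditions. Null-calibration runs use 200
channel simulations of 12-student, 20-event cohorts with durations
(6, 30) s and 200 permutations (calibration is insensitive to event
length); power and recovery runs use 20-student, 26-event cohorts with
durations (6, 60) s; decoding recovery uses the full (6, 200) s durations,
affordable because no permutation loop is involved. Boundary-recovery
simulations switch the embedded RSA component off (rho = 0) to isolate the
transient: a shared embedded signal is identical across subjects, so its
event-locked window means act as a per-cohort bias of random sign that a
paired test cannot average away — a genuine feature of event-locked
designs worth keeping in mind when interpreting single-cohort boundary
contrasts.

## Known limitations

- The decoder is the univariate form (one predictor: training-mean brain
  similarity per cell) with an intercept; multi-feature regressions are out
  of scope.
- The lag grid's 2 s step bounds lag-recovery precision to one step.
- The boundary contrast inherits transient bleed-through: for events
  shorter than ~30 s the offset response of one event overlaps the next
  event's windows, attenuating (not reversing) the contrast.
- Group tests assume approximately normal per-subject statistics (Fisher z
  helps); no hierarchical/mixed modelling is provided.
- PCA global-noise removal at a fixed 80% threshold is faithful to
  convention but indiscriminate; short-separation-channel regression is
  explicitly out of scope.
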