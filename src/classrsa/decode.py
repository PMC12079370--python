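"""Leave-one-dyad-out decoding of knowledge structure, pISC, and
behavior-brain coupling.

Decoding: the G = N(N-1)/2 inter-subject pair brain matrices form the
population; for each held-out pair, the remaining G-1 matrices are averaged
(cellwise, over lower-triangle values) and an intercept+slope regression of
the knowledge values on that training mean is fit, then applied to the
held-out pair's brain values to produce a predicted knowledge matrix. Each
student's N-1 predictions are averaged into a single predicted matrix.

The per-student Spearman correlation between predicted and reference
structure (the taught knowledge matrix, or the structure the student
actually recalled) is Fisher-z transformed and tested against zero across
students. pISC quantifies between-student consistency: neural pISC is the
Fisher z of each student's mean Pearson correlation with all other
students' predicted matrices; behavioral pISC is the mean Jaccard overlap
of binary recall vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import stats
from .types import ConfigError, RecallRecord, SimilarityMatrix

# re-exported: behavior-brain coupling controls for age/SES covariates
partial_correlation = stats.partial_correlation
group_one_sample_test = stats.one_sample_test


def _pairs(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


@dataclass
class DecodingResult:
    predicted: list[SimilarityMatrix]        # per student
    z: np.ndarray                            # per student Fisher z vs reference
    included: np.ndarray                     # per student bool
    group: Optional[stats.GroupTest] = None
    skipped_pairs: int = 0


def loo_dyad_decode(pair_mats: np.ndarray, knowledge: SimilarityMatrix,
                    n_subjects: int, return_fits: bool = False):
    """Per-student predicted knowledge matrices from leave-one-dyad-out
    regression.

    ``pair_mats`` is (G, M, M) in the i<j pair order of
    :func:`classrsa.rsa.cohort_pair_matrices`. Returns (list of predicted
    SimilarityMatrix per student, number of skipped zero-variance pairs);
    with ``return_fits`` also the per-held-out-pair (slope, intercept)
    array, NaN where a pair was skipped.
    """
    pairs = _pairs(n_subjects)
    g = len(pairs)
    if pair_mats.shape[0] != g:
        raise ConfigError("pair matrix count must equal N(N-1)/2")
    if g < 3:
        raise ConfigError("need at least 3 pairs")
    m = knowledge.n
    rows, cols = np.tril_indices(m, k=-1)
    ok = knowledge.mask[rows, cols]
    r, c = rows[ok], cols[ok]
    y = knowledge.values[r, c]
    x = pair_mats[:, r, c]                              # (G, cells)
    finite = np.isfinite(x)
    x_filled = np.where(finite, x, 0.0)

    preds = np.full((g, ok.sum()), np.nan)
    fits = np.full((g, 2), np.nan)
    skipped = 0
    total = x_filled.sum(axis=0)
    count = finite.sum(axis=0)
    for held in range(g):
        cnt = count - finite[held]
        train_mean = np.where(cnt > 0, (total - x_filled[held]) / np.maximum(
            cnt, 1), np.nan)
        use = np.isfinite(train_mean) & finite[held]
        if use.sum() < 3 or np.std(train_mean[use]) == 0:
            skipped += 1
            continue
        slope, intercept = np.polyfit(train_mean[use], y[use], 1)
        fits[held] = (slope, intercept)
        preds[held, finite[held]] = (intercept
                                     + slope * x[held, finite[held]])

    out = []
    for s in range(n_subjects):
        own = [g_ for g_, (i, j) in enumerate(pairs) if s in (i, j)]
        p = preds[own]
        with np.errstate(invalid="ignore"):
            mean_p = np.nanmean(p, axis=0)
        vals = np.zeros((m, m))
        mask = np.zeros((m, m), dtype=bool)
        cell_ok = np.isfinite(mean_p)
        vals[r[cell_ok], c[cell_ok]] = mean_p[cell_ok]
        vals[c[cell_ok], r[cell_ok]] = mean_p[cell_ok]
        mask[r[cell_ok], c[cell_ok]] = True
        mask[c[cell_ok], r[cell_ok]] = True
        out.append(SimilarityMatrix(vals, mask=mask, kind="predicted"))
    if return_fits:
        return out, skipped, fits
    return out, skipped


def decode_similarity(predicted: SimilarityMatrix,
                      reference: SimilarityMatrix,
                      min_cells: int = 3) -> float:
    """Fisher z of the Spearman correlation between predicted and reference
    structure on jointly masked cells (|rho| clipped below 1)."""
    rho = stats.spearman_masked(predicted, reference, min_cells=min_cells)
    return float(stats.fisher_z(rho))


def decode_and_test(pair_mats: np.ndarray, knowledge: SimilarityMatrix,
                    n_subjects: int,
                    reference: Optional[Sequence[SimilarityMatrix]] = None,
                    min_recalled: int = 3) -> DecodingResult:
    """Full decoding: predictions, per-student z vs the reference (the taught
    knowledge matrix by default, or one recalled matrix per student), and the
    one-sample group test over included students.

    Students whose per-student reference covers fewer than ``min_recalled``
    events (recalled fewer than three knowledge events) are excluded.
    """
    predicted, skipped = loo_dyad_decode(pair_mats, knowledge, n_subjects)
    z = np.full(n_subjects, np.nan)
    included = np.zeros(n_subjects, dtype=bool)
    for s in range(n_subjects):
        ref = knowledge if reference is None else reference[s]
        if reference is not None:
            # events available in the student's reference (diagonal of mask)
            n_events_ref = int(np.diag(ref.mask).sum())
            if n_events_ref < min_recalled:
                continue
        try:
            z[s] = decode_similarity(predicted[s], ref)
            included[s] = True
        except ConfigError:
            continue
    res = DecodingResult(predicted=predicted, z=z, included=included,
                         skipped_pairs=skipped)
    if included.sum() >= 3:
        res.group = stats.one_sample_test(z[included], 0.0)
    return res


# ---------------------------------------------------------------------------
# pISC


def neural_pisc(predicted: Sequence[SimilarityMatrix]) -> np.ndarray:
    """Per-student Fisher z of the mean Pearson correlation between the
    student's predicted matrix and every other student's, on vectorized
    strictly-lower triangles."""
    n = len(predicted)
    if n < 3:
        raise ConfigError("pISC needs at least 3 students")
    m = predicted[0].n
    rows, cols = np.tril_indices(m, k=-1)
    ok = np.ones(rows.size, dtype=bool)
    for pm in predicted:
        ok &= pm.mask[rows, cols]
    if ok.sum() < 3:
        raise ConfigError("fewer than 3 cells shared by all students")
    vecs = np.stack([pm.values[rows[ok], cols[ok]] for pm in predicted])
    if np.any(vecs.std(axis=1) == 0):
        raise ConfigError("constant predicted matrix")
    out = np.empty(n)
    for s in range(n):
        others = np.delete(np.arange(n), s)
        rs = stats.pearson_rows(vecs[others], vecs[s])
        out[s] = stats.fisher_z(np.mean(rs))
    return out


def behavioral_pisc(records: Sequence[RecallRecord] | np.ndarray) -> np.ndarray:
    """Per-student mean Jaccard similarity of binary recall vectors with all
    other students (both-empty pairs count 0)."""
    if isinstance(records, np.ndarray):
        vecs = np.asarray(records, dtype=bool)
    else:
        vecs = np.stack([r.recalled for r in records])
    n, m = vecs.shape
    if n < 2:
        raise ConfigError("need at least 2 students")
    out = np.empty(n)
    for s in range(n):
        sims = [stats.jaccard(vecs[s], vecs[o]) for o in range(n) if o != s]
        out[s] = np.mean(sims)
    return out
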