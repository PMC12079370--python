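"""Knowledge similarity matrices and network summaries.

The knowledge structure of a lecture is the event x event cosine-similarity
matrix of the events' semantic topic vectors; its network view treats events
as nodes and similarities as edge weights, with node degree the mean weight
of a node's edges. Semantic embeddings are *inputs* here: any vectorizer
producing a nonnegative K-dim vector per event can be plugged in, and the
synthetic generator supplies Dirichlet topic vectors directly.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional

import numpy as np

from .types import ConfigError, EventSet, SimilarityMatrix

# A vectorizer maps event text to a K-dim nonnegative vector. None is
# shipped; this is the seam where a topic model (or any sentence embedder)
# plugs in.
Vectorizer = Callable[[str], np.ndarray]


def filter_tokens(tokens: Iterable[str],
                  stop_words: Optional[set] = None) -> list[str]:
    """Optional token-cleanup hook: drops user-supplied stop words (no
    language-specific list is bundled)."""
    if stop_words is None:
        return list(tokens)
    return [t for t in tokens if t not in stop_words]


def cosine_knowledge_matrix(event_set: EventSet) -> SimilarityMatrix:
    """Entry (m, n) = cosine similarity of topic vectors m and n; full mask,
    unit diagonal."""
    tv = event_set.topic_vectors
    if tv is None:
        raise ConfigError("event set carries no topic vectors")
    norms = np.linalg.norm(tv, axis=1)
    if np.any(norms == 0):
        bad = event_set.event_ids[norms == 0].tolist()
        raise ConfigError(f"zero topic vector for events {bad}")
    v = tv / norms[:, None]
    values = np.clip(v @ v.T, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, kind="knowledge")


def node_degree(matrix: SimilarityMatrix) -> np.ndarray:
    """Per-event mean of masked off-diagonal similarities (NaN where a row
    has no masked neighbours)."""
    if matrix.n < 2:
        raise ConfigError("need at least 2 events")
    mask = matrix.mask.copy()
    np.fill_diagonal(mask, False)
    counts = mask.sum(axis=1)
    sums = np.where(mask, matrix.values, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        deg = sums / counts
    deg[counts == 0] = np.nan
    return deg


def group_average_recall_matrix(matrices: list[SimilarityMatrix]
                                ) -> SimilarityMatrix:
    """Cellwise mean over the students whose masks cover each cell.

    Different students recall different event subsets, so the number of
    contributors varies across cells and may be zero; zero-contributor cells
    are left unmasked (unavailable).
    """
    if not matrices:
        raise ConfigError("need at least one student matrix")
    n = matrices[0].n
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for m in matrices:
        if m.n != n:
            raise ConfigError("student matrices must share event dimension")
        acc += np.where(m.mask, m.values, 0.0)
        cnt += m.mask
    with np.errstate(invalid="ignore"):
        mean = acc / cnt
    mask = cnt > 0
    return SimilarityMatrix(np.where(mask, mean, 0.0), mask=mask,
                            kind="recalled")


def edge_list(matrix: SimilarityMatrix, event_ids=None):
    """Long-format (source, target, weight) rows for masked lower-triangle
    edges, for network export/visualization."""
    rows, cols = np.tril_indices(matrix.n, k=-1)
    ok = matrix.mask[rows, cols]
    ids = np.asarray(event_ids) if event_ids is not None \
        else np.array([f"E{i + 1:02d}" for i in range(matrix.n)])
    return [(str(ids[r]), str(ids[c]), float(matrix.values[r, c]))
            for r, c in zip(rows[ok], cols[ok])]
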