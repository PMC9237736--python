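"""Out-of-distribution (OOD) generation scoring by Top-X accuracy.

A generator conditioned on a label combination never seen in training is
scored against real sequences that do carry the combination (held out
from training). Each generated embedding is queried against a pool of
held-out true sequences mixed with distractors (real sequences without
the combination, at a configurable multiple of the held-out count); the
generation counts as accurate if at least one held-out true sequence
appears among its X nearest neighbors in embedding space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .spectrum import EmbeddingMatrix


@dataclass
class OODSetup:
    """Pool definition for one held-out label combination."""

    combination: set[str]
    ood_real: EmbeddingMatrix
    distractors: EmbeddingMatrix
    X: int = 10

    def __post_init__(self) -> None:
        overlap = set(self.ood_real.ids) & set(self.distractors.ids)
        if overlap:
            raise ValueError(
                f"distractors overlap held-out set by id: {sorted(overlap)[:5]}"
            )
        if self.X < 1:
            raise ValueError("X must be >= 1")

    @property
    def multiplier(self) -> float:
        return self.distractors.n / self.ood_real.n


def topx_accuracy(gen: EmbeddingMatrix, setup: OODSetup) -> float:
    """Fraction of generated rows with a held-out true sequence in their top X.

    The pool is the union of held-out and distractor rows; neighbors are
    ranked by Euclidean distance, ties at the X-th distance broken by
    ascending pool index (held-out rows first). The generated set itself
    is not part of the pool.
    """
    if gen.dim != setup.ood_real.dim or gen.dim != setup.distractors.dim:
        raise ValueError("embedding dimension mismatch")
    pool = np.vstack([setup.ood_real.matrix, setup.distractors.matrix])
    n_ood = setup.ood_real.n
    if setup.X > pool.shape[0]:
        raise ValueError(f"X={setup.X} exceeds pool size {pool.shape[0]}")
    # stable tie-break on index: sort squared distances with index as minor key
    d2 = ((gen.matrix[:, None, :] - pool[None, :, :]) ** 2).sum(-1) \
        if gen.n * pool.shape[0] * gen.dim < 5_000_000 else None
    if d2 is None:
        nn = NearestNeighbors(n_neighbors=setup.X).fit(pool)
        _, idx = nn.kneighbors(gen.matrix)
        hits = (idx < n_ood).any(axis=1)
        return float(hits.mean())
    order = np.argsort(d2, axis=1, kind="stable")[:, : setup.X]
    hits = (order < n_ood).any(axis=1)
    return float(hits.mean())


def random_generation_baseline(
    train: EmbeddingMatrix, size: int, seed: int = 0
) -> EmbeddingMatrix:
    """Label-blind baseline: sample generated rows uniformly from training.

    Uniform sample of rows without replacement, deterministic per seed.
    """
    if size > train.n:
        raise ValueError(f"requested {size} rows from a set of {train.n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(train.n, size=size, replace=False)
    return train.rows(list(idx))
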