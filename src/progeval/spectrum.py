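"""Spectrum-kernel feature maps and the generic embedding-matrix container.

The spectrum feature map of order ``k`` counts, for every possible
length-``k`` substring over the 20-letter amino-acid alphabet, its number
of occurrences in a sequence (overlapping windows). With ``k = 3`` this
yields 20**3 = 8000 features. Rows may be L2-normalized, in which case the
inner product between two rows is the normalized spectrum kernel value.
External per-sequence embeddings (precomputed by other feature extractors)
are loaded into the same container and are accepted interchangeably by all
downstream metrics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import AMINO_ACIDS, ProteinSequence


@dataclass
class SpectrumEmbedder:
    """k-mer counting feature map over a fixed ordered alphabet.

    Feature columns are ordered lexicographically over the alphabet, so
    matrices are bit-comparable across runs.
    """

    k: int = 3
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        self._char_to_int = {c: i for i, c in enumerate(self.alphabet)}

    @property
    def n_features(self) -> int:
        return len(self.alphabet) ** self.k

    def feature_names(self) -> list[str]:
        return ["".join(t) for t in itertools.product(self.alphabet, repeat=self.k)]

    def counts(self, residues: str) -> np.ndarray:
        """Integer k-mer counts for one sequence (length L-k+1 windows total)."""
        if len(residues) < self.k:
            raise ValueError(
                f"sequence of length {len(residues)} is shorter than k={self.k}"
            )
        a = len(self.alphabet)
        try:
            codes = np.array([self._char_to_int[c] for c in residues], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"non-alphabet residue {exc.args[0]!r}") from exc
        # rolling base-a window index
        powers = a ** np.arange(self.k - 1, -1, -1, dtype=np.int64)
        windows = np.lib.stride_tricks.sliding_window_view(codes, self.k)
        idx = windows @ powers
        return np.bincount(idx, minlength=self.n_features)


@dataclass
class EmbeddingMatrix:
    """Per-sequence feature vectors: one row per sequence id.

    If ``normalized`` every row has unit Euclidean norm; all-zero rows are
    disallowed under normalization.
    """

    ids: list[str]
    matrix: np.ndarray
    normalized: bool = False
    feature_names: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise ValueError("matrix must be 2-D with one row per id")
        if self.normalized:
            norms = np.linalg.norm(self.matrix, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("normalized flag set but rows are not unit-norm")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def rows(self, indices: Sequence[int]) -> "EmbeddingMatrix":
        return EmbeddingMatrix(
            [self.ids[i] for i in indices],
            self.matrix[list(indices)],
            normalized=self.normalized,
            feature_names=self.feature_names,
        )

    def save(self, path: str | Path) -> None:
        names = self.feature_names or [f"f{i}" for i in range(self.dim)]
        df = pd.DataFrame(self.matrix, columns=names)
        df.insert(0, "id", self.ids)
        df.to_csv(path, sep="\t", index=False)


def embed(
    seqs: Sequence[ProteinSequence],
    embedder: SpectrumEmbedder | None = None,
    normalize: bool = True,
) -> EmbeddingMatrix:
    """Spectrum-embed sequences; rows are k-mer counts, optionally unit-norm.

    Counts are accumulated as integers before any normalization. A
    sequence shorter than ``k`` raises an error naming its id (a zero row
    would break the unit-norm invariant).
    """
    if embedder is None:
        embedder = SpectrumEmbedder()
    mat = np.empty((len(seqs), embedder.n_features), dtype=float)
    for i, seq in enumerate(seqs):
        try:
            mat[i] = embedder.counts(seq.residues)
        except ValueError as exc:
            raise ValueError(f"sequence {seq.id!r}: {exc}") from exc
    if normalize:
        norms = np.linalg.norm(mat, axis=1, keepdims=True)
        mat = mat / norms
    return EmbeddingMatrix(
        [s.id for s in seqs],
        mat,
        normalized=normalize,
        feature_names=None if embedder.k > 3 else embedder.feature_names(),
    )


def load_external_embedding(path: str | Path) -> EmbeddingMatrix:
    """Load a precomputed embedding from a TSV/CSV with an id column first.

    The ``normalized`` flag is left false; downstream metrics accept the
    matrix interchangeably with spectrum embeddings.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else None
    df = pd.read_csv(path, sep=sep, engine="python")
    ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate id(s) in embedding file: {dupes}")
    body = df.iloc[:, 1:]
    try:
        matrix = body.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for col in body.columns:
            bad = pd.to_numeric(body[col], errors="coerce").isna() & body[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"non-numeric value at row {row}, column {col!r}"
                ) from None
        raise
    return EmbeddingMatrix(ids, matrix, normalized=False,
                           feature_names=list(body.columns))
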