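"""Per-label and per-combination n-gram baseline generators.

A classic autoregressive Markov model over the amino-acid alphabet:
sequences are START-padded (n-1 symbols) and STOP-terminated, all
length-n windows are counted, and sampling draws from the additively
smoothed conditionals until STOP or a maximum length. Two deployment
modes mirror the standard baselines for conditional generation: one
model per label (OpL, discarding multilabel information) and one model
per distinct label combination (OpC).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ..data_model import AMINO_ACIDS, LabeledDataset, ProteinSequence

logger = logging.getLogger(__name__)

START = "^"
STOP = "$"


@dataclass
class NGramModel:
    """Order-n Markov model with additive smoothing.

    ``counts`` maps a context (the previous n-1 symbols, as a string) to
    symbol counts; the smoothed conditional for symbol s given context c
    is (count(c, s) + alpha) / (total(c) + alpha * |alphabet + STOP|).
    """

    n: int = 3
    alpha: float = 0.1
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def symbols(self) -> list[str]:
        return list(AMINO_ACIDS) + [STOP]

    def conditional(self, context: str) -> dict[str, float]:
        """Smoothed next-symbol distribution for a length n-1 context."""
        if len(context) != self.n - 1:
            raise ValueError(
                f"context length {len(context)} != n-1 = {self.n - 1}"
            )
        syms = self.symbols
        ctx_counts = self.counts.get(context, {})
        total = sum(ctx_counts.values()) + self.alpha * len(syms)
        if total == 0:
            raise ValueError(
                f"context {context!r} unseen and alpha=0: distribution undefined"
            )
        return {s: (ctx_counts.get(s, 0) + self.alpha) / total for s in syms}


def fit_ngram(
    seqs: Sequence[ProteinSequence], n: int = 3, alpha: float = 0.1
) -> NGramModel:
    """Count all length-n windows over START-padded, STOP-terminated sequences."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not seqs:
        raise ValueError("cannot fit an n-gram model on an empty corpus")
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    pad = START * (n - 1)
    for seq in seqs:
        padded = pad + seq.residues + STOP
        for i in range(len(padded) - n + 1):
            context, symbol = padded[i : i + n - 1], padded[i + n - 1]
            counts[context][symbol] += 1
    return NGramModel(
        n=n, alpha=alpha, counts={c: dict(s) for c, s in counts.items()}
    )


def sample_ngram(
    model: NGramModel,
    count: int,
    max_len: int = 2048,
    seed: int = 0,
    labels: set[str] | None = None,
    min_len: int = 5,
    id_prefix: str = "gen",
) -> list[ProteinSequence]:
    """Autoregressive sampling until STOP or ``max_len``; deterministic per seed.

    Draws shorter than ``min_len`` are rejected and redrawn (a handful of
    residues cannot be embedded or aligned meaningfully); after 1000
    consecutive rejections the draw is accepted as-is.
    """
    rng = np.random.default_rng(seed)
    syms = model.symbols
    out: list[ProteinSequence] = []
    rejections = 0
    while len(out) < count:
        context = START * (model.n - 1)
        residues: list[str] = []
        while len(residues) < max_len:
            dist = model.conditional(context)
            probs = np.array([dist[s] for s in syms])
            symbol = syms[rng.choice(len(syms), p=probs / probs.sum())]
            if symbol == STOP:
                break
            residues.append(symbol)
            if model.n > 1:
                context = (context + symbol)[-(model.n - 1) :]
        if len(residues) < min_len and rejections < 1000:
            rejections += 1
            continue
        rejections = 0
        out.append(
            ProteinSequence(
                id=f"{id_prefix}{len(out):06d}",
                residues="".join(residues),
                labels=set(labels or ()),
            )
        )
    return out


def fit_opl(
    dataset: LabeledDataset,
    mode: str = "per_label",
    n: int = 3,
    alpha: float = 0.1,
) -> dict[str, NGramModel] | dict[frozenset, NGramModel]:
    """One model per label (OpL) or per distinct label combination (OpC).

    In per-label mode a multilabel sequence contributes to every one of
    its labels' corpora (the multilabel structure itself is discarded);
    in per-combination mode each distinct exact label set gets its own
    model. Keys with no sequences are skipped with a warning.
    """
    if mode == "per_label":
        models: dict[str, NGramModel] = {}
        for term in dataset.vocabulary:
            idx = dataset.label_index[term]
            if not idx:
                logger.warning("label %r has no sequences; skipped", term)
                continue
            models[term] = fit_ngram(
                [dataset.sequences[i] for i in idx], n=n, alpha=alpha
            )
        return models
    if mode == "per_combination":
        groups: dict[frozenset, list[ProteinSequence]] = defaultdict(list)
        for seq in dataset:
            groups[frozenset(seq.labels)].append(seq)
        return {
            combo: fit_ngram(seqs, n=n, alpha=alpha)
            for combo, seqs in groups.items()
        }
    raise ValueError(f"unknown mode {mode!r}")


def sample_per_label(
    models: Mapping[str, NGramModel],
    count_per_label: int,
    max_len: int = 2048,
    seed: int = 0,
) -> dict[str, list[ProteinSequence]]:
    """Sample a generated set for every label from its own model."""
    return {
        term: sample_ngram(
            models[term],
            count_per_label,
            max_len=max_len,
            seed=seed + i,
            labels={term},
            id_prefix=f"gen_{term}_",
        )
        for i, term in enumerate(sorted(models))
    }
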