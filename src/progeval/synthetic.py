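"""Simulator of hierarchically labeled protein-like corpora.

Emulates a functionally annotated sequence corpus at desk scale: a small
child-to-parent label DAG, per-label k-mer motifs inserted into random
background sequences at a controllable rate (the "signal"), variable
sequence lengths and composition, ancestor-closed multilabel assignments
(true-path rule by construction), and held-out label combinations for
out-of-distribution evaluation. With signal 0 the sequences are
statistically independent of their labels (a negative-control corpus);
with signal near 1 every sequence carries its labels' motifs (a strongly
separable positive-control corpus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import (
    AMINO_ACIDS,
    LabeledDataset,
    OntologyDAG,
    ProteinSequence,
    write_fasta,
    write_labels,
)


def layered_dag(shape: Sequence[int] = (2, 2)) -> OntologyDAG:
    """Build a small layered DAG: one root, then ``shape[i]`` children per node.

    The default (2, 2) yields 1 root, 2 internal terms and 4 leaves
    (7 terms) — large enough for hierarchy-tolerant ranking to differ
    from plain ranking, small enough for seconds-scale tests.
    """
    terms = ["T0"]
    edges: list[tuple[str, str]] = []
    level = ["T0"]
    counter = 1
    for width in shape:
        nxt = []
        for parent in level:
            for _ in range(width):
                term = f"T{counter}"
                counter += 1
                terms.append(term)
                edges.append((term, parent))  # child -> parent
                nxt.append(term)
        level = nxt
    return OntologyDAG(terms, edges)


def _leaves(dag: OntologyDAG) -> list[str]:
    return sorted(t for t in dag.terms if not dag.children(t))


@dataclass
class SyntheticConfig:
    """Parameters of the corpus simulator.

    ``signal`` is the per-slot probability of motif insertion: a sequence
    of length L offers floor(L / motif_length) non-overlapping slots per
    motif and each is filled independently with probability ``signal``.
    Motifs are distinct random k-mers per label (length ``motif_len``)
    unless given explicitly. ``multilabel_rate`` is the probability that
    a sequence carries one extra, non-ancestral leaf label.
    """

    dag_shape: tuple[int, ...] = (2, 2)
    motifs: dict[str, list[str]] | None = None
    motif_len: int = 4
    signal: float = 0.5
    length_mean: float = 80.0
    length_sd: float = 10.0
    length_min: int = 40
    length_max: int = 160
    background: np.ndarray | None = None
    multilabel_rate: float = 0.1
    include_root_label: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.signal <= 1.0:
            raise ValueError("signal must lie in [0, 1]")
        if not 0.0 <= self.multilabel_rate <= 1.0:
            raise ValueError("multilabel_rate must lie in [0, 1]")
        if self.length_max > 2048:
            raise ValueError("length_max must not exceed 2048")
        if self.background is None:
            self.background = np.full(20, 1 / 20)
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (20,) or not np.isclose(self.background.sum(), 1):
            raise ValueError("background must be a 20-vector summing to 1")

    def build(self) -> tuple[OntologyDAG, dict[str, list[str]]]:
        """Materialize the DAG and the per-label motif table."""
        dag = layered_dag(self.dag_shape)
        motifs = self.motifs
        if motifs is None:
            rng = np.random.default_rng(self.seed + 7919)
            motifs = {}
            seen: set[str] = set()
            for term in sorted(dag.terms):
                while True:
                    m = "".join(
                        AMINO_ACIDS[i]
                        for i in rng.integers(0, 20, size=self.motif_len)
                    )
                    if m not in seen:
                        seen.add(m)
                        motifs[term] = [m]
                        break
        for term, mlist in motifs.items():
            if term not in dag:
                raise ValueError(f"motif label {term!r} not in DAG")
            for m in mlist:
                if len(m) > self.length_min:
                    raise ValueError(
                        f"motif {m!r} longer than minimum sequence length"
                    )
                if set(m) - set(AMINO_ACIDS):
                    raise ValueError(f"motif {m!r} uses non-standard residues")
        return dag, motifs


def _sample_residues(
    rng: np.random.Generator,
    labels: set[str],
    config: SyntheticConfig,
    motifs: dict[str, list[str]],
) -> str:
    length = int(
        np.clip(
            round(rng.normal(config.length_mean, config.length_sd)),
            config.length_min,
            config.length_max,
        )
    )
    codes = rng.choice(20, size=length, p=config.background)
    seq = np.array([AMINO_ACIDS[c] for c in codes])
    occupied = np.zeros(length, dtype=bool)
    all_motifs = [m for t in sorted(labels) for m in motifs.get(t, [])]
    remaining = []
    for motif in all_motifs:
        # divide the slot budget evenly so every carried label's motifs
        # fit even at signal = 1
        slots = max(1, (length // len(motif)) // max(1, len(all_motifs)))
        remaining.append(rng.binomial(slots, config.signal))
    # round-robin placement across motifs so no label starves when crowded
    while any(remaining):
        for mi, motif in enumerate(all_motifs):
            if remaining[mi] == 0:
                continue
            remaining[mi] -= 1
            mlen = len(motif)
            windows = np.lib.stride_tricks.sliding_window_view(occupied, mlen)
            free = np.flatnonzero(~windows.any(axis=1))
            if free.size == 0:
                remaining[mi] = 0
                continue
            off = int(free[rng.integers(0, free.size)])
            seq[off : off + mlen] = list(motif)
            occupied[off : off + mlen] = True
    return "".join(seq)


def _assign_labels(
    rng: np.random.Generator, n: int, dag: OntologyDAG, config: SyntheticConfig
) -> list[set[str]]:
    leaves = _leaves(dag)
    # stratified leaf assignment so every label reaches its guaranteed support
    primary = np.array([leaves[i % len(leaves)] for i in range(n)], dtype=object)
    primary = primary[rng.permutation(n)]
    out = []
    for i in range(n):
        chosen = {primary[i]}
        if len(leaves) > 1 and rng.random() < config.multilabel_rate:
            others = [l for l in leaves if l != primary[i]]
            chosen.add(others[int(rng.integers(0, len(others)))])
        labels = set(chosen)
        for t in chosen:
            labels |= dag.ancestors(t)
        if not config.include_root_label:
            # drop the (uninformative) root carried by every sequence; with a
            # single-level DAG this yields a flat label problem
            labels.discard("T0")
        out.append(labels)
    return out


def generate_dataset(
    config: SyntheticConfig, n: int
) -> tuple[LabeledDataset, OntologyDAG]:
    """Draw ``n`` i.i.d. labeled sequences from the simulator.

    Each sequence receives a leaf label (stratified over leaves, so every
    label attains at least floor(n / (2 d)) sequences), possibly an extra
    leaf per ``multilabel_rate``, plus all ancestors (label sets are
    ancestor-closed by construction); background residues are then
    overwritten with the carried labels' motifs at rate ``signal``.
    Deterministic given ``config.seed``.
    """
    dag, motifs = config.build()
    if n < len(dag.terms):
        raise ValueError(f"need n >= number of labels ({len(dag.terms)})")
    rng = np.random.default_rng(config.seed)
    label_sets = _assign_labels(rng, n, dag, config)
    seqs = [
        ProteinSequence(
            id=f"syn{i:06d}",
            residues=_sample_residues(rng, label_sets[i], config, motifs),
            labels=label_sets[i],
        )
        for i in range(n)
    ]
    return LabeledDataset(seqs), dag


def generate_ood_split(
    config: SyntheticConfig,
    n: int,
    holdout: set[str],
    multiplier: int = 2,
    ood_fraction: float = 0.1,
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Corpus with a held-out label combination, for OOD evaluation.

    A fraction of sequences is constructed to carry the full holdout
    combination (plus ancestors); every sequence whose label set contains
    the combination is diverted to the OOD set. Distractors are sampled
    from the remaining sequences at ``multiplier`` times the OOD count;
    the rest form the training set.
    """
    dag, motifs = config.build()
    for t in holdout:
        if t not in dag:
            raise ValueError(f"holdout label {t!r} not in DAG")
    rng = np.random.default_rng(config.seed)
    label_sets = _assign_labels(rng, n, dag, config)
    stride = max(2, int(round(1 / ood_fraction)))
    combo_closed = set(holdout)
    for t in holdout:
        combo_closed |= dag.ancestors(t)
    for i in range(0, n, stride):
        label_sets[i] = set(combo_closed)
    seqs = [
        ProteinSequence(
            id=f"syn{i:06d}",
            residues=_sample_residues(rng, label_sets[i], config, motifs),
            labels=label_sets[i],
        )
        for i in range(n)
    ]
    ood = [s for s in seqs if holdout <= s.labels]
    rest = [s for s in seqs if not holdout <= s.labels]
    n_distract = multiplier * len(ood)
    if n_distract > len(rest):
        raise ValueError(
            f"not enough non-holdout sequences for multiplier {multiplier}"
        )
    idx = rng.choice(len(rest), size=n_distract, replace=False)
    chosen = set(int(i) for i in idx)
    distractors = [rest[i] for i in sorted(chosen)]
    train = [rest[i] for i in range(len(rest)) if i not in chosen]
    vocab = sorted({t for s in seqs for t in s.labels})
    return (
        LabeledDataset(train, vocabulary=vocab),
        LabeledDataset(ood, vocabulary=vocab),
        LabeledDataset(distractors, vocabulary=vocab),
    )


def save_corpus(
    dataset: LabeledDataset, dag: OntologyDAG, out_dir: str | Path
) -> dict[str, Path]:
    """Write FASTA + label TSV + DAG edge TSV (the formats the loaders read)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "sequences.fasta",
        "labels": out / "labels.tsv",
        "dag": out / "dag.tsv",
    }
    write_fasta(dataset, paths["fasta"])
    write_labels(dataset, paths["labels"])
    dag.to_edge_tsv(paths["dag"])
    return paths
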