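"""Conditional consistency via label-wise MMD rank statistics.

For each target label i, the generated-for-label-i sample G_i is compared
by MMD against every real per-label sample R_j. The rank of the on-target
distance MMD(R_i, G_i) within row i of the resulting d x d matrix gives
the reciprocal-rank contribution of label i; the mean over labels is the
mean reciprocal rank (MRR), maximal at 1 when every generated per-label
distribution sits closest to its own real counterpart. A hierarchy-
tolerant variant (``mrr_blind``) removes a label's DAG parents and
children from its competitor set, so that confusions among hierarchically
adjacent functions are not penalized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import OntologyDAG
from .mmd import KernelSpec, mmd
from .spectrum import EmbeddingMatrix


@dataclass
class MMDMatrix:
    """d x d matrix of distances; entry (i, j) = MMD(R_j, G_i).

    Row i holds the distances of the generated-for-label-i sample to
    every real per-label sample; the diagonal is the on-target distance.
    """

    labels: list[str]
    values: np.ndarray
    kernel: KernelSpec = field(default_factory=KernelSpec)
    subset_size: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        d = len(self.labels)
        if self.values.shape != (d, d):
            raise ValueError(f"values must be {d}x{d}, got {self.values.shape}")
        if d < 2:
            raise ValueError("need at least 2 labels")
        if (self.values < 0).any():
            raise ValueError("MMD values must be nonnegative")

    @property
    def d(self) -> int:
        return len(self.labels)

    def save(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        df.to_csv(path, sep="\t")
        sidecar = {
            "kernel": {"kind": self.kernel.kind, "sigma": self.kernel.sigma},
            "subset_size": self.subset_size,
            "seed": self.seed,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def mmd_matrix(
    real: Mapping[str, EmbeddingMatrix],
    gen: Mapping[str, EmbeddingMatrix],
    kernel: KernelSpec = KernelSpec("linear"),
    subset_size: int | None = None,
    seed: int | None = None,
) -> MMDMatrix:
    """All-pairs label MMD matrix between real and generated per-label sets.

    ``real`` and ``gen`` must have identical label keys; subsets should be
    equalized to a common size upstream (recorded for provenance).
    """
    if set(real) != set(gen):
        diff = sorted(set(real) ^ set(gen))
        raise ValueError(f"label keys differ between real and gen: {diff}")
    labels = sorted(real)
    d = len(labels)
    values = np.zeros((d, d))
    for i, li in enumerate(labels):
        for j, lj in enumerate(labels):
            values[i, j] = mmd(real[lj], gen[li], kernel).mmd
    return MMDMatrix(labels, values, kernel=kernel, subset_size=subset_size, seed=seed)


def _rank(row: np.ndarray, i: int, competitors: np.ndarray) -> int:
    """Rank of the diagonal entry among competitor entries of its row.

    Strict-less counting with pessimistic ties: competitors tied exactly
    with the on-target distance also count against the model, keeping
    degenerate inputs deterministic.
    """
    target = row[i]
    others = row[competitors]
    return 1 + int(np.sum(others < target) + np.sum(others == target))


def per_label_ranks(
    M: MMDMatrix, dag: OntologyDAG | None = None, transitive: bool = False
) -> dict[str, int]:
    """Rank of each label's on-target distance within its matrix row.

    With a DAG, each label's parents and children (or full ancestors and
    descendants if ``transitive``) are removed from its competitor set.
    """
    ranks: dict[str, int] = {}
    for i, label in enumerate(M.labels):
        excluded = {i}
        if dag is not None:
            if label not in dag:
                raise ValueError(f"label {label!r} missing from DAG")
            family = dag.neighbors(label, transitive=transitive)
            excluded |= {j for j, lj in enumerate(M.labels) if lj in family}
        competitors = np.array(
            [j for j in range(M.d) if j not in excluded], dtype=int
        )
        ranks[label] = _rank(M.values[i], i, competitors)
    return ranks


def mrr(M: MMDMatrix) -> float:
    """Mean reciprocal rank of the on-target distances; in (0, 1]."""
    ranks = per_label_ranks(M)
    return float(np.mean([1.0 / r for r in ranks.values()]))


def mrr_blind(M: MMDMatrix, dag: OntologyDAG, transitive: bool = False) -> float:
    """Hierarchy-tolerant MRR: DAG parents/children excluded as competitors.

    Never smaller than plain :func:`mrr` on the same matrix. By default
    only direct DAG neighbors are excluded; ``transitive=True`` excludes
    full ancestors and descendants instead.
    """
    ranks = per_label_ranks(M, dag=dag, transitive=transitive)
    return float(np.mean([1.0 / r for r in ranks.values()]))
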