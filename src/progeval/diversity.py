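"""Diversity, novelty and overfitting controls for generated sequence sets.

Mode collapse — a generator concentrating on few modes — is monitored by
two heuristics: the average Shannon entropy of the per-feature empirical
histograms (1000 equal-width bins by default) and the average pairwise
RKHS distance between samples. Both are reported as signed differences
(generated minus real test set). Overfitting is controlled by comparing
nearest-neighbor squared distances of generated-vs-training embeddings
against test-vs-training ones, and novelty by the maximum percent
identity of each generated sequence to the training set. A random-
mutagenesis ladder provides an MMD reference curve: natural sequences are
perturbed by per-site substitutions at increasing rates and compared to
the originals by MMD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
from Bio import Align
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

from .data_model import AMINO_ACIDS, ProteinSequence
from .mmd import KernelSpec, MMDResult, mmd, resolve_kernel
from .spectrum import EmbeddingMatrix, SpectrumEmbedder, embed


@dataclass
class DiversityStats:
    """Entropy- and distance-based diversity summary of one embedded set."""

    entropy: float
    mean_pairwise_distance: float
    n: int
    bins: int

    def __post_init__(self) -> None:
        if self.entropy < -1e-12 or self.entropy > np.log(self.bins) + 1e-9:
            raise ValueError("entropy outside [0, ln(bins)]")


def _pairwise_rkhs_distances(
    X: np.ndarray, kernel: KernelSpec, max_pairs: int = 10**6, seed: int = 0
) -> np.ndarray:
    n = X.shape[0]
    iu = np.triu_indices(n, k=1)
    if iu[0].size > max_pairs:
        rng = np.random.default_rng(seed)
        keep = rng.choice(iu[0].size, max_pairs, replace=False)
        iu = (iu[0][keep], iu[1][keep])
    if kernel.kind == "linear":
        d = cdist(X, X)[iu]
    else:
        sigma = float(kernel.sigma)
        sq = cdist(X, X, "sqeuclidean")[iu]
        # d_H^2 = k(x,x) + k(y,y) - 2 k(x,y) = 2 - 2 exp(-||x-y||^2 / 2 sigma^2)
        d = np.sqrt(np.maximum(0.0, 2.0 - 2.0 * np.exp(-sq / (2 * sigma**2))))
    return d


def diversity(
    X: EmbeddingMatrix,
    bins: int = 1000,
    kernel: KernelSpec = KernelSpec("linear"),
    max_pairs: int = 10**6,
    seed: int = 0,
) -> DiversityStats:
    """Average per-feature histogram entropy and mean pairwise RKHS distance.

    Each feature column is histogrammed into ``bins`` equal-width bins
    over [0, 1] (normalized features are bounded by 1) and its Shannon
    entropy taken in nats; the mean over columns is reported. The
    distance part averages over unordered pairs, subsampled to at most
    ``max_pairs`` with a recorded seed for large sets.
    """
    mat = X.matrix
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows for pairwise distances")
    clipped = np.clip(mat, 0.0, 1.0)
    idx = np.minimum((clipped * bins).astype(int), bins - 1)
    entropies = np.empty(mat.shape[1])
    for j in range(mat.shape[1]):
        counts = np.bincount(idx[:, j], minlength=bins)
        p = counts[counts > 0] / n
        entropies[j] = -(p * np.log(p)).sum()
    kernel = resolve_kernel(mat, mat, kernel)
    dists = _pairwise_rkhs_distances(mat, kernel, max_pairs=max_pairs, seed=seed)
    return DiversityStats(
        entropy=float(entropies.mean()),
        mean_pairwise_distance=float(dists.mean()),
        n=n,
        bins=bins,
    )


def delta_stats(gen: DiversityStats, ref: DiversityStats) -> tuple[float, float]:
    """Signed diversity differences (generated minus reference)."""
    if gen.bins != ref.bins:
        raise ValueError(f"bin counts differ: {gen.bins} vs {ref.bins}")
    return (gen.entropy - ref.entropy,
            gen.mean_pairwise_distance - ref.mean_pairwise_distance)


def nn_squared_distances(
    A: EmbeddingMatrix, B: EmbeddingMatrix, exclude_self: bool | None = None
) -> np.ndarray:
    """Squared Euclidean distance of each row of A to its nearest row of B.

    When A and B are the same object, each row's own index is excluded
    from the search (override with ``exclude_self``).
    """
    if B.n == 0:
        raise ValueError("reference set B is empty")
    if A.dim != B.dim:
        raise ValueError("dimension mismatch")
    if exclude_self is None:
        exclude_self = A is B
    k = 2 if exclude_self else 1
    nn = NearestNeighbors(n_neighbors=k).fit(B.matrix)
    dist, idx = nn.kneighbors(A.matrix)
    if exclude_self:
        out = np.where(idx[:, 0] == np.arange(A.n), dist[:, 1], dist[:, 0])
    else:
        out = dist[:, 0]
    return out**2


_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=0,
    open_gap_score=-1,
    extend_gap_score=-1,
)


def _alignment_identity(a: str, b: str) -> float:
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / length


def max_percent_identity(
    gen: Sequence[ProteinSequence],
    reference: Sequence[ProteinSequence],
    prefilter_topk: int = 20,
    k: int = 3,
    method: str = "alignment",
) -> np.ndarray:
    """Per generated sequence, the maximum percent identity to the reference.

    Identity is matches / alignment length x 100 under global alignment
    with unit match score, zero mismatch and linear gap penalty -1.
    Candidate references are prefiltered to the ``prefilter_topk`` most
    cosine-similar spectrum embeddings for tractability.
    ``method='edit'`` instead scores 100 x (1 - edit_distance /
    max(len)), the edit-distance reading of sequence similarity.
    """
    if not reference:
        raise ValueError("reference set is empty")
    embedder = SpectrumEmbedder(k=k)
    G = embed(gen, embedder).matrix
    R = embed(reference, embedder).matrix
    sims = G @ R.T  # cosine similarity of unit rows
    topk = min(prefilter_topk, len(reference))
    out = np.empty(len(gen))
    for i, g in enumerate(gen):
        cand = np.argsort(-sims[i])[:topk]
        best = 0.0
        for j in cand:
            r = reference[j].residues
            if method == "alignment":
                pid = _alignment_identity(g.residues, r)
            elif method == "edit":
                dist = edlib.align(g.residues, r, task="distance")["editDistance"]
                pid = 100.0 * (1.0 - dist / max(len(g.residues), len(r)))
            else:
                raise ValueError(f"unknown method {method!r}")
            best = max(best, pid)
        out[i] = best
    return out


def mutate_sequences(
    seqs: Sequence[ProteinSequence], rate: float, seed: int = 0
) -> list[ProteinSequence]:
    """Independent per-site substitution at the given rate.

    Each residue is replaced with probability ``rate`` by a uniform draw
    from the 19 other amino acids (substitution-only; lengths preserved).
    """
    rng = np.random.default_rng(seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    out = []
    for seq in seqs:
        codes = np.frombuffer(seq.residues.encode(), dtype=np.uint8).copy()
        hit = rng.random(codes.size) < rate
        if hit.any():
            # draw from the 19 alternatives by shifting past the original
            orig_idx = np.searchsorted(aa, codes[hit])
            offset = rng.integers(1, 20, size=int(hit.sum()))
            codes[hit] = aa[(orig_idx + offset) % 20]
        out.append(ProteinSequence(seq.id, codes.tobytes().decode(), set(seq.labels)))
    return out


def mutagenesis_ladder(
    seqs: Sequence[ProteinSequence],
    rates: Sequence[float],
    reference_embed: EmbeddingMatrix,
    kernel: KernelSpec = KernelSpec("linear"),
    seed: int = 0,
    embedder: SpectrumEmbedder | None = None,
) -> dict[float, MMDResult]:
    """MMD of mutated copies of ``seqs`` to a reference, per mutation rate.

    Emulates random mutagenesis: at rate r every residue is substituted
    independently with probability r, the mutated set is spectrum-embedded
    and compared to ``reference_embed`` by MMD. Deterministic per seed.
    """
    if any(r < 0 or r > 1 for r in rates):
        raise ValueError("rates must lie in [0, 1]")
    results: dict[float, MMDResult] = {}
    for step, rate in enumerate(rates):
        mutated = mutate_sequences(seqs, rate, seed=seed + step)
        X = embed(mutated, embedder)
        results[rate] = mmd(X, reference_embed, kernel)
    return results
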