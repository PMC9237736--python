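"""Core data structures for labeled protein sequence corpora.

A corpus is a collection of protein sequences, each carrying a set of
functional term identifiers drawn from a hierarchical vocabulary (a
child-to-parent directed acyclic graph, as in the Gene Ontology). This
module provides the containers, file I/O (FASTA, label TSV, DAG edge
lists / minimal OBO), the standard filtering rules (canonical residues,
maximum length, minimum per-label support), true-path label imputation,
deterministic train/validation/test splitting with out-of-distribution
(OOD) label-combination holdouts, and per-label subsetting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, in alphabetical one-letter-code order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


@dataclass
class ProteinSequence:
    """A single protein sequence with optional functional labels."""

    id: str
    residues: str
    labels: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.residues)

    def is_canonical(self) -> bool:
        """True if every residue is one of the 20 standard amino acids."""
        return not set(self.residues) - _AA_SET


class LabeledDataset:
    """Sequences plus a fixed, ordered label vocabulary.

    The vocabulary defaults to the lexicographically sorted set of all
    term ids appearing in the sequences, so that label column indices are
    reproducible across runs. ``label_index`` maps each vocabulary term
    to the indices of the sequences annotated with it.
    """

    def __init__(
        self,
        sequences: Sequence[ProteinSequence],
        vocabulary: Sequence[str] | None = None,
    ) -> None:
        self.sequences: list[ProteinSequence] = list(sequences)
        if vocabulary is None:
            terms: set[str] = set()
            for seq in self.sequences:
                terms |= seq.labels
            vocabulary = sorted(terms)
        self.vocabulary: list[str] = list(vocabulary)
        vocab_set = set(self.vocabulary)
        for seq in self.sequences:
            extra = seq.labels - vocab_set
            if extra:
                raise ValueError(
                    f"sequence {seq.id!r} carries labels outside the "
                    f"vocabulary: {sorted(extra)}"
                )
        self.label_index: dict[str, list[int]] = {t: [] for t in self.vocabulary}
        for i, seq in enumerate(self.sequences):
            for term in seq.labels:
                self.label_index[term].append(i)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def label_count(self, term: str) -> int:
        return len(self.label_index[term])

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        """New dataset restricted to the given sequence indices (vocabulary kept)."""
        seqs = [self.sequences[i] for i in indices]
        return LabeledDataset(seqs, vocabulary=self.vocabulary)


class OntologyDAG:
    """A child-to-parent directed acyclic graph of term identifiers."""

    def __init__(self, terms: Iterable[str], edges: Iterable[tuple[str, str]]) -> None:
        self.terms: set[str] = set(terms)
        self.edges: set[tuple[str, str]] = set(edges)
        for child, parent in self.edges:
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"edge ({child!r}, {parent!r}) references unknown term")
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.edges)  # child -> parent
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"term graph contains a cycle: {cycle}")
        self._graph = g

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def parents(self, term: str) -> set[str]:
        return set(self._graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self._graph.predecessors(term))

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable by following child->parent edges (excl. term)."""
        return set(nx.descendants(self._graph, term))

    def descendants(self, term: str) -> set[str]:
        return set(nx.ancestors(self._graph, term))

    def neighbors(self, term: str, transitive: bool = False) -> set[str]:
        """Parents and children of ``term``; full ancestors/descendants if transitive."""
        if transitive:
            return self.ancestors(term) | self.descendants(term)
        return self.parents(term) | self.children(term)

    @classmethod
    def from_edge_tsv(cls, path: str | Path) -> "OntologyDAG":
        """Read a 2-column child<TAB>parent edge list."""
        edges = []
        terms = set()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ParseError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, "
                        f"got {len(parts)}"
                    )
                child, parent = parts
                edges.append((child, parent))
                terms.update((child, parent))
        return cls(terms, edges)

    @classmethod
    def from_obo(cls, path: str | Path) -> "OntologyDAG":
        """Read a minimal OBO subset: ``[Term]`` stanzas with id / is_a lines."""
        terms: set[str] = set()
        edges: list[tuple[str, str]] = []
        current: str | None = None
        in_term = False
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line == "[Term]":
                    in_term, current = True, None
                elif line.startswith("["):
                    in_term = False
                elif in_term and line.startswith("id:"):
                    current = line[3:].strip()
                    terms.add(current)
                elif in_term and line.startswith("is_a:"):
                    if current is None:
                        raise ParseError(f"{path}: is_a before id in [Term] stanza")
                    parent = line[5:].strip().split("!")[0].strip()
                    terms.add(parent)
                    edges.append((current, parent))
        return cls(terms, edges)

    def to_edge_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for child, parent in sorted(self.edges):
                fh.write(f"{child}\t{parent}\n")


@dataclass
class SplitSpec:
    """Parameters of a deterministic train/val/test split with OOD holdouts.

    ``ood_combinations`` lists label-id sets withheld entirely from all
    three splits; a sequence is routed to the OOD pool if its (imputed)
    label set matches a combination either as a superset (``ood_match =
    'subset'``, the permissive reading) or exactly (``'exact'``).
    """

    ood_combinations: list[set[str]] = field(default_factory=list)
    min_per_label: int = 0
    seed: int = 0
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    ood_match: str = "subset"
    assignment: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ood_combinations": [sorted(c) for c in self.ood_combinations],
            "min_per_label": self.min_per_label,
            "seed": self.seed,
            "fractions": list(self.fractions),
            "ood_match": self.ood_match,
            "assignment": self.assignment,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitSpec":
        payload = json.loads(Path(path).read_text())
        return cls(
            ood_combinations=[set(c) for c in payload["ood_combinations"]],
            min_per_label=payload["min_per_label"],
            seed=payload["seed"],
            fractions=tuple(payload["fractions"]),
            ood_match=payload.get("ood_match", "subset"),
            assignment=payload.get("assignment", {}),
        )


# ---------------------------------------------------------------------------
# File I/O


def read_fasta(path: str | Path, strict: bool = False) -> list[ProteinSequence]:
    """Read a FASTA file into :class:`ProteinSequence` records (labels empty).

    Residues are uppercased and record order is preserved. With
    ``strict=True`` any residue outside the 20-letter canonical alphabet
    raises :class:`ParseError` naming the offending character.
    """
    path = Path(path)
    with open(path) as fh:
        first = None
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                first = (lineno, line)
                break
        if first is not None and not first[1].startswith(">"):
            raise ParseError(
                f"{path}:{first[0]}: expected FASTA header starting with '>'"
            )
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if strict:
            bad = set(residues) - _AA_SET
            if bad:
                raise ParseError(
                    f"sequence {rec.id!r} contains non-standard residue(s) "
                    f"{sorted(bad)}"
                )
        records.append(ProteinSequence(id=rec.id, residues=residues))
    return records


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path,
                label_headers: bool = False) -> None:
    """Write sequences to FASTA; optionally echo labels in the header."""
    with open(path, "w") as fh:
        for seq in seqs:
            header = seq.id
            if label_headers and seq.labels:
                header += " " + ";".join(sorted(seq.labels))
            fh.write(f">{header}\n")
            for i in range(0, len(seq.residues), 80):
                fh.write(seq.residues[i : i + 80] + "\n")


def read_labels(
    path: str | Path,
    sequences: Sequence[ProteinSequence],
    vocabulary: Sequence[str] | None = None,
) -> LabeledDataset:
    """Attach labels from a 2-column ``id<TAB>term`` TSV to sequences.

    Sequences left without any label after the join are excluded (the
    corpus requires at least one functional annotation per sequence); the
    number excluded is logged. An id in the TSV that does not match any
    sequence raises :class:`ParseError`.
    """
    by_id: dict[str, ProteinSequence] = {}
    for seq in sequences:
        if seq.id in by_id:
            raise ParseError(f"duplicate sequence id {seq.id!r}")
        by_id[seq.id] = ProteinSequence(seq.id, seq.residues, set())
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            seq_id, term = parts
            if seq_id not in by_id:
                raise ParseError(
                    f"{path}:{lineno}: label references unknown sequence id "
                    f"{seq_id!r}"
                )
            by_id[seq_id].labels.add(term)
    labeled = [s for s in by_id.values() if s.labels]
    dropped = len(by_id) - len(labeled)
    if dropped:
        logger.warning("excluded %d sequence(s) without any label", dropped)
    # preserve input order
    order = {s.id: i for i, s in enumerate(sequences)}
    labeled.sort(key=lambda s: order[s.id])
    return LabeledDataset(labeled, vocabulary=vocabulary)


def write_labels(dataset: LabeledDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq in dataset:
            for term in sorted(seq.labels):
                fh.write(f"{seq.id}\t{term}\n")


# ---------------------------------------------------------------------------
# Corpus transformations


def impute_true_path(dataset: LabeledDataset, dag: OntologyDAG) -> LabeledDataset:
    """Close every label set under the ancestor relation (true-path rule).

    A sequence annotated with a term implicitly carries all of that
    term's ancestors in the DAG; this adds the missing ancestors.
    Idempotent, and only ever grows label sets.
    """
    new_seqs = []
    for seq in dataset:
        labels = set(seq.labels)
        for term in seq.labels:
            if term not in dag:
                raise ValueError(f"label {term!r} of sequence {seq.id!r} not in DAG")
            labels |= dag.ancestors(term)
        new_seqs.append(ProteinSequence(seq.id, seq.residues, labels))
    return LabeledDataset(new_seqs)


def filter_dataset(
    dataset: LabeledDataset,
    max_len: int = 2048,
    min_per_label: int = 1,
) -> tuple[LabeledDataset, dict[str, int]]:
    """Apply the three corpus filters; returns (dataset, removal counts).

    Removes sequences with non-standard residues or longer than
    ``max_len``, drops vocabulary terms with fewer than ``min_per_label``
    remaining sequences (removing them from label sets), and finally
    removes sequences left with no labels at all. Label dropping and
    sequence removal are iterated to a fixed point so that the output
    satisfies all rules simultaneously and re-filtering is a no-op.
    """
    counts = {"non_standard": 0, "too_long": 0, "rare_label_terms": 0, "unlabeled": 0}
    seqs = []
    for seq in dataset:
        if not seq.is_canonical():
            counts["non_standard"] += 1
        elif len(seq) > max_len:
            counts["too_long"] += 1
        else:
            seqs.append(ProteinSequence(seq.id, seq.residues, set(seq.labels)))

    vocab = [t for t in dataset.vocabulary]
    while True:
        support = {t: 0 for t in vocab}
        for seq in seqs:
            for t in seq.labels:
                if t in support:
                    support[t] += 1
        dropped_terms = {t for t, c in support.items() if c < min_per_label}
        if dropped_terms:
            counts["rare_label_terms"] += len(dropped_terms)
            vocab = [t for t in vocab if t not in dropped_terms]
            for seq in seqs:
                seq.labels -= dropped_terms
        unlabeled = [s for s in seqs if not s.labels]
        if unlabeled:
            counts["unlabeled"] += len(unlabeled)
            seqs = [s for s in seqs if s.labels]
        if not dropped_terms and not unlabeled:
            break
    if not seqs:
        raise ValueError("filtering removed every sequence")
    return LabeledDataset(seqs, vocabulary=vocab), counts


def _matches_combination(labels: set[str], combo: set[str], mode: str) -> bool:
    if mode == "subset":
        return combo <= labels
    if mode == "exact":
        return labels == combo
    raise ValueError(f"unknown ood_match mode {mode!r}")


def split_dataset(
    dataset: LabeledDataset, spec: SplitSpec
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset, list[LabeledDataset]]:
    """Deterministic train/val/test split with OOD-combination holdouts.

    Sequences whose label sets match one of ``spec.ood_combinations`` are
    diverted to per-combination OOD pools and excluded from all three
    splits. The remaining ids are partitioned at ``spec.fractions``,
    guaranteeing every vocabulary term at least ``spec.min_per_label``
    sequences in both validation and test. The assignment is recorded in
    ``spec.assignment`` and is a pure function of the seed.
    """
    ood_indices: list[list[int]] = [[] for _ in spec.ood_combinations]
    rest: list[int] = []
    for i, seq in enumerate(dataset):
        for c, combo in enumerate(spec.ood_combinations):
            if _matches_combination(seq.labels, combo, spec.ood_match):
                ood_indices[c].append(i)
                break
        else:
            rest.append(i)

    rng = np.random.default_rng(spec.seed)
    order = [rest[j] for j in rng.permutation(len(rest))]
    assignment: dict[int, str] = {}

    if spec.min_per_label > 0:
        # fill minima for the scarcest labels first
        support = {
            t: [i for i in rest if t in dataset.sequences[i].labels]
            for t in dataset.vocabulary
        }
        for t, avail in support.items():
            if len(avail) < 2 * spec.min_per_label:
                raise ValueError(
                    f"label {t!r} has only {len(avail)} non-OOD sequences; "
                    f"cannot place {spec.min_per_label} in both val and test"
                )
        for t in sorted(support, key=lambda t: len(support[t])):
            for part in ("val", "test"):
                have = sum(
                    1
                    for i in rest
                    if assignment.get(i) == part and t in dataset.sequences[i].labels
                )
                for i in order:
                    if have >= spec.min_per_label:
                        break
                    if i not in assignment and t in dataset.sequences[i].labels:
                        assignment[i] = part
                        have += 1
                if have < spec.min_per_label:
                    raise ValueError(
                        f"cannot satisfy min_per_label={spec.min_per_label} for "
                        f"label {t!r} in {part}"
                    )

    n = len(rest)
    n_val = int(round(spec.fractions[1] * n))
    n_test = int(round(spec.fractions[2] * n))
    counts = {"train": 0, "val": 0, "test": 0}
    for part in assignment.values():
        counts[part] += 1
    for i in order:
        if i in assignment:
            continue
        if counts["val"] < n_val:
            assignment[i] = "val"
            counts["val"] += 1
        elif counts["test"] < n_test:
            assignment[i] = "test"
            counts["test"] += 1
        else:
            assignment[i] = "train"
            counts["train"] += 1

    spec.assignment = {
        dataset.sequences[i].id: part for i, part in assignment.items()
    }
    parts = {
        part: dataset.subset([i for i in rest if assignment[i] == part])
        for part in ("train", "val", "test")
    }
    ood_sets = [dataset.subset(ix) for ix in ood_indices]
    return parts["train"], parts["val"], parts["test"], ood_sets


def subset_by_label(
    dataset: LabeledDataset, term: str, size: int, seed: int = 0
) -> list[ProteinSequence]:
    """Uniform sample (without replacement) of ``size`` sequences carrying ``term``.

    A multilabel sequence may appear in several labels' subsets. When
    ``size`` equals the label's total count the full subset is returned
    in canonical dataset order. Deterministic given the seed.
    """
    if term not in dataset.label_index:
        raise KeyError(f"term {term!r} not in vocabulary")
    pool = dataset.label_index[term]
    if size > len(pool):
        raise ValueError(
            f"label {term!r} has only {len(pool)} sequences, requested {size}"
        )
    if size == len(pool):
        chosen = pool
    else:
        rng = np.random.default_rng(seed)
        chosen = sorted(rng.choice(len(pool), size=size, replace=False))
        chosen = [pool[j] for j in chosen]
    return [dataset.sequences[i] for i in chosen]
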