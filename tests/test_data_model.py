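import networkx as nx
import numpy as np
import pytest

from progeval import (
    LabeledDataset,
    OntologyDAG,
    ProteinSequence,
    SplitSpec,
    filter_dataset,
    impute_true_path,
    read_fasta,
    read_labels,
    split_dataset,
    subset_by_label,
    write_fasta,
    write_labels,
)
from progeval.data_model import ParseError


def make_dataset(entries, vocabulary=None):
    return LabeledDataset(
        [ProteinSequence(i, r, set(l)) for i, r, l in entries], vocabulary
    )


class TestFastaIO:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nACDE\n")
        recs = read_fasta(p)
        assert len(recs) == 1
        assert recs[0].id == "s1" and recs[0].residues == "ACDE"

    def test_order_preserved_and_uppercased(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nacde\n>s2\nGHIK\nLMNP\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["s1", "s2"]
        assert recs[0].residues == "ACDE"
        assert recs[1].residues == "GHIKLMNP"

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        assert read_fasta(p) == []

    def test_malformed_header_reports_line(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("ACDE\n>s1\nGHIK\n")
        with pytest.raises(ParseError, match=":1"):
            read_fasta(p)

    def test_strict_rejects_non_standard_residue(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nACBDE\n")
        with pytest.raises(ParseError, match="B"):
            read_fasta(p, strict=True)

    def test_round_trip(self, tmp_path):
        seqs = [ProteinSequence("x", "ACDE" * 50), ProteinSequence("y", "WYW")]
        p = tmp_path / "out.fasta"
        write_fasta(seqs, p)
        back = read_fasta(p)
        assert [(s.id, s.residues) for s in back] == [
            (s.id, s.residues) for s in seqs
        ]


class TestLabels:
    def test_attach_and_set_semantics(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("s1\tT1\ns1\tT2\ns1\tT1\n")
        ds = read_labels(p, [ProteinSequence("s1", "ACDE")])
        assert ds.sequences[0].labels == {"T1", "T2"}
        assert ds.vocabulary == ["T1", "T2"]

    def test_unknown_id_raises(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("nope\tT1\n")
        with pytest.raises(ParseError, match="nope"):
            read_labels(p, [ProteinSequence("s1", "ACDE")])

    def test_unlabeled_sequences_excluded(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("s1\tT1\n")
        ds = read_labels(
            p, [ProteinSequence("s1", "ACDE"), ProteinSequence("s2", "GHIK")]
        )
        assert ds.ids == ["s1"]

    def test_empty_label_file_excludes_all(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("")
        ds = read_labels(p, [ProteinSequence("s1", "ACDE")])
        assert len(ds) == 0

    def test_round_trip(self, tmp_path, corpus):
        ds, _ = corpus
        p = tmp_path / "l.tsv"
        write_labels(ds, p)
        back = read_labels(p, ds.sequences)
        assert all(
            a.labels == b.labels for a, b in zip(back, ds.sequences)
        )


class TestOntologyDAG:
    def test_rejects_cycle(self):
        with pytest.raises(ValueError, match="cycle"):
            OntologyDAG({"a", "b"}, {("a", "b"), ("b", "a")})

    def test_edge_tsv_round_trip(self, tmp_path):
        dag = OntologyDAG({"T1", "T2", "T3"}, {("T2", "T1"), ("T3", "T2")})
        p = tmp_path / "dag.tsv"
        dag.to_edge_tsv(p)
        back = OntologyDAG.from_edge_tsv(p)
        assert back.terms == dag.terms and back.edges == dag.edges

    def test_obo_subset_matches_edge_list(self, tmp_path):
        obo = tmp_path / "mini.obo"
        obo.write_text(
            "format-version: 1.2\n\n[Term]\nid: T2\nis_a: T1 ! parent\n\n"
            "[Term]\nid: T3\nis_a: T2\n\n[Typedef]\nid: part_of\n"
        )
        dag = OntologyDAG.from_obo(obo)
        assert dag.edges == {("T2", "T1"), ("T3", "T2")}
        assert dag.ancestors("T3") == {"T1", "T2"}


class TestTruePathImputation:
    dag = OntologyDAG({"T1", "T2", "T3"}, {("T2", "T1"), ("T3", "T2")})

    def test_parent_inherited(self):
        ds = make_dataset([("s", "ACDE", {"T2"})])
        out = impute_true_path(ds, self.dag)
        assert out.sequences[0].labels == {"T1", "T2"}

    def test_root_unchanged(self):
        ds = make_dataset([("s", "ACDE", {"T1"})])
        out = impute_true_path(ds, self.dag)
        assert out.sequences[0].labels == {"T1"}

    def test_chain_matches_bfs_oracle(self):
        ds = make_dataset([("s", "ACDE", {"T3"})])
        out = impute_true_path(ds, self.dag)
        g = nx.DiGraph([("T2", "T1"), ("T3", "T2")])
        oracle = {"T3"} | nx.descendants(g, "T3")
        assert out.sequences[0].labels == oracle == {"T1", "T2", "T3"}

    def test_idempotent_and_monotone(self, corpus):
        ds, dag = corpus
        once = impute_true_path(ds, dag)
        twice = impute_true_path(once, dag)
        for a, b, c in zip(ds, once, twice):
            assert a.labels <= b.labels == c.labels

    def test_unknown_label_raises(self):
        ds = make_dataset([("s", "ACDE", {"TX"})])
        with pytest.raises(ValueError, match="TX"):
            impute_true_path(ds, self.dag)


class TestFilter:
    def test_overlong_sequence_removed(self):
        ds = make_dataset(
            [("long", "A" * 2049, {"T1"}), ("ok", "A" * 2048, {"T1"})]
        )
        out, counts = filter_dataset(ds, min_per_label=1)
        assert out.ids == ["ok"] and counts["too_long"] == 1

    def test_non_standard_residue_removed(self):
        ds = make_dataset([("bad", "ACXDE", {"T1"}), ("ok", "ACDE", {"T1"})])
        out, counts = filter_dataset(ds)
        assert out.ids == ["ok"] and counts["non_standard"] == 1

    def test_rare_label_dropped_from_vocabulary(self):
        ds = make_dataset(
            [("a", "ACDE", {"T1", "T2"}), ("b", "GHIK", {"T1"})]
        )
        out, counts = filter_dataset(ds, min_per_label=2)
        assert out.vocabulary == ["T1"]
        assert counts["rare_label_terms"] == 1
        assert all("T2" not in s.labels for s in out)

    def test_clean_input_is_identity(self, corpus):
        ds, _ = corpus
        out, counts = filter_dataset(ds, min_per_label=1)
        assert len(out) == len(ds)
        assert sum(counts.values()) == 0

    def test_refilter_is_noop(self):
        ds = make_dataset(
            [("a", "ACDE", {"T1", "T2"}), ("b", "GHIK", {"T1"}),
             ("c", "B" * 3000, {"T2"})]
        )
        once, _ = filter_dataset(ds, min_per_label=2)
        twice, counts = filter_dataset(once, min_per_label=2)
        assert twice.ids == once.ids and sum(counts.values()) == 0

    def test_empty_result_raises(self):
        ds = make_dataset([("a", "ACDE", {"T1"})])
        with pytest.raises(ValueError):
            filter_dataset(ds, min_per_label=5)


class TestSplit:
    def test_deterministic(self, corpus):
        ds, _ = corpus
        a = split_dataset(ds, SplitSpec(seed=7, min_per_label=5))
        b = split_dataset(ds, SplitSpec(seed=7, min_per_label=5))
        for x, y in zip(a[:3], b[:3]):
            assert x.ids == y.ids

    def test_partitions_exactly(self, corpus):
        ds, _ = corpus
        train, val, test, ood = split_dataset(ds, SplitSpec(seed=3))
        ids = train.ids + val.ids + test.ids
        assert sorted(ids) == sorted(ds.ids)
        assert len(set(ids)) == len(ids)
        assert ood == []

    def test_fractions_respected(self, corpus):
        ds, _ = corpus
        train, val, test, _ = split_dataset(ds, SplitSpec(seed=3))
        assert abs(len(val) - 0.1 * len(ds)) <= 1
        assert abs(len(test) - 0.1 * len(ds)) <= 1

    def test_min_per_label_holds_in_val_and_test(self, corpus):
        ds, _ = corpus
        _, val, test, _ = split_dataset(ds, SplitSpec(seed=3, min_per_label=6))
        for part in (val, test):
            for t in ds.vocabulary:
                assert part.label_count(t) >= 6

    def test_ood_subset_routing(self, corpus):
        ds, _ = corpus
        combo = {"T3", "T4"}
        spec = SplitSpec(seed=3, ood_combinations=[combo])
        train, val, test, ood = split_dataset(ds, spec)
        assert len(ood) == 1
        for part in (train, val, test):
            assert not any(combo <= s.labels for s in part)
        assert all(combo <= s.labels for s in ood[0])

    def test_ood_exact_routing_is_stricter(self, corpus):
        ds, _ = corpus
        combo = {"T3", "T4"}
        subset = split_dataset(ds, SplitSpec(seed=3, ood_combinations=[combo]))
        exact = split_dataset(
            ds, SplitSpec(seed=3, ood_combinations=[combo], ood_match="exact")
        )
        assert len(exact[3][0]) <= len(subset[3][0])

    def test_infeasible_minimum_names_worst_label(self, corpus):
        ds, _ = corpus
        with pytest.raises(ValueError, match="min_per_label|only"):
            split_dataset(ds, SplitSpec(seed=3, min_per_label=1000))

    def test_spec_json_round_trip(self, tmp_path, corpus):
        ds, _ = corpus
        spec = SplitSpec(seed=5, ood_combinations=[{"T3", "T4"}], min_per_label=2)
        split_dataset(ds, spec)
        p = tmp_path / "spec.json"
        spec.to_json(p)
        back = SplitSpec.from_json(p)
        assert back.assignment == spec.assignment
        assert back.ood_combinations == spec.ood_combinations


class TestSubsetByLabel:
    def test_full_size_returns_canonical_order(self, corpus):
        ds, _ = corpus
        total = ds.label_count("T3")
        sub = subset_by_label(ds, "T3", total, seed=1)
        assert [s.id for s in sub] == [
            ds.sequences[i].id for i in ds.label_index["T3"]
        ]

    def test_deterministic_and_members_carry_term(self, corpus):
        ds, _ = corpus
        a = subset_by_label(ds, "T3", 20, seed=9)
        b = subset_by_label(ds, "T3", 20, seed=9)
        assert [s.id for s in a] == [s.id for s in b]
        assert len({s.id for s in a}) == 20
        assert all("T3" in s.labels for s in a)

    def test_oversized_request_raises(self, corpus):
        ds, _ = corpus
        with pytest.raises(ValueError):
            subset_by_label(ds, "T3", len(ds) + 1)
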