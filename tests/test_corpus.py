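"""Corpus model: readers, route filtering and fixture-corpus construction."""

from __future__ import annotations

import pytest

from herbnet.corpus import (
    MERIDIANS,
    CorpusError,
    CountSpec,
    HerbAnnotation,
    InfeasibleCountSpec,
    Prescription,
    build_fixture_corpus,
    count_occurrences,
    filter_by_route,
    read_annotations,
    read_transactions,
    write_annotations,
    write_transactions,
)

from conftest import make_corpus


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadTransactions:
    def test_rows_collapse_into_set_valued_prescriptions(self, tmp_path):
        path = _write(
            tmp_path,
            "t.csv",
            "prescription_id,herb_id,route\np1,A,internal\np1,B,internal\np2,A,internal\n",
        )
        corpus = read_transactions(path)
        assert corpus.n == 2
        herbs = {p.prescription_id: p.herbs for p in corpus.prescriptions}
        assert herbs == {"p1": {"A", "B"}, "p2": {"A"}}

    def test_duplicate_herb_rows_collapse(self, tmp_path):
        path = _write(
            tmp_path,
            "t.csv",
            "prescription_id,herb_id,route\np1,A,internal\np1,A,internal\n",
        )
        corpus = read_transactions(path)
        assert corpus.prescriptions[0].herbs == {"A"}

    def test_row_order_is_irrelevant(self, tmp_path):
        rows = ["p2,X,external", "p1,A,internal", "p1,B,internal"]
        a = _write(tmp_path, "a.csv", "prescription_id,herb_id,route\n" + "\n".join(rows))
        b = _write(tmp_path, "b.csv",
                   "prescription_id,herb_id,route\n" + "\n".join(reversed(rows)))
        ca, cb = read_transactions(a), read_transactions(b)
        assert [(p.prescription_id, p.route, p.herbs) for p in ca.prescriptions] == [
            (p.prescription_id, p.route, p.herbs) for p in cb.prescriptions
        ]

    @pytest.mark.parametrize(
        "body,match",
        [
            ("p1,A,topical\n", "unknown route"),
            ("p1,A,internal\np1,B,external\n", "two route"),
            ("", "empty"),
        ],
    )
    def test_malformed_input_is_a_hard_error(self, tmp_path, body, match):
        path = _write(tmp_path, "t.csv", "prescription_id,herb_id,route\n" + body)
        with pytest.raises(CorpusError, match=match):
            read_transactions(path)

    def test_tab_delimiter_autodetected(self, tmp_path):
        path = _write(tmp_path, "t.tsv",
                      "prescription_id\therb_id\troute\np1\tA\tinternal\n")
        assert read_transactions(path).n == 1

    def test_round_trip_preserves_corpus(self, tmp_path):
        corpus = make_corpus([{"A", "B"}, {"C"}, {"A", "C", "D"}])
        out = tmp_path / "rt.tsv"
        write_transactions(corpus, out)
        back = read_transactions(out)
        assert back.n == corpus.n
        assert [p.herbs for p in back.prescriptions] == [
            p.herbs for p in corpus.prescriptions
        ]


class TestReadAnnotations:
    HEADER = "herb_id,latin_name,category," + ",".join(MERIDIANS) + "\n"

    def test_flags_decode_to_meridian_sets(self, tmp_path):
        row = "Polygonum,Polygonum multiflorum Thunb.,17,Y,,,,,Y,,,,,,\n"
        ann = read_annotations(_write(tmp_path, "a.csv", self.HEADER + row))
        assert ann["Polygonum"].meridians == {"LR", "KI"}
        assert ann["Polygonum"].category == 17

    def test_empty_meridian_set_is_allowed(self, tmp_path):
        row = "Glycyrrhiza,Glycyrrhiza uralensis Fisch.,8,,,,,,,,,,,,\n"
        ann = read_annotations(_write(tmp_path, "a.csv", self.HEADER + row))
        assert ann["Glycyrrhiza"].meridians == frozenset()

    def test_duplicate_herb_id_rejected(self, tmp_path):
        rows = "X,x,1,,,,,,,,,,,,\nX,x,2,,,,,,,,,,,,\n"
        with pytest.raises(CorpusError, match="duplicate"):
            read_annotations(_write(tmp_path, "a.csv", self.HEADER + rows))

    def test_category_out_of_range_rejected(self, tmp_path):
        row = "X,x,21,,,,,,,,,,,,\n"
        with pytest.raises(CorpusError, match="category"):
            read_annotations(_write(tmp_path, "a.csv", self.HEADER + row))

    def test_unknown_meridian_column_rejected(self, tmp_path):
        header = "herb_id,latin_name,category,XX\n"
        with pytest.raises(CorpusError, match="meridian column"):
            read_annotations(_write(tmp_path, "a.csv", header + "X,x,1,Y\n"))

    def test_round_trip(self, tmp_path):
        ann = {
            "A": HerbAnnotation("A", "Aa", frozenset({"LR", "ST"}), 17),
            "B": HerbAnnotation("B", "Bb", frozenset(), 2),
        }
        out = tmp_path / "a.tsv"
        write_annotations(ann, out)
        assert read_annotations(out) == ann


class TestFilterByRoute:
    def test_partitions_counts_by_route(self):
        corpus = make_corpus([{"A"}] * 5)
        external = [
            Prescription(f"e{i}", "external", frozenset({"X"})) for i in range(3)
        ]
        corpus.prescriptions.extend(external)
        internal = filter_by_route(corpus, "internal")
        ext = filter_by_route(corpus, "external")
        assert internal.n == 5 and ext.n == 3
        assert internal.n + ext.n == corpus.n

    def test_herb_sets_preserved_and_annotations_carried(self):
        ann = {"A": HerbAnnotation("A")}
        corpus = make_corpus([{"A", "B"}], annotations=ann)
        filtered = filter_by_route(corpus, "internal")
        assert filtered.prescriptions[0].herbs == {"A", "B"}
        assert filtered.annotations == ann

    def test_empty_result_is_fine(self):
        corpus = make_corpus([{"A"}])
        assert filter_by_route(corpus, "external").n == 0

    def test_unknown_route_rejected(self):
        with pytest.raises(CorpusError):
            filter_by_route(make_corpus([{"A"}]), "topical")


class TestBuildFixtureCorpus:
    def test_pair_spec_realizes_published_counts(self):
        spec = CountSpec(
            n=312,
            marginals={"Angelica": 171, "Polygonum": 175},
            joints={frozenset({"Angelica", "Polygonum"}): 120},
        )
        corpus = build_fixture_corpus(spec)
        assert corpus.n == 312
        assert count_occurrences(corpus, {"Angelica"}) == 171
        assert count_occurrences(corpus, {"Polygonum"}) == 175
        assert count_occurrences(corpus, {"Angelica", "Polygonum"}) == 120

    def test_triple_spec_with_member_pairs(self):
        triple = frozenset({"A", "B", "C"})
        spec = CountSpec(
            n=50,
            marginals={"A": 20, "B": 18, "C": 15},
            joints={
                triple: 5,
                frozenset({"A", "B"}): 9,
                frozenset({"A", "C"}): 7,
                frozenset({"B", "C"}): 6,
            },
        )
        corpus = build_fixture_corpus(spec)
        for items, want in spec.joints.items():
            assert count_occurrences(corpus, items) == want
        for herb, want in spec.marginals.items():
            assert count_occurrences(corpus, {herb}) == want

    def test_zero_joint_keeps_herbs_disjoint(self):
        spec = CountSpec(n=4, marginals={"A": 2, "B": 2},
                         joints={frozenset({"A", "B"}): 0})
        corpus = build_fixture_corpus(spec)
        assert count_occurrences(corpus, {"A", "B"}) == 0
        assert count_occurrences(corpus, {"A"}) == 2
        assert count_occurrences(corpus, {"B"}) == 2

    def test_joint_exceeding_marginal_is_infeasible(self):
        with pytest.raises(InfeasibleCountSpec):
            CountSpec(n=10, marginals={"A": 3, "B": 3},
                      joints={frozenset({"A", "B"}): 5})

    def test_blocks_exceeding_n_is_infeasible(self):
        spec = CountSpec(n=5, marginals={"A": 4, "B": 4},
                         joints={frozenset({"A", "B"}): 1})
        with pytest.raises(InfeasibleCountSpec, match="N="):
            build_fixture_corpus(spec)

    def test_negative_counts_rejected(self):
        with pytest.raises(InfeasibleCountSpec, match="negative"):
            CountSpec(n=10, marginals={"A": -1})

    def test_overlapping_triples_detected_as_infeasible(self):
        # both triples contain {A,B}; their blocks alone exceed the pair count
        joints = {
            frozenset({"A", "B", "C"}): 4,
            frozenset({"A", "B", "D"}): 4,
            frozenset({"A", "B"}): 5,
        }
        spec = CountSpec(n=100, marginals={"A": 20, "B": 20, "C": 10, "D": 10},
                         joints=joints)
        with pytest.raises(InfeasibleCountSpec):
            build_fixture_corpus(spec)

    def test_deterministic_given_spec_and_policy(self):
        spec = CountSpec(n=20, marginals={"A": 6, "B": 5},
                         joints={frozenset({"A", "B"}): 3})
        a = build_fixture_corpus(spec)
        b = build_fixture_corpus(spec)
        assert [p.herbs for p in a.prescriptions] == [p.herbs for p in b.prescriptions]

    def test_filler_policies(self):
        spec = CountSpec(n=6, marginals={"A": 2})
        dummies = build_fixture_corpus(spec, "dummy_herb")
        pads = {h for p in dummies.prescriptions[2:] for h in p.herbs}
        assert len(pads) == 4  # one fresh dummy per pad transaction
        placebo = build_fixture_corpus(spec, "empty_pad")
        pads = {h for p in placebo.prescriptions[2:] for h in p.herbs}
        assert len(pads) == 1  # one shared placebo herb
        for c in (dummies, placebo):
            assert all(p.herbs for p in c.prescriptions)
            assert count_occurrences(c, {"A"}) == 2
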