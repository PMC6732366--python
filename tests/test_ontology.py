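import random

import pytest

from hposhuffle.errors import CycleError, FormatError
from hposhuffle.ontology import (
    GenePhenotypeMap,
    PhenotypeRepository,
    ancestor_closure,
    build_hpr,
    ids_in,
    load_disease_annotations,
    load_gene_phenotype_map,
    name_contains,
    parse_obo,
    read_hpr,
    select_all,
    write_hpr,
)

from conftest import make_obo


class TestParseObo:
    def test_minimal_chain(self, toy_obo):
        g = parse_obo(toy_obo)
        assert len(g) == 3
        assert g.root_ids == {"A"}
        assert g.terms["C"].parent_ids == {"B"}
        assert not g.terms["C"].obsolete

    def test_obsolete_term_flagged_and_excluded_from_closure(self, tmp_path):
        path = tmp_path / "obs.obo"
        path.write_text(
            make_obo(
                [
                    ("A", "root", [], False),
                    ("B", "mid", ["A"], False),
                    ("C", "leaf", ["B"], True),
                ]
            )
        )
        g = parse_obo(path)
        assert g.terms["C"].obsolete
        assert ancestor_closure(g, {"C"}) == set()

    def test_cycle_raises(self, tmp_path):
        path = tmp_path / "cycle.obo"
        path.write_text(
            make_obo([("B", "b", ["C"], False), ("C", "c", ["B"], False)])
        )
        with pytest.raises(CycleError) as err:
            parse_obo(path)
        assert set(err.value.cycle) == {"B", "C"}

    def test_stanza_without_id_names_line(self, tmp_path):
        path = tmp_path / "bad.obo"
        path.write_text("format-version: 1.2\n\n[Term]\nname: orphan\n")
        with pytest.raises(FormatError, match=r"line 3"):
            parse_obo(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(IOError):
            parse_obo(tmp_path / "nope.obo")

    def test_round_trip_of_generated_ontologies(self, tmp_path):
        rng = random.Random(7)
        for trial in range(20):
            n = rng.randint(2, 12)
            spec = [("T0", "root", [], False)]
            for i in range(1, n):
                parents = sorted(
                    rng.sample(range(i), k=min(i, rng.randint(1, 2)))
                )
                spec.append((f"T{i}", f"t{i}", [f"T{p}" for p in parents], False))
            path = tmp_path / f"rt{trial}.obo"
            path.write_text(make_obo(spec))
            g = parse_obo(path)
            assert {(t, frozenset(ps)) for t, _, ps, _ in spec} == {
                (t.term_id, t.parent_ids) for t in g.terms.values()
            }


class TestDiseaseAnnotations:
    def test_thirteen_rows_load(self, disease_tsv):
        records = load_disease_annotations(disease_tsv)
        assert len(records) == 13
        assert records[0].disease_id == "608217"
        assert records[0].term_id == "HP:0000006"

    def test_header_only_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("database_id\tdisease_name\thpo_id\n")
        assert load_disease_annotations(path) == []

    def test_bad_accession_row_skipped_others_kept(self, tmp_path):
        path = tmp_path / "mixed.tsv"
        path.write_text(
            "database_id\tdisease_name\thpo_id\n"
            "1\tD1\tHP:12\n"
            "2\tD2\tHP:0000001\n"
        )
        records = load_disease_annotations(path)
        assert [r.disease_id for r in records] == ["2"]

    def test_all_rows_bad_is_hard_error(self, tmp_path):
        path = tmp_path / "allbad.tsv"
        path.write_text("database_id\tdisease_name\thpo_id\n1\tD1\tHP:12\n")
        with pytest.raises(FormatError):
            load_disease_annotations(path)


class TestBuildHpr:
    def test_distinct_union_over_all_diseases(self, disease_tsv):
        records = load_disease_annotations(disease_tsv)
        hpr = build_hpr(records, select_all)
        assert len(hpr.term_ids) == 11
        assert hpr.source_disease_ids == {"608217", "611277", "267740"}

    def test_single_disease_selection(self, disease_tsv):
        records = load_disease_annotations(disease_tsv)
        hpr = build_hpr(records, ids_in({"608217"}))
        assert hpr.term_ids == {"HP:0000006", "HP:0002069", "HP:0003593"}

    def test_empty_selection(self, disease_tsv):
        records = load_disease_annotations(disease_tsv)
        hpr = build_hpr(records, ids_in({"999999"}))
        assert hpr.term_ids == frozenset()

    def test_name_substring_selector(self, disease_tsv):
        records = load_disease_annotations(disease_tsv)
        hpr = build_hpr(records, name_contains("retinal"))
        assert hpr.source_disease_ids == {"267740"}

    def test_invariant_to_row_order_and_duplication(self, disease_tsv):
        records = load_disease_annotations(disease_tsv)
        baseline = build_hpr(records, select_all)
        rng = random.Random(3)
        shuffled = records * 2
        rng.shuffle(shuffled)
        assert build_hpr(shuffled, select_all).term_ids == baseline.term_ids

    def test_closure_never_shrinks_repository(self, disease_tsv, tmp_path):
        records = load_disease_annotations(disease_tsv)
        # small ontology over a few of the terms; the rest fall outside it
        path = tmp_path / "mini.obo"
        path.write_text(
            make_obo(
                [
                    ("HP:0000001", "All", [], False),
                    ("HP:0001250", "Seizure", ["HP:0000001"], False),
                    ("HP:0002069", "GTCS", ["HP:0001250"], False),
                ]
            )
        )
        g = parse_obo(path)
        plain = build_hpr(records, select_all)
        closed = build_hpr(records, select_all, graph=g, apply_closure=True)
        assert closed.closure_applied
        assert len(closed.term_ids) >= len(plain.term_ids)
        assert "HP:0001250" in closed.term_ids  # ancestor pulled in


class TestAncestorClosure:
    def test_chain_excludes_root(self, toy_obo):
        g = parse_obo(toy_obo)
        assert ancestor_closure(g, {"C"}) == {"C", "B"}

    def test_root_identity(self, toy_obo):
        g = parse_obo(toy_obo)
        assert ancestor_closure(g, {"A"}) == {"A"}

    def test_missing_term_kept(self, toy_obo):
        g = parse_obo(toy_obo)
        assert ancestor_closure(g, {"Z"}) == {"Z"}

    def test_idempotent_on_random_dags(self, tmp_path):
        rng = random.Random(11)
        for trial in range(25):
            n = rng.randint(3, 15)
            spec = [("N0", "root", [], False)]
            edges = {}
            for i in range(1, n):
                parents = rng.sample(range(i), k=min(i, rng.randint(1, 3)))
                spec.append((f"N{i}", "x", [f"N{p}" for p in parents], False))
                edges[f"N{i}"] = {f"N{p}" for p in parents}
            path = tmp_path / f"dag{trial}.obo"
            path.write_text(make_obo(spec))
            g = parse_obo(path)
            seed_terms = set(rng.sample([s[0] for s in spec], k=rng.randint(1, n)))
            once = ancestor_closure(g, seed_terms)
            assert ancestor_closure(g, once) == once
            # brute-force reachability oracle (root excluded unless seeded)
            expected = set(seed_terms)
            frontier = list(seed_terms)
            while frontier:
                t = frontier.pop()
                for p in edges.get(t, ()):
                    if p not in expected:
                        expected.add(p)
                        frontier.append(p)
            expected -= {"N0"} - seed_terms
            assert once == expected


class TestGenePhenotypeMap:
    def test_case_fold_and_dedupe(self, annotation_writer):
        path = annotation_writer(
            [("geneX", "HP:0000001"), ("genex", "HP:0000001"), ("geneX", "HP:0000002")]
        )
        m = load_gene_phenotype_map(path)
        assert m.entries == {"GENEX": frozenset({"HP:0000001", "HP:0000002"})}

    def test_empty_file(self, tmp_path):
        path = tmp_path / "none.tsv"
        path.write_text("gene_symbol\thpo_id\n")
        assert len(load_gene_phenotype_map(path)) == 0

    def test_absent_gene_lookup_is_empty(self):
        m = GenePhenotypeMap(entries={"A": frozenset({"HP:0000001"})})
        assert m.terms_for("nonexistent") == frozenset()
        assert m.terms_for(" a ") == frozenset({"HP:0000001"})


def test_hpr_round_trips_through_file(tmp_path):
    hpr = PhenotypeRepository(
        term_ids=frozenset({"HP:0000001", "HP:0000002"}),
        source_disease_ids=frozenset({"1"}),
    )
    path = tmp_path / "hpr.txt"
    write_hpr(hpr, path)
    assert read_hpr(path).term_ids == hpr.term_ids
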