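"""Ontology parsing, validation, traversal and version diffing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ontodrift import (
    OntologyError,
    Term,
    UnknownTermError,
    diff_ontologies,
    make_ontology,
    parse_obo,
)
from .conftest import CHAIN_OBO, brute_force_ancestors, brute_force_descendants, random_dag_ontology


class TestParseObo:
    def test_two_term_stanza_yields_terms_and_relation(self):
        obo = (
            "format-version: 1.2\n\n"
            "[Term]\nid: SY:0000001\nname: A\nnamespace: biological_process\n\n"
            "[Term]\nid: SY:0000002\nname: B\nnamespace: biological_process\n"
            "is_a: SY:0000001\n"
        )
        v = parse_obo(obo)
        assert set(v.terms) == {"SY:0000001", "SY:0000002"}
        assert v.relations == {("SY:0000002", "SY:0000001", "is_a")}

    def test_obsolete_term_keeps_replacement_and_no_relations(self, chain_ontology):
        t = chain_ontology.terms["SY:0000004"]
        assert t.is_obsolete and t.replaced_by == ("SY:0000002",)
        assert all("SY:0000004" not in (c, p) for c, p, _ in chain_ontology.relations)

    def test_part_of_captured_as_typed_relation(self, chain_ontology):
        assert ("SY:0000003", "SY:0000002", "part_of") in chain_ontology.relations

    def test_non_propagating_relationship_stored_as_other(self):
        obo = (
            "format-version: 1.2\n\n"
            "[Term]\nid: SY:0000001\nname: A\nnamespace: biological_process\n\n"
            "[Term]\nid: SY:0000002\nname: B\nnamespace: biological_process\n"
            "is_a: SY:0000001\nrelationship: regulates SY:0000001\n"
        )
        v = parse_obo(obo)
        assert ("SY:0000002", "SY:0000001", "other") in v.relations
        # and it never propagates
        assert v.closure("SY:0000002", "ancestors") == {"SY:0000002", "SY:0000001"}

    def test_cycle_is_rejected_naming_a_cycle(self):
        obo = (
            "format-version: 1.2\n\n"
            "[Term]\nid: SY:0000001\nname: A\nnamespace: biological_process\n"
            "is_a: SY:0000002\n\n"
            "[Term]\nid: SY:0000002\nname: B\nnamespace: biological_process\n"
            "is_a: SY:0000001\n"
        )
        with pytest.raises(OntologyError, match="cycle"):
            parse_obo(obo)

    def test_relation_to_missing_term_is_rejected(self):
        obo = (
            "format-version: 1.2\n\n"
            "[Term]\nid: SY:0000001\nname: A\nnamespace: biological_process\n"
            "is_a: SY:0000099\n"
        )
        with pytest.raises(OntologyError, match="missing term"):
            parse_obo(obo)

    def test_multiple_roots_in_namespace_rejected(self):
        obo = (
            "format-version: 1.2\n\n"
            "[Term]\nid: SY:0000001\nname: A\nnamespace: biological_process\n\n"
            "[Term]\nid: SY:0000002\nname: B\nnamespace: biological_process\n"
        )
        with pytest.raises(OntologyError, match="root"):
            parse_obo(obo)


class TestClosure:
    def test_chain_closures(self, chain_ontology):
        assert chain_ontology.closure("SY:0000003", "ancestors") == {
            "SY:0000003", "SY:0000002", "SY:0000001",
        }
        assert chain_ontology.closure("SY:0000001", "descendants") == {
            "SY:0000001", "SY:0000002", "SY:0000003",
        }

    def test_closure_is_reflexive_on_isolated_term(self):
        v = make_ontology("v", [("SY:0000001", "root", "biological_process")])
        assert v.closure("SY:0000001", "ancestors") == {"SY:0000001"}

    def test_unknown_term_raises_lookup_error(self, chain_ontology):
        with pytest.raises(UnknownTermError):
            chain_ontology.closure("SY:9999999", "ancestors")

    @pytest.mark.parametrize("seed", range(10))
    def test_closures_match_brute_force_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        v = random_dag_ontology(rng, n_terms=int(rng.integers(3, 16)))
        for t in v.terms:
            assert v.closure(t, "ancestors") == brute_force_ancestors(v, t)
            assert v.closure(t, "descendants") == brute_force_descendants(v, t)


class TestAcyclicityProperty:
    @given(st.integers(0, 10_000))
    def test_back_edge_into_random_dag_is_always_rejected(self, seed):
        rng = np.random.default_rng(seed)
        v = random_dag_ontology(rng, n_terms=int(rng.integers(4, 12)))
        # add a back-edge: parent of some relation becomes child of its child
        c, p, _ = sorted(v.relations)[int(rng.integers(len(v.relations)))]
        broken = make_ontology(
            "broken", v.terms.values(), set(v.relations) | {(p, c, "is_a")}
        )
        with pytest.raises(OntologyError, match="cycle"):
            broken.validate()


class TestDiff:
    def _single(self, *term_ids, label="v", obsolete=(), replaced=None):
        terms = []
        for tid in term_ids:
            terms.append(
                Term(
                    tid, tid, "biological_process",
                    is_obsolete=tid in obsolete,
                    replaced_by=(replaced.get(tid, ()) if replaced else ()),
                )
            )
        rels = [
            (t.id, term_ids[0], "is_a") for t in terms[1:] if not t.is_obsolete
        ]
        return make_ontology(label, terms, rels)

    def test_pure_addition(self):
        old = self._single("A")
        new = self._single("A", "B", label="w")
        d = diff_ontologies(old, new)
        assert d.added_terms == {"B"}
        assert not d.deleted_terms and not d.mapped_terms

    def test_identical_versions_give_empty_diff(self):
        old = self._single("A", "B")
        assert diff_ontologies(old, old).is_empty()

    def test_obsoleted_with_replacement_is_mapped_not_deleted(self):
        old = self._single("A", "X")
        new = self._single("A", "X", label="w", obsolete={"X"}, replaced={"X": ("A",)})
        d = diff_ontologies(old, new)
        assert d.mapped_terms == {("X", "A")}
        assert "X" not in d.deleted_terms

    def test_absent_or_unreplaced_obsolete_counts_deleted(self):
        old = self._single("A", "X", "Y")
        new = self._single("A", "Y", label="w", obsolete={"Y"})
        d = diff_ontologies(old, new)
        assert d.deleted_terms == {"X", "Y"}

    def test_relation_diff_on_typed_triples(self):
        old = self._single("A", "B")
        new_terms = [Term(t, t, "biological_process") for t in ("A", "B")]
        new = make_ontology("w", new_terms, [("B", "A", "part_of")])
        d = diff_ontologies(old, new)
        assert d.deleted_relations == {("B", "A", "is_a")}
        assert d.added_relations == {("B", "A", "part_of")}

    @pytest.mark.parametrize("seed", range(5))
    def test_self_diff_empty_on_random_versions(self, seed):
        v = random_dag_ontology(np.random.default_rng(seed), 10)
        assert diff_ontologies(v, v).is_empty()

    @pytest.mark.parametrize("seed", range(5))
    def test_added_terms_compose_across_three_growing_versions(self, seed):
        rng = np.random.default_rng(seed)
        v3 = random_dag_ontology(rng, 12)
        ids = sorted(v3.terms)

        def prefix(n, label):
            keep = set(ids[:n])
            rels = {r for r in v3.relations if r[0] in keep and r[1] in keep}
            return make_ontology(label, [v3.terms[t] for t in sorted(keep)], rels)

        v1, v2 = prefix(6, "v1"), prefix(9, "v2")
        a13 = diff_ontologies(v1, v3).added_terms
        a12 = diff_ontologies(v1, v2).added_terms
        a23 = diff_ontologies(v2, v3).added_terms
        assert a13 <= a12 | a23
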