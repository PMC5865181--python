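"""Hypergeometric test, BH-FDR, enrichment runs and the version grid."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ontodrift import (
    AnnotationRecord,
    AnnotationSet,
    GeneSignature,
    bh_fdr,
    enrich,
    hypergeometric_upper_tail,
    make_ontology,
    propagate,
    pvalue_grid,
    significant_terms,
)
from .conftest import hypergeom_tail_enumeration


class TestHypergeometricUpperTail:
    def test_k_zero_is_certain(self):
        assert hypergeometric_upper_tail(0, 5, 3, 10) == 1.0

    def test_all_background_annotated_is_certain(self):
        assert hypergeometric_upper_tail(3, 3, 10, 10) == pytest.approx(1.0)

    def test_small_case_equals_combinatorial_ratio(self):
        # N=10, K=4, n=3, k=3: C(4,3)/C(10,3)
        assert hypergeometric_upper_tail(3, 3, 4, 10) == pytest.approx(4 / 120, abs=1e-15)

    def test_matches_enumeration_on_modest_cases(self):
        for N, K, n, k in [(8, 3, 4, 2), (10, 5, 5, 4), (12, 6, 4, 1), (7, 2, 7, 2)]:
            assert hypergeometric_upper_tail(k, n, K, N) == pytest.approx(
                hypergeom_tail_enumeration(k, n, K, N), abs=1e-12
            )

    def test_non_increasing_in_k(self):
        ps = [hypergeometric_upper_tail(k, 10, 15, 40) for k in range(11)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize(
        "k,n,K,N", [(4, 3, 5, 10), (1, 11, 5, 10), (1, 5, 11, 10), (-1, 3, 5, 10)]
    )
    def test_bound_violations_rejected(self, k, n, K, N):
        with pytest.raises(ValueError):
            hypergeometric_upper_tail(k, n, K, N)


class TestBhFdr:
    def test_single_pvalue_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_stepup_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_pvalues_unchanged(self):
        assert bh_fdr([0.2, 0.2, 0.2, 0.2]) == pytest.approx([0.2] * 4)

    def test_empty_input(self):
        assert len(bh_fdr([])) == 0

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1, size=50)
        assert (bh_fdr(p) >= p - 1e-15).all()

    @given(st.integers(0, 10_000))
    def test_matches_statsmodels_reference(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-12, 1, size=int(rng.integers(1, 40)))
        ours = bh_fdr(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert ours == pytest.approx(theirs, abs=1e-12)


def two_level_ontology():
    terms = [("SY:0000001", "root", "biological_process"),
             ("SY:0000002", "small", "biological_process"),
             ("SY:0000003", "big", "biological_process")]
    rels = [("SY:0000002", "SY:0000001", "is_a"),
            ("SY:0000003", "SY:0000001", "is_a")]
    return make_ontology("v", terms, rels).validate()


def annotations(pairs):
    return AnnotationSet(
        "v", tuple(AnnotationRecord(g, g, t, "IDA", "P") for g, t in pairs), filtered=True
    )


def fixture_index():
    """20-gene background: 4 genes in the small term, 16 in the big one."""
    pairs = [(f"G{i:02d}", "SY:0000002") for i in range(4)]
    pairs += [(f"G{i:02d}", "SY:0000003") for i in range(4, 20)]
    return propagate(annotations(pairs), two_level_ontology())


class TestEnrich:
    def test_signature_equal_to_small_term_minimises_its_p(self):
        idx = fixture_index()
        sig = GeneSignature("s", frozenset(f"G{i:02d}" for i in range(4)))
        res = enrich(sig, idx)
        table = res.table
        assert table["p"].idxmin() == "SY:0000002"
        assert table.at["SY:0000002", "p"] == pytest.approx(
            hypergeom_tail_enumeration(4, 4, 4, 20), abs=1e-12
        )
        assert (table["q"] >= table["p"] - 1e-15).all()

    def test_unannotated_signature_yields_empty_status(self):
        idx = fixture_index()
        res = enrich(GeneSignature("s", frozenset({"NOPE1", "NOPE2"})), idx)
        assert res.status == "no_annotated_signature_genes"
        assert res.table.empty and res.significant_terms() == frozenset()

    def test_all_q_above_alpha_keeps_rows_but_no_significance(self):
        idx = fixture_index()
        sig = GeneSignature("s", frozenset({"G00", "G04"}))
        res = enrich(sig, idx, alpha=1e-6)
        assert len(res.table) > 0 and res.significant_terms() == frozenset()

    def test_adding_unannotated_gene_changes_nothing(self):
        idx = fixture_index()
        sig = GeneSignature("s", frozenset(f"G{i:02d}" for i in range(4)))
        bigger = GeneSignature("s2", sig.genes | {"UNSEEN"})
        res1, res2 = enrich(sig, idx), enrich(bigger, idx)
        assert res1.n_effective == res2.n_effective
        assert (res1.table[["k", "n", "K", "N", "p"]]
                .equals(res2.table[["k", "n", "K", "N", "p"]]))
        assert res2.n_dropped_unannotated == 1

    def test_explicit_background_restricts_counts(self):
        idx = fixture_index()
        sig = GeneSignature("s", frozenset({"G00", "G01"}))
        res = enrich(sig, idx, background=[f"G{i:02d}" for i in range(10)])
        assert res.table.at["SY:0000002", "N"] == 10
        assert res.table.at["SY:0000002", "K"] == 4

    def test_significance_boundary_inclusive(self):
        qs = np.array([0.04, 0.05, 0.051])
        assert (qs <= 0.05).sum() == 2  # the convention enrich applies to q


class TestSignificantTerms:
    def test_matches_threshold_rule(self):
        idx = fixture_index()
        sig = GeneSignature("s", frozenset(f"G{i:02d}" for i in range(4)))
        res = enrich(sig, idx, alpha=0.05)
        assert significant_terms(res) == frozenset(
            res.table.index[res.table["q"] <= 0.05]
        )


class TestPvalueGrid:
    def _series(self):
        v1 = two_level_ontology()
        terms = list(v1.terms.values()) + [
            type(next(iter(v1.terms.values())))(
                "SY:0000004", "late", "biological_process"
            )
        ]
        rels = set(v1.relations) | {("SY:0000004", "SY:0000001", "is_a")}
        v2 = make_ontology("w", terms, rels).validate()
        a1 = annotations(
            [(f"G{i:02d}", "SY:0000002") for i in range(4)]
            + [(f"G{i:02d}", "SY:0000003") for i in range(4, 20)]
        )
        a2 = annotations(
            [(f"G{i:02d}", "SY:0000002") for i in range(4)]
            + [(f"G{i:02d}", "SY:0000003") for i in range(4, 20)]
            + [(f"G{i:02d}", "SY:0000004") for i in range(4)]
        )
        return [("v", v1), ("w", v2)], [("a1", a1), ("a2", a2)]

    def test_grid_runs_every_version_pair(self):
        ontologies, asets = self._series()
        sig = GeneSignature("s", frozenset(f"G{i:02d}" for i in range(4)))
        grid = pvalue_grid(sig, ontologies, asets)
        assert set(grid.results) == {("v", "a1"), ("v", "a2"), ("w", "a1"), ("w", "a2")}

    def test_term_absent_from_early_ontology_has_no_cell(self):
        ontologies, asets = self._series()
        sig = GeneSignature("s", frozenset(f"G{i:02d}" for i in range(4)))
        grid = pvalue_grid(sig, ontologies, asets)
        long = grid.long_table()
        early = long[(long["obo_version"] == "v") & (long["term"] == "SY:0000004")]
        late = long[(long["obo_version"] == "w") & (long["gaf_version"] == "a2")
                    & (long["term"] == "SY:0000004")]
        assert early.empty and len(late) == 1

    def test_identical_axes_give_identical_cells(self):
        ontologies, asets = self._series()
        sig = GeneSignature("s", frozenset(f"G{i:02d}" for i in range(4)))
        _, v1 = ontologies[0]
        _, a1 = asets[0]
        grid = pvalue_grid(sig, [("x", v1), ("y", v1)], [("a", a1), ("b", a1)])
        tables = [r.table for r in grid.results.values()]
        assert len(tables) == 4
        for t in tables[1:]:
            assert t.equals(tables[0])
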