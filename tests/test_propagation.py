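"""True-path propagation, Resnik IC and the class-IC comparison."""

import numpy as np
import pandas as pd
import pytest

from ontodrift import (
    AnnotationRecord,
    AnnotationSet,
    Term,
    build_ic_table,
    classify_genes,
    compare_class_ic,
    gene_mean_ic,
    make_ontology,
    propagate,
    term_stats,
)
from .conftest import brute_force_descendants, random_annotations, random_dag_ontology


def chain(label="v"):
    terms = [("SY:0000001", "root", "biological_process"),
             ("SY:0000002", "mid", "biological_process"),
             ("SY:0000003", "leaf", "biological_process")]
    rels = [("SY:0000002", "SY:0000001", "is_a"),
            ("SY:0000003", "SY:0000002", "is_a")]
    return make_ontology(label, terms, rels).validate()


def aset(pairs, label="v"):
    return AnnotationSet(
        version_label=label,
        records=tuple(
            AnnotationRecord(g, g, t, "IDA", "P") for g, t in pairs
        ),
        filtered=True,
    )


class TestPropagate:
    def test_leaf_annotation_reaches_all_ancestors(self):
        idx = propagate(aset([("GENE0001", "SY:0000003")]), chain())
        for t in ("SY:0000001", "SY:0000002", "SY:0000003"):
            assert idx.term_genes[t] == {"GENE0001"}
        assert idx.root_gene_count == {"biological_process": 1}

    def test_gene_on_two_siblings_counted_once_at_parent(self):
        terms = [("SY:0000001", "root", "biological_process"),
                 ("SY:0000002", "a", "biological_process"),
                 ("SY:0000003", "b", "biological_process")]
        rels = [("SY:0000002", "SY:0000001", "is_a"),
                ("SY:0000003", "SY:0000001", "is_a")]
        v = make_ontology("v", terms, rels)
        idx = propagate(aset([("G", "SY:0000002"), ("G", "SY:0000003")]), v)
        assert idx.term_genes["SY:0000001"] == {"G"}

    def test_empty_annotations_give_empty_index(self):
        idx = propagate(aset([]), chain())
        assert idx.term_genes == {}
        assert idx.root_gene_count == {"biological_process": 0}

    def test_obsolete_term_remapped_through_replaced_by(self):
        terms = [Term("SY:0000001", "root", "biological_process"),
                 Term("SY:0000002", "kept", "biological_process"),
                 Term("SY:0000009", "dead", "biological_process",
                      is_obsolete=True, replaced_by=("SY:0000002",))]
        v = make_ontology("v", terms, [("SY:0000002", "SY:0000001", "is_a")])
        idx = propagate(aset([("G", "SY:0000009")]), v)
        assert idx.term_genes["SY:0000002"] == {"G"}
        assert idx.n_remapped_obsolete == 1 and idx.n_dropped_records == 0

    def test_unplaceable_term_dropped_and_tallied(self):
        idx = propagate(aset([("G", "SY:4444444")]), chain())
        assert idx.n_dropped_records == 1 and idx.term_genes == {}

    def test_subset_invariant_along_every_edge(self):
        rng = np.random.default_rng(5)
        v = random_dag_ontology(rng, 15)
        idx = propagate(random_annotations(rng, v, 30, 60), v)
        for c, p, r in v.relations:
            if r in ("is_a", "part_of"):
                assert idx.term_genes.get(c, frozenset()) <= idx.term_genes.get(p, frozenset())

    @pytest.mark.parametrize("seed", range(10))
    def test_counts_match_brute_force_descendant_recount(self, seed):
        rng = np.random.default_rng(seed)
        v = random_dag_ontology(rng, int(rng.integers(5, 21)))
        ann = random_annotations(rng, v, 25, 50)
        idx = propagate(ann, v)
        direct = {}
        for r in ann.records:
            direct.setdefault(r.term, set()).add(r.gene_symbol)
        for t in v.terms:
            expected = set()
            for d in brute_force_descendants(v, t):
                expected |= direct.get(d, set())
            assert idx.term_genes.get(t, frozenset()) == expected

    def test_growth_monotonicity_at_ancestors(self):
        rng = np.random.default_rng(7)
        v = random_dag_ontology(rng, 12)
        ann = random_annotations(rng, v, 20, 30)
        idx = propagate(ann, v)
        extra_term = sorted(v.terms)[-1]
        grown = AnnotationSet(
            version_label="v",
            records=ann.records + (AnnotationRecord("NEWG", "NEWG", extra_term, "IDA", "P"),),
            filtered=True,
        )
        idx2 = propagate(grown, v)
        for t in v.terms:
            assert len(idx2.term_genes.get(t, ())) >= len(idx.term_genes.get(t, ()))


class TestInformationContent:
    def test_root_has_probability_one_and_zero_ic(self):
        idx = propagate(aset([("G1", "SY:0000003"), ("G2", "SY:0000002")]), chain())
        count, p, ic = term_stats(idx, "SY:0000001")
        assert (count, p, ic) == (2, 1.0, 0.0)

    def test_one_in_1024_genes_is_ten_bits(self):
        pairs = [("G0", "SY:0000003")] + [(f"G{i}", "SY:0000002") for i in range(1, 1024)]
        idx = propagate(aset(pairs), chain())
        count, p, ic = term_stats(idx, "SY:0000003")
        assert count == 1 and ic == pytest.approx(10.0)

    def test_quarter_probability_is_two_bits(self):
        pairs = [("G1", "SY:0000003"), ("G2", "SY:0000003")] + [
            (f"G{i}", "SY:0000002") for i in range(3, 9)
        ]
        idx = propagate(aset(pairs), chain())
        count, p, ic = term_stats(idx, "SY:0000003")
        assert (count, p, ic) == (2, 0.25, 2.0)

    def test_zero_gene_term_absent_not_crash(self):
        idx = propagate(aset([("G", "SY:0000002")]), chain())
        assert term_stats(idx, "SY:0000003") is None
        assert "SY:0000003" not in build_ic_table(idx).index

    @pytest.mark.parametrize("seed", range(10))
    def test_child_ic_never_below_parent_ic(self, seed):
        rng = np.random.default_rng(seed)
        v = random_dag_ontology(rng, int(rng.integers(6, 25)))
        idx = propagate(random_annotations(rng, v, 30, 80), v)
        table = build_ic_table(idx)
        for c, p, r in v.relations:
            if r in ("is_a", "part_of") and c in table.index and p in table.index:
                assert table.at[c, "ic"] >= table.at[p, "ic"] - 1e-12

    def test_gene_mean_ic_is_arithmetic_mean_of_direct_terms(self):
        ann = aset([("G", "SY:0000003"), ("G", "SY:0000002"),
                    ("H1", "SY:0000002"), ("H2", "SY:0000002"), ("H3", "SY:0000003")])
        idx = propagate(ann, chain())
        table = build_ic_table(idx)
        expected = (table.at["SY:0000003", "ic"] + table.at["SY:0000002", "ic"]) / 2
        assert gene_mean_ic("G", ann, table) == pytest.approx(expected)
        assert gene_mean_ic("ABSENT", ann, table) is None


class TestClassICComparison:
    def _table(self, ics_poor, ics_well, threshold=10):
        genes, counts = {}, []
        records = []
        for i, _ in enumerate(ics_poor):
            g = f"poor{i}"
            records.extend(
                AnnotationRecord(g, g, f"SY:{j + 1:07d}", "IDA", "P") for j in range(2)
            )
        for i, _ in enumerate(ics_well):
            g = f"well{i}"
            records.extend(
                AnnotationRecord(g, g, f"SY:{j + 1:07d}", "IDA", "P") for j in range(threshold + 1)
            )
        aset_ = AnnotationSet("v", tuple(records), filtered=True)
        universe = [f"poor{i}" for i in range(len(ics_poor))] + [
            f"well{i}" for i in range(len(ics_well))
        ]
        table = classify_genes(aset_, universe, threshold)
        ics = {f"poor{i}": v for i, v in enumerate(ics_poor)}
        ics.update({f"well{i}": v for i, v in enumerate(ics_well)})
        return table, pd.Series(ics)

    def test_fully_separated_groups_significant_with_well_higher(self):
        rng = np.random.default_rng(3)
        poor = rng.uniform(1, 2, size=20)
        well = rng.uniform(3, 4, size=20)
        table, ics = self._table(poor, well)
        res = compare_class_ic(table, ics)
        assert res.pvalue < 0.01 and res.well_higher

    def test_null_calibration_rejects_at_nominal_rate(self):
        """Under exchangeable groups the test should reject ~5% of the time;
        check the rejection count lies inside a generous binomial band."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            pooled = rng.normal(size=30)
            table, ics = self._table(pooled[:15], pooled[15:])
            if compare_class_ic(table, ics).pvalue <= 0.05:
                rejections += 1
        # 99% binomial interval around 0.05 * 200 = 10
        assert 2 <= rejections <= 19

    def test_identical_constant_values_give_p_one(self):
        table, ics = self._table([1.0] * 5, [1.0] * 5)
        res = compare_class_ic(table, ics)
        assert res.pvalue == 1.0 and np.isfinite(res.statistic)

    def test_empty_class_returns_unavailable(self):
        table, ics = self._table([], [1.0, 2.0])
        assert compare_class_ic(table, ics) is None
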