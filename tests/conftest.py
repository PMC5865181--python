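"""Shared fixtures: tiny hand-written OBO/GAF texts and random-DAG builders."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from ontodrift import AnnotationRecord, AnnotationSet, Term, make_ontology

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


CHAIN_OBO = """\
format-version: 1.2
data-version: 2010/01/01

[Term]
id: SY:0000001
name: biological_process root
namespace: biological_process

[Term]
id: SY:0000002
name: mid
namespace: biological_process
is_a: SY:0000001

[Term]
id: SY:0000003
name: leaf
namespace: biological_process
relationship: part_of SY:0000002

[Term]
id: SY:0000004
name: gone
namespace: biological_process
is_obsolete: true
replaced_by: SY:0000002
"""


@pytest.fixture
def chain_ontology():
    """root <- mid <- leaf chain plus one obsolete term mapped to mid."""
    from ontodrift import parse_obo

    return parse_obo(CHAIN_OBO)


def gaf_line(
    gene_id="DB:000001",
    symbol="GENE0001",
    term="SY:0000003",
    evidence="IDA",
    aspect="P",
    qualifier="",
):
    cols = [
        "SYNDB", gene_id, symbol, qualifier, term, "SYN_REF:0000001",
        evidence, "", aspect, "", "", "protein", "taxon:9606",
        "20100101", "SYN", "", "",
    ]
    return "\t".join(cols)


@pytest.fixture
def known_gaf_text():
    """GAF with exactly known composition for the filter semantics checks.

    10 lines: 4 clean records on distinct (gene, term) pairs, 1 IEA, 1 ND,
    1 aspect-C, 1 NOT, and 2 evidence-only duplicates of the first record.
    After default filtering: 4 records.
    """
    lines = [
        "!gaf-version: 2.1",
        gaf_line("DB:000001", "GENE0001", "SY:0000003", "IDA"),
        gaf_line("DB:000002", "GENE0002", "SY:0000003", "EXP"),
        gaf_line("DB:000003", "GENE0003", "SY:0000002", "TAS"),
        gaf_line("DB:000004", "GENE0004", "SY:0000002", "NAS"),
        gaf_line("DB:000005", "GENE0005", "SY:0000003", "IEA"),
        gaf_line("DB:000006", "GENE0006", "SY:0000002", "ND"),
        gaf_line("DB:000007", "GENE0007", "SY:0000009", "IDA", aspect="C"),
        gaf_line("DB:000008", "GENE0008", "SY:0000003", "IDA", qualifier="NOT"),
        gaf_line("DB:000001", "GENE0001", "SY:0000003", "TAS"),
        gaf_line("DB:000001", "GENE0001", "SY:0000003", "EXP"),
    ]
    return "\n".join(lines) + "\n"


def random_dag_ontology(rng: np.random.Generator, n_terms: int, label="v"):
    """Random single-root BP ontology: term i>0 attaches to a random earlier
    term, with an optional second parent. Always acyclic by construction."""
    terms = [Term(f"SY:{i + 1:07d}", f"t{i}", "biological_process") for i in range(n_terms)]
    relations = set()
    for i in range(1, n_terms):
        parent = int(rng.integers(i))
        relations.add((terms[i].id, terms[parent].id, "is_a"))
        if i > 1 and rng.random() < 0.3:
            extra = int(rng.integers(i))
            if extra != parent:
                relations.add((terms[i].id, terms[extra].id, "is_a"))
    return make_ontology(label, terms, relations).validate()


def random_annotations(
    rng: np.random.Generator, ontology, n_genes: int, n_records: int, label="v"
):
    """Uniform random direct annotations onto non-root terms (filtered set)."""
    term_ids = sorted(t.id for t in ontology.active_terms())
    records = []
    seen = set()
    for _ in range(n_records):
        g = f"GENE{int(rng.integers(n_genes)) + 1:04d}"
        t = term_ids[int(rng.integers(len(term_ids)))]
        if (g, t) in seen:
            continue
        seen.add((g, t))
        records.append(
            AnnotationRecord(
                gene_id=g, gene_symbol=g, term=t, evidence_code="IDA", aspect="P"
            )
        )
    return AnnotationSet(version_label=label, records=tuple(records), filtered=True)


def brute_force_ancestors(ontology, term, relation_types=("is_a", "part_of")):
    """Oracle: reflexive-transitive closure by repeated edge expansion."""
    out = {term}
    changed = True
    while changed:
        changed = False
        for c, p, r in ontology.relations:
            if r in relation_types and c in out and p not in out:
                out.add(p)
                changed = True
    return out


def brute_force_descendants(ontology, term, relation_types=("is_a", "part_of")):
    out = {term}
    changed = True
    while changed:
        changed = False
        for c, p, r in ontology.relations:
            if r in relation_types and p in out and c not in out:
                out.add(c)
                changed = True
    return out


def hypergeom_tail_enumeration(k, n, K, N):
    """Oracle: P(X >= k) by exhaustive enumeration of all n-subsets of N."""
    population = [1] * K + [0] * (N - K)
    total = 0
    hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return hits / total
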