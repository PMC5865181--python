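"""True-path propagation and Resnik information content.

A gene annotated to a term is implicitly annotated to every ancestor of that
term over the propagating relations (is_a, part_of). The propagated per-term
gene sets define a term's probability P(t) = genes(t) / genes(root of t's
namespace) and its information content IC(t) = -log2 P(t) in bits: the root
scores 0 and IC can only grow (weakly) from parent to child.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .annotations import AnnotationSet, GeneClassTable
from .ontology import PROPAGATING_RELATIONS, OntologyVersion

MAX_REPLACED_BY_DEPTH = 5


@dataclass
class PropagatedIndex:
    """Propagated gene sets for one (ontology version, annotation version) pair."""

    ontology_label: str
    annotation_label: str
    term_genes: dict[str, frozenset[str]]
    term_namespace: dict[str, str]
    root_gene_count: dict[str, int]  # namespace -> genes under that root
    n_remapped_obsolete: int  # records whose term was remapped via replaced_by
    n_dropped_records: int  # records whose term could not be placed

    def annotated_genes(self) -> frozenset[str]:
        """All genes with at least one propagated annotation."""
        out: set[str] = set()
        for genes in self.term_genes.values():
            out |= genes
        return frozenset(out)

    def gene_count(self, term: str) -> int:
        return len(self.term_genes.get(term, ()))


def _resolve_term(ontology: OntologyVersion, term: str) -> tuple[str | None, bool]:
    """Map an annotation term into the ontology.

    Follows replaced_by chains of obsolete terms up to MAX_REPLACED_BY_DEPTH.
    Returns (resolved id or None, whether a remap happened).
    """
    current = term
    for depth in range(MAX_REPLACED_BY_DEPTH + 1):
        t = ontology.terms.get(current)
        if t is None:
            return None, depth > 0
        if not t.is_obsolete:
            return current, depth > 0
        if not t.replaced_by:
            return None, depth > 0
        current = t.replaced_by[0]
    return None, True


def propagate(
    annotations: AnnotationSet,
    ontology: OntologyVersion,
    relation_types: frozenset[str] = PROPAGATING_RELATIONS,
) -> PropagatedIndex:
    """Build per-term propagated gene sets under the true-path rule.

    Annotation terms obsolete in the ontology are first remapped through
    their replaced_by chain; terms that cannot be placed drop their records
    (tallied). Genes accumulate bottom-up: genes(t) is every gene directly
    annotated to t or to any descendant of t.
    """
    if not annotations.filtered:
        raise ValueError("propagate expects a filtered AnnotationSet")
    direct: dict[str, set[str]] = {}
    n_remapped = 0
    n_dropped = 0
    for r in annotations.records:
        resolved, remapped = _resolve_term(ontology, r.term)
        if remapped:
            n_remapped += 1
        if resolved is None:
            n_dropped += 1
            continue
        direct.setdefault(resolved, set()).add(r.gene_symbol)

    g = ontology.propagation_graph(frozenset(relation_types))
    genes: dict[str, set[str]] = {t: set(s) for t, s in direct.items()}
    # edges point child -> parent, so topological order yields children first
    for node in nx.topological_sort(g):
        acc = genes.get(node)
        if not acc:
            continue
        for parent in g.successors(node):
            genes.setdefault(parent, set()).update(acc)

    term_genes = {t: frozenset(s) for t, s in genes.items() if s}
    term_namespace = {t: ontology.terms[t].namespace for t in term_genes}
    root_gene_count = {
        ns: len(term_genes.get(root, ()))
        for ns, root in ontology.roots().items()
    }
    return PropagatedIndex(
        ontology_label=ontology.version_label,
        annotation_label=annotations.version_label,
        term_genes=term_genes,
        term_namespace=term_namespace,
        root_gene_count=root_gene_count,
        n_remapped_obsolete=n_remapped,
        n_dropped_records=n_dropped,
    )


# ---------------------------------------------------------------------------
# information content


def _denominator(index: PropagatedIndex, namespace: str, mode: str) -> int:
    if mode == "namespace":
        return index.root_gene_count.get(namespace, 0)
    if mode == "global":
        return len(index.annotated_genes())
    raise ValueError(f"denominator must be 'namespace' or 'global', got {mode!r}")


def term_stats(
    index: PropagatedIndex, term: str, denominator: str = "namespace"
) -> tuple[int, float, float] | None:
    """(gene_count, P(t), IC in bits) for one term, or None if no genes carry it."""
    genes = index.term_genes.get(term)
    if not genes:
        return None
    denom = _denominator(index, index.term_namespace[term], denominator)
    p = len(genes) / denom
    ic = -math.log2(p)
    return len(genes), p, ic + 0.0  # normalise -0.0 at the root


def build_ic_table(
    index: PropagatedIndex, denominator: str = "namespace"
) -> pd.DataFrame:
    """IC table over every term with at least one propagated gene.

    Columns: namespace, gene_count, probability, ic (bits, base 2). The
    logarithm base is fixed at 2 and recorded in ``df.attrs``.
    """
    rows = []
    for term in sorted(index.term_genes):
        count, p, ic = term_stats(index, term, denominator)
        rows.append((term, index.term_namespace[term], count, p, ic))
    df = pd.DataFrame(
        rows, columns=["term", "namespace", "gene_count", "probability", "ic"]
    ).set_index("term")
    df.attrs["log_base"] = 2
    df.attrs["denominator"] = denominator
    return df


def gene_mean_ic(
    gene: str, annotations: AnnotationSet, ic_table: pd.DataFrame
) -> float | None:
    """Mean IC over the terms directly assigned to ``gene``; None if undefined."""
    terms = {r.term for r in annotations.records if r.gene_symbol == gene}
    ics = [float(ic_table.at[t, "ic"]) for t in terms if t in ic_table.index]
    if not ics:
        return None
    return float(np.mean(ics))


def gene_mean_ic_table(
    annotations: AnnotationSet, ic_table: pd.DataFrame
) -> pd.Series:
    """Mean IC per gene over its directly assigned in-table terms."""
    pairs = {(r.gene_symbol, r.term) for r in annotations.records}
    df = pd.DataFrame(pairs, columns=["gene", "term"])
    df = df[df["term"].isin(ic_table.index)]
    df["ic"] = ic_table["ic"].reindex(df["term"]).to_numpy()
    out = df.groupby("gene")["ic"].mean()
    out.name = "mean_ic"
    return out


@dataclass
class ClassICComparison:
    statistic: float
    pvalue: float
    mean_poor: float
    mean_well: float
    n_poor: int
    n_well: int

    @property
    def well_higher(self) -> bool:
        return self.mean_well > self.mean_poor


def compare_class_ic(
    table: GeneClassTable, mean_ics: Mapping[str, float] | pd.Series
) -> ClassICComparison | None:
    """Two-sided Mann-Whitney U: mean IC of well- vs poorly characterized genes.

    Genes without a defined mean IC are excluded. Returns None when either
    class is empty after exclusion. Fully tied samples (zero rank variance)
    report p = 1 by convention.
    """
    ics = pd.Series(dict(mean_ics)) if not isinstance(mean_ics, pd.Series) else mean_ics
    classes = table.table["gene_class"]
    well = ics.reindex(classes.index[classes == "well_characterized"]).dropna()
    poor = ics.reindex(classes.index[classes == "poorly_characterized"]).dropna()
    if len(well) == 0 or len(poor) == 0:
        return None
    if np.ptp(np.concatenate([well.to_numpy(), poor.to_numpy()])) == 0:
        return ClassICComparison(
            statistic=len(well) * len(poor) / 2.0,
            pvalue=1.0,
            mean_poor=float(poor.mean()),
            mean_well=float(well.mean()),
            n_poor=len(poor),
            n_well=len(well),
        )
    res = stats.mannwhitneyu(well, poor, alternative="two-sided")
    return ClassICComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        mean_poor=float(poor.mean()),
        mean_well=float(well.mean()),
        n_poor=len(poor),
        n_well=len(well),
    )
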