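"""Hypergeometric over-representation analysis over ontology/annotation grids.

For one gene signature, one ontology version and one annotation version:
with N background genes carrying at least one propagated annotation, K of
them in a term's propagated gene set, and n annotated signature genes of
which k fall in the term's set, the enrichment p-value is the hypergeometric
upper tail P(X >= k). Benjamini-Hochberg adjustment is applied across all
tested terms of one analysis and a term is significant when q <= alpha
(boundary inclusive).

Sweeping the same signature over every (ontology version x annotation
version) pair yields a :class:`PvalueGrid`; its diagonal — same year on both
axes — is the "annual update" series used for trajectory reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import AnnotationSet, GeneIdMap, filter_enrichment_relevant, remap_and_prune
from .ontology import OntologyVersion
from .propagation import PropagatedIndex, propagate


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set to be interpreted by enrichment analysis."""

    name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")


def hypergeometric_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Computed through the survival function, exact to double precision for
    the problem sizes used here.
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if n > N or K > N:
        raise ValueError(f"n={n} and K={K} must not exceed N={N}")
    if k > min(n, K):
        raise ValueError(f"k={k} exceeds min(n={n}, K={K})")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class EnrichmentResult:
    """Per-term counts and p/q values for one (signature, version pair) run."""

    signature: str
    ontology_label: str
    annotation_label: str
    alpha: float
    table: pd.DataFrame  # index term: k, n, K, N, p, q, significant
    n_signature: int
    n_dropped_not_in_background: int
    n_dropped_unannotated: int
    n_effective: int
    status: str = "ok"  # or "no_annotated_signature_genes"

    def significant_terms(self) -> frozenset[str]:
        if self.table.empty:
            return frozenset()
        return frozenset(self.table.index[self.table["significant"]])


def enrich(
    signature: GeneSignature,
    index: PropagatedIndex,
    background: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Over-representation of ``signature`` against ``background``.

    ``background=None`` uses every gene with at least one propagated
    annotation in the index (the usual over-representation default). With an
    explicit universe, genes of the universe without annotations cannot be
    drawn into any term and are excluded from N. Signature genes outside the
    background, or without any propagated annotation, are dropped and
    tallied. One row per term with k >= 1 and K >= 1; BH-FDR across exactly
    those rows; significant iff q <= alpha.
    """
    annotated = set(index.annotated_genes())
    sig = set(signature.genes)
    if background is None:
        bg = annotated
        sig_in_universe = sig
        dropped_bg = 0
    else:
        universe = set(background)
        bg = universe & annotated
        sig_in_universe = sig & universe
        dropped_bg = len(sig) - len(sig_in_universe)
    sig_annotated = sig_in_universe & annotated
    dropped_unannotated = len(sig_in_universe) - len(sig_annotated)
    n = len(sig_annotated)
    N = len(bg)
    meta = dict(
        signature=signature.name,
        ontology_label=index.ontology_label,
        annotation_label=index.annotation_label,
        alpha=alpha,
        n_signature=len(sig),
        n_dropped_not_in_background=dropped_bg,
        n_dropped_unannotated=dropped_unannotated,
        n_effective=n,
    )
    empty = pd.DataFrame(
        columns=["k", "n", "K", "N", "p", "q", "significant"]
    ).rename_axis("term")
    if n == 0:
        return EnrichmentResult(
            table=empty, status="no_annotated_signature_genes", **meta
        )
    rows = []
    for term in sorted(index.term_genes):
        genes = index.term_genes[term]
        K = len(genes & bg)
        if K == 0:
            continue
        k = len(genes & sig_annotated)
        if k == 0:
            continue
        rows.append((term, k, n, K, N, hypergeometric_upper_tail(k, n, K, N)))
    if not rows:
        return EnrichmentResult(table=empty, status="ok", **meta)
    df = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"]).set_index("term")
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["significant"] = df["q"] <= alpha
    return EnrichmentResult(table=df, status="ok", **meta)


def significant_terms(result: EnrichmentResult) -> frozenset[str]:
    """Terms with FDR-adjusted value <= alpha (boundary inclusive)."""
    return result.significant_terms()


@dataclass
class PvalueGrid:
    """Enrichment runs for one signature over every version pair."""

    signature: str
    ontology_labels: list[str]
    annotation_labels: list[str]
    results: dict[tuple[str, str], EnrichmentResult]

    def result(self, ontology_label: str, annotation_label: str) -> EnrichmentResult:
        return self.results[(ontology_label, annotation_label)]

    def significant_sets(self) -> dict[tuple[str, str], frozenset[str]]:
        return {key: r.significant_terms() for key, r in self.results.items()}

    def diagonal_labels(self) -> list[tuple[str, str]]:
        """Paired (ontology, annotation) labels of the annual-update series."""
        return list(zip(self.ontology_labels, self.annotation_labels))

    def long_table(self) -> pd.DataFrame:
        """Long format: term, obo_version, gaf_version, k, K, p, q, significant.

        A term absent (or zero-count) in a version pair simply has no row —
        the absent-cell marker of the grid.
        """
        frames = []
        for (ol, al), res in self.results.items():
            if res.table.empty:
                continue
            t = res.table.reset_index()
            t.insert(1, "obo_version", ol)
            t.insert(2, "gaf_version", al)
            frames.append(t)
        if not frames:
            return pd.DataFrame(
                columns=["term", "obo_version", "gaf_version", "k", "n", "K", "N", "p", "q", "significant"]
            )
        return pd.concat(frames, ignore_index=True)


def build_indices(
    ontologies: Sequence[tuple[str, OntologyVersion]],
    annotation_sets: Sequence[tuple[str, AnnotationSet]],
    include_iea: bool = False,
    gene_map: GeneIdMap | None = None,
) -> dict[tuple[str, str], PropagatedIndex]:
    """Propagated index for every (ontology version, annotation version) pair.

    Raw annotation sets are filtered (and, when a gene map is given,
    remapped to canonical symbols) once per annotation version, then
    propagated against each ontology version. The indices are shared by all
    signatures swept over the same grid.
    """
    if not ontologies or not annotation_sets:
        raise ValueError("at least one version is required on each axis")
    prepared: list[tuple[str, AnnotationSet]] = []
    for label, aset in annotation_sets:
        filtered = aset if aset.filtered else filter_enrichment_relevant(aset, include_iea)
        if gene_map is not None:
            filtered, _ = remap_and_prune(filtered, gene_map)
        prepared.append((label, filtered))
    indices: dict[tuple[str, str], PropagatedIndex] = {}
    for olabel, ontology in ontologies:
        for alabel, filtered in prepared:
            indices[(olabel, alabel)] = propagate(filtered, ontology)
    return indices


def grid_from_indices(
    signature: GeneSignature,
    indices: Mapping[tuple[str, str], PropagatedIndex],
    ontology_labels: Sequence[str],
    annotation_labels: Sequence[str],
    background: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> PvalueGrid:
    """Enrichment of one signature over pre-built propagated indices."""
    results = {
        (ol, al): enrich(signature, indices[(ol, al)], background=background, alpha=alpha)
        for ol in ontology_labels
        for al in annotation_labels
    }
    return PvalueGrid(
        signature=signature.name,
        ontology_labels=list(ontology_labels),
        annotation_labels=list(annotation_labels),
        results=results,
    )


def pvalue_grid(
    signature: GeneSignature,
    ontologies: Sequence[tuple[str, OntologyVersion]],
    annotation_sets: Sequence[tuple[str, AnnotationSet]],
    include_iea: bool = False,
    gene_map: GeneIdMap | None = None,
    background: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> PvalueGrid:
    """Run one enrichment per (ontology version x annotation version) pair."""
    indices = build_indices(ontologies, annotation_sets, include_iea, gene_map)
    return grid_from_indices(
        signature,
        indices,
        [l for l, _ in ontologies],
        [l for l, _ in annotation_sets],
        background=background,
        alpha=alpha,
    )
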