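"""Versioned Gene Ontology graphs: parsing, validation, traversal, diffing.

An :class:`OntologyVersion` is a dated snapshot of the ontology DAG. Terms
carry a namespace (``biological_process``, ``molecular_function``,
``cellular_component``) and a lifecycle state: an obsolete term participates
in no relations and may name replacement terms via ``replaced_by``.

Relations are typed triples ``(child, parent, relation_type)``. Only ``is_a``
and ``part_of`` propagate annotations up the graph (classical true-path
semantics); every other relationship type (``regulates`` and friends) is
retained as ``other`` and never propagates unless explicitly requested.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

#: Relation types that propagate annotations from child to parent.
PROPAGATING_RELATIONS = frozenset({"is_a", "part_of"})

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


class OntologyError(ValueError):
    """Raised when an ontology fails structural validation."""


class UnknownTermError(KeyError):
    """Raised when an operation references a term absent from the version."""


@dataclass(frozen=True)
class Term:
    id: str
    name: str
    namespace: str
    is_obsolete: bool = False
    replaced_by: tuple[str, ...] = ()
    consider: tuple[str, ...] = ()


@dataclass
class OntologyVersion:
    """One dated ontology snapshot.

    ``relations`` holds ``(child, parent, relation_type)`` triples with
    ``relation_type`` in ``{"is_a", "part_of", "other"}``.
    """

    version_label: str
    terms: dict[str, Term]
    relations: frozenset[tuple[str, str, str]]
    _propagation_graph: nx.DiGraph | None = field(
        default=None, repr=False, compare=False
    )

    # -- structure ---------------------------------------------------------

    def propagation_graph(
        self, relation_types: frozenset[str] = PROPAGATING_RELATIONS
    ) -> nx.DiGraph:
        """Directed graph with one child->parent edge per propagating relation."""
        if relation_types == PROPAGATING_RELATIONS and self._propagation_graph is not None:
            return self._propagation_graph
        g = nx.DiGraph()
        g.add_nodes_from(t for t, term in self.terms.items() if not term.is_obsolete)
        g.add_edges_from(
            (c, p) for c, p, r in self.relations if r in relation_types
        )
        if relation_types == PROPAGATING_RELATIONS:
            self._propagation_graph = g
        return g

    def active_terms(self) -> list[Term]:
        return [t for t in self.terms.values() if not t.is_obsolete]

    def roots(self) -> dict[str, str]:
        """Namespace -> root term id (term with no propagating parent)."""
        g = self.propagation_graph()
        out: dict[str, str] = {}
        for term in self.active_terms():
            if term.id in g and g.out_degree(term.id) == 0:
                if term.namespace in out:
                    raise OntologyError(
                        f"{self.version_label}: multiple roots in namespace "
                        f"{term.namespace}: {out[term.namespace]}, {term.id}"
                    )
                out[term.namespace] = term.id
        return out

    def validate(self) -> "OntologyVersion":
        """Check the version invariants; return self for chaining.

        Raises :class:`OntologyError` on a cycle over propagating relations,
        a relation endpoint that is missing or obsolete, or a namespace with
        more (or fewer) than one root.
        """
        for c, p, r in self.relations:
            for endpoint in (c, p):
                term = self.terms.get(endpoint)
                if term is None:
                    raise OntologyError(
                        f"{self.version_label}: relation {c} -{r}-> {p} "
                        f"references missing term {endpoint}"
                    )
                if term.is_obsolete:
                    raise OntologyError(
                        f"{self.version_label}: obsolete term {endpoint} "
                        f"participates in relation {c} -{r}-> {p}"
                    )
        for term in self.terms.values():
            if term.replaced_by and not term.is_obsolete:
                raise OntologyError(
                    f"{self.version_label}: non-obsolete term {term.id} has replaced_by"
                )
            if term.namespace not in NAMESPACES:
                raise OntologyError(
                    f"{self.version_label}: term {term.id} has unknown namespace "
                    f"{term.namespace!r}"
                )
        g = self.propagation_graph()
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(e[0] for e in cycle) + " -> " + cycle[-1][1]
            raise OntologyError(f"{self.version_label}: cycle over is_a/part_of: {path}")
        self.roots()  # raises on multi-root
        # exactly one root per populated namespace
        namespaces = {t.namespace for t in self.active_terms()}
        missing = namespaces - set(self.roots())
        if missing:
            raise OntologyError(
                f"{self.version_label}: namespaces without a root: {sorted(missing)}"
            )
        return self

    # -- traversal ---------------------------------------------------------

    def closure(
        self,
        term: str,
        direction: str = "ancestors",
        relation_types: frozenset[str] = PROPAGATING_RELATIONS,
    ) -> frozenset[str]:
        """Reflexive-transitive closure of ``term``.

        ``direction="ancestors"`` walks child->parent edges, ``"descendants"``
        the reverse. The result always contains ``term`` itself.
        """
        t = self.terms.get(term)
        if t is None:
            raise UnknownTermError(term)
        g = self.propagation_graph(frozenset(relation_types))
        if term not in g:  # obsolete or isolated
            if t.is_obsolete:
                raise UnknownTermError(f"{term} is obsolete in {self.version_label}")
            return frozenset({term})
        if direction == "ancestors":
            reach = nx.descendants(g, term)  # edges point child -> parent
        elif direction == "descendants":
            reach = nx.ancestors(g, term)
        else:
            raise ValueError(f"direction must be 'ancestors' or 'descendants', got {direction!r}")
        return frozenset(reach) | {term}


@dataclass
class OntologyDiff:
    """Simplified change summary between two ontology versions.

    ``mapped_terms`` pairs an old term made obsolete in the newer version
    with each of its declared replacements. A term absent from the newer
    version, or obsolete there without any replacement, counts as deleted.
    """

    old_label: str
    new_label: str
    added_terms: frozenset[str]
    deleted_terms: frozenset[str]
    mapped_terms: frozenset[tuple[str, str]]
    added_relations: frozenset[tuple[str, str, str]]
    deleted_relations: frozenset[tuple[str, str, str]]

    def is_empty(self) -> bool:
        return not (
            self.added_terms
            or self.deleted_terms
            or self.mapped_terms
            or self.added_relations
            or self.deleted_relations
        )

    def summary(self) -> dict[str, int]:
        return {
            "added_terms": len(self.added_terms),
            "deleted_terms": len(self.deleted_terms),
            "mapped_terms": len(self.mapped_terms),
            "added_relations": len(self.added_relations),
            "deleted_relations": len(self.deleted_relations),
        }


# ---------------------------------------------------------------------------
# parsing


def _coerce_source(source):
    if isinstance(source, str) and "\n" in source:
        return io.StringIO(source)
    return source


def parse_obo(source) -> OntologyVersion:
    """Parse an OBO 1.2-dialect file into a validated :class:`OntologyVersion`.

    ``source`` may be a path, an open text handle, or OBO text itself.
    ``is_a`` and ``relationship: part_of`` become typed relations; any other
    relationship type is kept with type ``other``. Unknown stanza keys are
    ignored (obonet drops them or stores them as inert node attributes).
    """
    handle = _coerce_source(source)
    graph = obonet.read_obo(handle, ignore_obsolete=False)

    default_ns = graph.graph.get("default-namespace", [None])
    default_ns = default_ns[0] if isinstance(default_ns, list) else default_ns
    label = graph.graph.get("data-version") or graph.graph.get("date") or "unknown"

    terms: dict[str, Term] = {}
    for node, data in graph.nodes(data=True):
        if "name" not in data and not data:
            # node materialised only because a relation points at it
            continue
        ns = data.get("namespace", default_ns)
        if ns is None:
            raise OntologyError(f"term {node} has no namespace and no default-namespace")
        terms[node] = Term(
            id=node,
            name=data.get("name", node),
            namespace=ns,
            is_obsolete=str(data.get("is_obsolete", "false")).lower() == "true",
            replaced_by=tuple(data.get("replaced_by", ())),
            consider=tuple(data.get("consider", ())),
        )

    relations = set()
    for child, parent, key in graph.edges(keys=True):
        rtype = key if key in PROPAGATING_RELATIONS else "other"
        relations.add((child, parent, rtype))

    version = OntologyVersion(
        version_label=str(label), terms=terms, relations=frozenset(relations)
    )
    return version.validate()


def write_obo(version: OntologyVersion, handle) -> None:
    """Write the OBO 1.2 subset this package reads. Deterministic order."""
    handle.write("format-version: 1.2\n")
    handle.write(f"data-version: {version.version_label}\n")
    handle.write("ontology: synthetic_go\n")
    by_child: dict[str, list[tuple[str, str, str]]] = {}
    for c, p, r in sorted(version.relations):
        by_child.setdefault(c, []).append((c, p, r))
    for tid in sorted(version.terms):
        term = version.terms[tid]
        handle.write("\n[Term]\n")
        handle.write(f"id: {term.id}\n")
        handle.write(f"name: {term.name}\n")
        handle.write(f"namespace: {term.namespace}\n")
        for c, p, r in by_child.get(tid, ()):  # noqa: B007 - c == tid
            if r == "is_a":
                handle.write(f"is_a: {p}\n")
            elif r == "part_of":
                handle.write(f"relationship: part_of {p}\n")
            else:
                handle.write(f"relationship: regulates {p}\n")
        if term.is_obsolete:
            handle.write("is_obsolete: true\n")
            for rep in term.replaced_by:
                handle.write(f"replaced_by: {rep}\n")
            for con in term.consider:
                handle.write(f"consider: {con}\n")


# ---------------------------------------------------------------------------
# diffing


def diff_ontologies(old: OntologyVersion, new: OntologyVersion) -> OntologyDiff:
    """Added / deleted / mapped terms and relation changes between versions.

    Candidates for deletion or mapping are the terms active (non-obsolete)
    in ``old``. A candidate obsolete in ``new`` with a non-empty
    ``replaced_by`` is *mapped* to each replacement; one absent from ``new``
    or obsolete without replacement is *deleted*.
    """
    old_ids = set(old.terms)
    added = frozenset(
        t for t, term in new.terms.items() if t not in old_ids and not term.is_obsolete
    )
    deleted: set[str] = set()
    mapped: set[tuple[str, str]] = set()
    for tid, term in old.terms.items():
        if term.is_obsolete:
            continue
        new_term = new.terms.get(tid)
        if new_term is None:
            deleted.add(tid)
        elif new_term.is_obsolete:
            if new_term.replaced_by:
                mapped.update((tid, rep) for rep in new_term.replaced_by)
            else:
                deleted.add(tid)
    return OntologyDiff(
        old_label=old.version_label,
        new_label=new.version_label,
        added_terms=added,
        deleted_terms=frozenset(deleted),
        mapped_terms=frozenset(mapped),
        added_relations=frozenset(new.relations - old.relations),
        deleted_relations=frozenset(old.relations - new.relations),
    )


def make_ontology(
    version_label: str,
    terms: Iterable[Term | tuple],
    relations: Iterable[tuple[str, str, str]] = (),
) -> OntologyVersion:
    """Convenience constructor used by the generator and tests.

    ``terms`` items may be :class:`Term` or ``(id, name, namespace)`` tuples.
    Does not validate; call ``.validate()`` when invariants must hold.
    """
    tdict: dict[str, Term] = {}
    for t in terms:
        if not isinstance(t, Term):
            t = Term(*t)
        tdict[t.id] = t
    return OntologyVersion(
        version_label=version_label, terms=tdict, relations=frozenset(relations)
    )
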