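"""GO annotation sets: GAF parsing, relevance filtering, gene-id unification,
and annotation-bias statistics.

The filtering step mirrors what an over-representation analysis should see:
electronically inferred annotations (IEA) are optional, "no biological data"
placeholders (ND), cellular-component annotations, NOT-qualified records and
evidence-only duplicates are always removed.

Gene identifiers drift across annotation versions; :func:`build_gene_map`
pools the (object id -> symbol) mappings of every version, later versions
winning, so that records from any year can be rewritten to one canonical
symbol (or dropped and tallied when no current gene can be recovered).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ASPECTS = ("P", "F", "C")

#: Evidence codes always excluded from enrichment-relevant sets.
ALWAYS_EXCLUDED_EVIDENCE = frozenset({"ND"})


class GafParseError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotationRecord:
    gene_id: str
    gene_symbol: str
    term: str
    evidence_code: str
    aspect: str
    qualifier_not: bool = False


@dataclass
class AnnotationSet:
    version_label: str
    records: tuple[AnnotationRecord, ...]
    filtered: bool = False

    def __len__(self) -> int:
        return len(self.records)

    def genes(self) -> frozenset[str]:
        return frozenset(r.gene_symbol for r in self.records)


# ---------------------------------------------------------------------------
# GAF i/o


def parse_gaf(source, version_label: str = "unknown") -> AnnotationSet:
    """Parse GAF 1.0 (15-column) or GAF 2.x (17-column) text.

    ``source`` may be a path, an open handle, or GAF text. Comment lines
    start with ``!``; a ``!gaf-date:`` header, when present, sets the
    version label. A data line with any other column count raises
    :class:`GafParseError` naming the line number.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        if "\n" in s or "\t" in s:
            text = s
        else:
            with open(s) as fh:
                text = fh.read()
    records: list[AnnotationRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("!"):
            if line.lower().startswith("!gaf-date:"):
                version_label = line.split(":", 1)[1].strip()
            continue
        cols = line.split("\t")
        if len(cols) not in (15, 17):
            raise GafParseError(
                f"line {lineno}: expected 15 or 17 tab-separated columns, got {len(cols)}"
            )
        qualifier = cols[3]
        records.append(
            AnnotationRecord(
                gene_id=cols[1],
                gene_symbol=cols[2],
                term=cols[4],
                evidence_code=cols[6],
                aspect=cols[8],
                qualifier_not="NOT" in qualifier.split("|"),
            )
        )
    return AnnotationSet(version_label=version_label, records=tuple(records))


GAF_COLUMNS = 17


def write_gaf(aset: AnnotationSet, handle) -> None:
    """Write records as GAF 2.1 (17 columns), deterministic order."""
    handle.write("!gaf-version: 2.1\n")
    handle.write(f"!gaf-date: {aset.version_label}\n")
    date = aset.version_label.replace("/", "").replace("-", "")
    for r in aset.records:
        cols = [
            "SYNDB",
            r.gene_id,
            r.gene_symbol,
            "NOT" if r.qualifier_not else "",
            r.term,
            "SYN_REF:0000001",
            r.evidence_code,
            "",
            r.aspect,
            "",
            "",
            "protein",
            "taxon:9606",
            date,
            "SYN",
            "",
            "",
        ]
        handle.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# filtering


def filter_enrichment_relevant(
    raw: AnnotationSet, include_iea: bool = False
) -> AnnotationSet:
    """Keep only annotations that should support an enrichment analysis.

    Removes ND always, IEA unless ``include_iea``, cellular-component
    (aspect ``C``) annotations, NOT-qualified records, and collapses records
    identical in ``(gene_id, term)`` — duplicates differing only in evidence
    code count once. Idempotent.
    """
    excluded = set(ALWAYS_EXCLUDED_EVIDENCE)
    if not include_iea:
        excluded.add("IEA")
    seen: set[tuple[str, str]] = set()
    kept: list[AnnotationRecord] = []
    for r in raw.records:
        if r.evidence_code in excluded or r.aspect == "C" or r.qualifier_not:
            continue
        key = (r.gene_id, r.term)
        if key in seen:
            continue
        seen.add(key)
        kept.append(r)
    return AnnotationSet(
        version_label=raw.version_label, records=tuple(kept), filtered=True
    )


# ---------------------------------------------------------------------------
# gene identity across versions


class GeneIdMap:
    """Mapping from historical gene ids / symbols to canonical symbols.

    Total on its declared domain and idempotent: canonical symbols map to
    themselves.
    """

    def __init__(self, mapping: Mapping[str, str]):
        self._map = dict(mapping)
        # idempotence: every canonical target maps to itself
        for sym in list(self._map.values()):
            self._map.setdefault(sym, sym)

    def __contains__(self, key: str) -> bool:
        return key in self._map

    def __len__(self) -> int:
        return len(self._map)

    def canonical(self, key: str) -> str:
        return self._map[key]

    def get(self, key: str, default: str | None = None) -> str | None:
        return self._map.get(key, default)

    def canonical_symbols(self) -> frozenset[str]:
        return frozenset(self._map.values())


def build_gene_map(sets: Sequence[AnnotationSet]) -> GeneIdMap:
    """Pool (gene_id -> symbol) pairs across versions, later versions winning.

    Historical symbols are mapped forward through their object id: if id
    ``DB:1`` carried symbol ``OLD`` in an early version and ``NEW`` later,
    both ``DB:1`` and ``OLD`` map to ``NEW``. Records with a missing symbol
    (``-`` or empty) contribute no mapping.
    """
    if not sets:
        raise ValueError("build_gene_map requires at least one annotation set")
    # last-seen symbol per object id, in version order
    final_symbol: dict[str, str] = {}
    observed_pairs: list[tuple[str, str]] = []
    for aset in sets:
        for r in aset.records:
            if not r.gene_symbol or r.gene_symbol == "-":
                continue
            final_symbol[r.gene_id] = r.gene_symbol
            observed_pairs.append((r.gene_id, r.gene_symbol))
    # walk in version order so the last observation of an id or symbol wins
    mapping: dict[str, str] = {}
    for gene_id, symbol in observed_pairs:
        canonical = final_symbol[gene_id]
        mapping[gene_id] = canonical
        mapping[symbol] = canonical
    return GeneIdMap(mapping)


def remap_and_prune(
    aset: AnnotationSet, gene_map: GeneIdMap
) -> tuple[AnnotationSet, int]:
    """Rewrite records to canonical symbols; drop and tally unmappable ones.

    A record maps through its symbol first, then its object id. After
    remapping, a filtered set is re-deduplicated on (symbol, term) since two
    historical identities can collapse onto one gene.
    """
    kept: list[AnnotationRecord] = []
    dropped = 0
    for r in aset.records:
        canonical = gene_map.get(r.gene_symbol)
        if canonical is None:
            canonical = gene_map.get(r.gene_id)
        if canonical is None:
            dropped += 1
            continue
        kept.append(replace(r, gene_symbol=canonical))
    if aset.filtered:
        seen: set[tuple[str, str]] = set()
        deduped = []
        for r in kept:
            key = (r.gene_symbol, r.term)
            if key not in seen:
                seen.add(key)
                deduped.append(r)
        kept = deduped
    return (
        AnnotationSet(
            version_label=aset.version_label, records=tuple(kept), filtered=aset.filtered
        ),
        dropped,
    )


# ---------------------------------------------------------------------------
# annotation-bias statistics


@dataclass
class GeneClassTable:
    """Per-gene direct annotation counts and characterization class.

    ``uncharacterized``: 0 annotations; ``poorly_characterized``: 1..threshold;
    ``well_characterized``: > threshold.
    """

    table: pd.DataFrame  # index gene, columns n_annotations, gene_class
    threshold: int

    def class_counts(self) -> dict[str, int]:
        counts = self.table["gene_class"].value_counts().to_dict()
        return {
            c: int(counts.get(c, 0))
            for c in ("uncharacterized", "poorly_characterized", "well_characterized")
        }

    def well_characterized_fraction(self) -> float:
        return float((self.table["gene_class"] == "well_characterized").mean())

    def counts(self) -> pd.Series:
        return self.table["n_annotations"]


def classify_genes(
    aset: AnnotationSet, universe: Iterable[str], threshold: int = 10
) -> GeneClassTable:
    """Classify universe genes by their number of direct annotations.

    Counts distinct (gene, term) pairs per gene from the filtered set —
    direct annotations, not propagated. Genes of the universe absent from
    the set count zero. Records for genes outside the universe are ignored.
    """
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    if not aset.filtered:
        raise ValueError("classify_genes requires a filtered AnnotationSet")
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("universe must be non-empty")
    uset = set(universe)
    pairs = {(r.gene_symbol, r.term) for r in aset.records if r.gene_symbol in uset}
    counts: dict[str, int] = {g: 0 for g in universe}
    for gene, _term in pairs:
        counts[gene] += 1
    n = pd.Series(counts, name="n_annotations").loc[universe]
    gene_class = pd.cut(
        n,
        bins=[-1, 0, threshold, np.inf],
        labels=["uncharacterized", "poorly_characterized", "well_characterized"],
    ).astype(str)
    df = pd.DataFrame({"n_annotations": n, "gene_class": gene_class})
    df.index.name = "gene"
    return GeneClassTable(table=df, threshold=threshold)


def bias_summary(
    table: GeneClassTable, thresholds: Iterable[int] = range(5, 16)
) -> pd.DataFrame:
    """Fraction of genes above each threshold and the annotation share they hold.

    One row per threshold ``t``: ``gene_fraction`` = |{g : count(g) > t}| /
    |universe|; ``annotation_fraction`` = their summed counts over all
    counts. With zero total annotations both fractions are 0 and the
    ``warning`` flag is set.
    """
    counts = table.counts().to_numpy()
    n_genes = len(counts)
    total = counts.sum()
    rows = []
    for t in thresholds:
        above = counts > t
        if total == 0:
            rows.append((t, 0.0, 0.0, True))
        else:
            rows.append(
                (t, above.sum() / n_genes, counts[above].sum() / total, False)
            )
    return pd.DataFrame(
        rows, columns=["threshold", "gene_fraction", "annotation_fraction", "warning"]
    )
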