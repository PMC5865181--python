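"""Synthetic ontology/annotation evolution generator.

Emulates, at desk scale, the statistical structure of a decade of Gene
Ontology archives: a DAG ontology that grows by term births (with occasional
leaf obsoletions carrying ``replaced_by`` pointers), annotation sets that
only ever grow, a preferential-attachment bias that concentrates new
annotations on already-annotated genes (a gene's chance of receiving the
next annotation is proportional to ``(1 + current count) ** gamma``),
planted enriched branches whose terms do not exist before their introduction
version, and gene signatures made of planted signal genes plus noise.

Gene-identifier churn is simulated too: a fraction of genes appear under
historical alias symbols in early versions, and a few records carry orphan
identifiers that map to no current gene, so identifier unification and
pruning have real work to do.

Everything is reproducible from ``rng_seed``: per-version random substreams
are spawned from one seed sequence, so extending the series never perturbs
earlier versions, and writing fixtures twice yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotations import AnnotationRecord, AnnotationSet, write_gaf
from .enrichment import GeneSignature
from .ontology import OntologyVersion, Term, write_obo

_NS_BP = "biological_process"
_NS_MF = "molecular_function"
_NS_CC = "cellular_component"
_ASPECT = {_NS_BP: "P", _NS_MF: "F", _NS_CC: "C"}

#: Evidence codes the generator treats as curated (usable for duplicates
#: and planted-branch annotations).
_CURATED = ("EXP", "IDA", "TAS", "NAS")


@dataclass(frozen=True)
class PlantedBranch:
    """An enriched ontology branch that appears mid-series.

    ``branch_genes`` genes end up annotated somewhere in the branch by the
    final version, of which ``signal_genes`` belong to the signature built
    on this branch. The branch root and its ``branch_terms - 1`` child terms
    are absent from every ontology version before ``introduction_version``.
    """

    introduction_version: int
    branch_genes: int = 30
    signal_genes: int = 10
    branch_terms: int = 4


@dataclass
class EvolutionConfig:
    n_genes: int = 1000
    n_versions: int = 8
    initial_terms: int = 30  # per propagating namespace (BP and MF)
    cc_terms: int = 8
    term_birth_rate: float = 10.0  # expected new terms/version/namespace
    relation_extra_parent_prob: float = 0.2
    part_of_prob: float = 0.2
    regulates_prob: float = 0.05  # chance a new term also gets an "other" relation
    obsoletion_rate: float = 1.0  # expected leaf obsoletions/version
    annotations_initial: int = 2000
    annotation_growth_rate: int = 1000  # new annotations per later version
    bias_exponent: float = 1.5  # gamma of the preferential attachment
    planted_branches: tuple[PlantedBranch, ...] = (
        PlantedBranch(1),
        PlantedBranch(2),
        PlantedBranch(3),
        PlantedBranch(5),
        PlantedBranch(6),
        PlantedBranch(7),
    )
    signature_size: int = 50
    noise_genes: int = 40
    alias_fraction: float = 0.1  # genes shown under historical symbols early on
    alias_versions: int = 2  # versions that still use alias symbols
    orphan_annotations: int = 20  # first-version records with unmappable ids
    evidence_mix: tuple[tuple[str, float], ...] = (
        ("EXP", 0.20),
        ("IDA", 0.20),
        ("TAS", 0.15),
        ("NAS", 0.05),
        ("IEA", 0.30),
        ("ND", 0.10),
    )
    duplicate_rate: float = 0.05  # evidence-only duplicate records
    not_rate: float = 0.02  # NOT-qualified records
    rng_seed: int = 0

    def validate(self) -> "EvolutionConfig":
        positive = {
            "n_genes": self.n_genes,
            "n_versions": self.n_versions,
            "initial_terms": self.initial_terms,
            "annotations_initial": self.annotations_initial,
            "annotation_growth_rate": self.annotation_growth_rate,
            "signature_size": self.signature_size,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.bias_exponent < 0:
            raise ValueError(f"bias_exponent must be >= 0, got {self.bias_exponent}")
        reserved = 0
        for b in self.planted_branches:
            if not (0 <= b.introduction_version < self.n_versions):
                raise ValueError(
                    f"introduction_version {b.introduction_version} outside "
                    f"[0, {self.n_versions})"
                )
            if b.signal_genes > b.branch_genes:
                raise ValueError("signal_genes cannot exceed branch_genes")
            if self.signature_size < b.signal_genes:
                raise ValueError(
                    f"signature_size {self.signature_size} < signal genes "
                    f"{b.signal_genes}"
                )
            reserved += b.branch_genes
        if reserved > self.n_genes // 2:
            raise ValueError("planted branches reserve more than half the universe")
        return self

    def version_label(self, v: int) -> str:
        return f"{2004 + v}/01/01"


def gene_symbol(i: int) -> str:
    return f"GENE{i + 1:04d}"


def _gene_id(i: int) -> str:
    return f"DB:{i + 1:06d}"


def _alias_symbol(i: int) -> str:
    return f"OLD{i + 1:04d}"


@dataclass
class _Raw:
    """One annotation event, independent of how the gene is spelled per version."""

    gene: int | None  # index into the universe; None for orphan records
    orphan: str | None
    term: str
    evidence: str
    qualifier_not: bool


class _Generator:
    def __init__(self, config: EvolutionConfig):
        self.cfg = config.validate()
        ss = np.random.SeedSequence(config.rng_seed)
        self._streams = ss.spawn(config.n_versions + 2)
        setup_rng = np.random.default_rng(self._streams[0])

        # reserved planted blocks come first in the universe
        self.branch_blocks: list[list[int]] = []
        cursor = 0
        for b in config.planted_branches:
            self.branch_blocks.append(list(range(cursor, cursor + b.branch_genes)))
            cursor += b.branch_genes
        reserved = set(range(cursor))
        free = np.array(sorted(set(range(config.n_genes)) - reserved))
        n_alias = int(round(config.alias_fraction * config.n_genes))
        n_alias = min(n_alias, free.size)
        self.alias_genes = set(
            setup_rng.choice(free, size=n_alias, replace=False).tolist()
        ) if n_alias else set()

        # ontology state
        self.terms: dict[str, Term] = {}
        self.relations: set[tuple[str, str, str]] = set()
        self.active: dict[str, list[str]] = {_NS_BP: [], _NS_MF: [], _NS_CC: []}
        self.children_count: dict[str, int] = {}
        self.branch_terms: list[list[str]] = [[] for _ in config.planted_branches]
        self.all_branch_term_ids: set[str] = set()
        self._counter = 0
        self.roots: dict[str, str] = {}

        # annotation state
        self.records: list[_Raw] = []
        self.counts = np.zeros(config.n_genes, dtype=np.int64)

    # -- ids ---------------------------------------------------------------

    def _new_term(
        self, namespace: str, name: str | None = None, planted: bool = False
    ) -> str:
        self._counter += 1
        tid = f"SY:{self._counter:07d}"
        self.terms[tid] = Term(
            id=tid,
            name=name or f"synthetic term {self._counter}",
            namespace=namespace,
        )
        self.active[namespace].append(tid)
        self.children_count[tid] = 0
        if planted:
            self.all_branch_term_ids.add(tid)
        return tid

    def _add_relation(self, child: str, parent: str, rtype: str) -> None:
        self.relations.add((child, parent, rtype))
        if rtype in ("is_a", "part_of"):
            self.children_count[parent] += 1

    # -- ontology growth ---------------------------------------------------

    def _grow_namespace(self, rng, namespace: str, n_new: int) -> None:
        for _ in range(n_new):
            # planted branches keep their scripted membership: random growth
            # never attaches below them
            pool = [
                t for t in self.active[namespace] if t not in self.all_branch_term_ids
            ]
            parent = pool[int(rng.integers(len(pool)))]
            tid = self._new_term(namespace)
            rtype = "part_of" if rng.random() < self.cfg.part_of_prob else "is_a"
            self._add_relation(tid, parent, rtype)
            if rng.random() < self.cfg.relation_extra_parent_prob and len(pool) > 2:
                extra = pool[int(rng.integers(len(pool)))]
                if extra != parent:
                    self._add_relation(tid, extra, "is_a")
            if rng.random() < self.cfg.regulates_prob and len(pool) > 2:
                target = pool[int(rng.integers(len(pool)))]
                if target != parent:
                    self._add_relation(tid, target, "other")

    def _init_ontology(self, rng) -> None:
        for ns, n_terms in (
            (_NS_BP, self.cfg.initial_terms),
            (_NS_MF, self.cfg.initial_terms),
            (_NS_CC, self.cfg.cc_terms),
        ):
            root = self._new_term(ns, name=f"{ns} root")
            self.roots[ns] = root
            self._grow_namespace(rng, ns, n_terms)

    def _obsolete_leaves(self, rng, n: int) -> None:
        candidates = [
            t
            for ns in (_NS_BP, _NS_MF)
            for t in self.active[ns]
            if self.children_count.get(t, 0) == 0
            and t not in self.all_branch_term_ids
            and t != self.roots[ns]
        ]
        n = min(n, len(candidates))
        if n == 0:
            return
        chosen = rng.choice(len(candidates), size=n, replace=False)
        for idx in sorted(int(i) for i in chosen):
            tid = candidates[idx]
            parents = [p for c, p, r in self.relations if c == tid and r != "other"]
            dropped = {rel for rel in self.relations if tid in (rel[0], rel[1])}
            for c, p, r in dropped:
                if r in ("is_a", "part_of") and c == tid:
                    self.children_count[p] -= 1
            self.relations -= dropped
            old = self.terms[tid]
            self.terms[tid] = dataclasses.replace(
                old, is_obsolete=True, replaced_by=tuple(parents[:1])
            )
            self.active[old.namespace].remove(tid)

    def _plant_branch(self, b_index: int, branch: PlantedBranch) -> None:
        root = self._new_term(
            _NS_BP, name=f"planted branch {b_index}", planted=True
        )
        self._add_relation(root, self.roots[_NS_BP], "is_a")
        terms = [root]
        for _ in range(branch.branch_terms - 1):
            tid = self._new_term(_NS_BP, planted=True)
            self._add_relation(tid, root, "is_a")
            terms.append(tid)
        self.branch_terms[b_index] = terms

    # -- annotations -------------------------------------------------------

    def _eligible_terms(self) -> list[str]:
        out = []
        for ns in (_NS_BP, _NS_MF, _NS_CC):
            root = self.roots[ns]
            out.extend(
                t
                for t in self.active[ns]
                if t != root and t not in self.all_branch_term_ids
            )
        return out

    def _draw_annotations(self, rng, n_draws: int) -> None:
        cfg = self.cfg
        weights = (1.0 + self.counts.astype(float)) ** cfg.bias_exponent
        weights /= weights.sum()
        genes = rng.choice(cfg.n_genes, size=n_draws, p=weights)
        terms = self._eligible_terms()
        term_idx = rng.integers(len(terms), size=n_draws)
        codes = [c for c, _ in cfg.evidence_mix]
        probs = np.array([w for _, w in cfg.evidence_mix], dtype=float)
        probs /= probs.sum()
        ev_idx = rng.choice(len(codes), size=n_draws, p=probs)
        nots = rng.random(n_draws) < cfg.not_rate
        dups = rng.random(n_draws) < cfg.duplicate_rate
        for i in range(n_draws):
            g = int(genes[i])
            term = terms[int(term_idx[i])]
            ev = codes[int(ev_idx[i])]
            self.records.append(_Raw(g, None, term, ev, bool(nots[i])))
            self.counts[g] += 1
            if dups[i] and not nots[i]:
                # evidence-only duplicate of the same (gene, term) pair
                alt = _CURATED[int(rng.integers(len(_CURATED)))]
                if alt == ev:
                    alt = _CURATED[(int(rng.integers(len(_CURATED))) + 1) % len(_CURATED)]
                self.records.append(_Raw(g, None, term, alt, False))
                self.counts[g] += 1

    def _orphan_annotations(self, rng) -> None:
        terms = self._eligible_terms()
        for k in range(self.cfg.orphan_annotations):
            term = terms[int(rng.integers(len(terms)))]
            self.records.append(_Raw(None, f"LOST:{k + 1:04d}", term, "TAS", False))

    def _planted_progress(self, branch: PlantedBranch, v: int) -> int:
        """Number of branch genes annotated by version v (ramps to all)."""
        span = self.cfg.n_versions - 1 - branch.introduction_version
        if span <= 0:
            return branch.branch_genes
        frac = (v - branch.introduction_version + 1) / (span + 1)
        return min(branch.branch_genes, math.ceil(branch.branch_genes * frac))

    def _branch_gene_order(self, branch: PlantedBranch, block: list[int]) -> list[int]:
        # interleave signal and filler genes so both ramp up together
        signal = block[: branch.signal_genes]
        filler = block[branch.signal_genes :]
        order: list[int] = []
        for i in range(max(len(signal), len(filler))):
            if i < len(signal):
                order.append(signal[i])
            if i < len(filler):
                order.append(filler[i])
        return order

    def _annotate_planted(self, rng, v: int, done: list[int]) -> None:
        for b_index, branch in enumerate(self.cfg.planted_branches):
            if v < branch.introduction_version:
                continue
            target = self._planted_progress(branch, v)
            order = self._branch_gene_order(branch, self.branch_blocks[b_index])
            # every branch gene is annotated to the branch root; signal genes
            # are additionally assigned, in blocks, to one child term each,
            # so the branch converges to a nested staircase of small,
            # decisively enriched child terms under one growing root
            terms = self.branch_terms[b_index]
            root = terms[0]
            children = terms[1:]
            block = self.branch_blocks[b_index]
            signal = block[: branch.signal_genes]
            for pos in range(done[b_index], target):
                g = order[pos]
                self.records.append(_Raw(g, None, root, "IDA", False))
                self.counts[g] += 1
                if children and g in signal:
                    s = signal.index(g)
                    child = children[min(
                        len(children) - 1, s * len(children) // branch.signal_genes
                    )]
                    self.records.append(_Raw(g, None, child, "IDA", False))
                    self.counts[g] += 1
            done[b_index] = max(done[b_index], target)

    # -- materialisation ---------------------------------------------------

    def _snapshot_ontology(self, v: int) -> OntologyVersion:
        version = OntologyVersion(
            version_label=self.cfg.version_label(v),
            terms=dict(self.terms),
            relations=frozenset(self.relations),
        )
        return version.validate()

    def _snapshot_annotations(self, v: int) -> AnnotationSet:
        cfg = self.cfg
        use_alias = v < cfg.alias_versions
        ns_of = {t: term.namespace for t, term in self.terms.items()}
        recs = []
        for raw in self.records:
            if raw.gene is None:
                gid, symbol = raw.orphan, "-"
            else:
                gid = _gene_id(raw.gene)
                if use_alias and raw.gene in self.alias_genes:
                    symbol = _alias_symbol(raw.gene)
                else:
                    symbol = gene_symbol(raw.gene)
            recs.append(
                AnnotationRecord(
                    gene_id=gid,
                    gene_symbol=symbol,
                    term=raw.term,
                    evidence_code=raw.evidence,
                    aspect=_ASPECT[ns_of[raw.term]],
                    qualifier_not=raw.qualifier_not,
                )
            )
        return AnnotationSet(
            version_label=cfg.version_label(v), records=tuple(recs), filtered=False
        )

    # -- driver ------------------------------------------------------------

    def run(self) -> list[tuple[OntologyVersion, AnnotationSet]]:
        cfg = self.cfg
        series = []
        done = [0] * len(cfg.planted_branches)
        for v in range(cfg.n_versions):
            rng = np.random.default_rng(self._streams[2 + v])
            if v == 0:
                self._init_ontology(rng)
            else:
                for ns in (_NS_BP, _NS_MF):
                    self._grow_namespace(rng, ns, int(rng.poisson(cfg.term_birth_rate)))
                self._obsolete_leaves(rng, int(rng.poisson(cfg.obsoletion_rate)))
            for b_index, branch in enumerate(cfg.planted_branches):
                if branch.introduction_version == v:
                    self._plant_branch(b_index, branch)
            n_draws = cfg.annotations_initial if v == 0 else cfg.annotation_growth_rate
            self._draw_annotations(rng, n_draws)
            if v == 0 and cfg.orphan_annotations:
                self._orphan_annotations(rng)
            self._annotate_planted(rng, v, done)
            series.append((self._snapshot_ontology(v), self._snapshot_annotations(v)))
        return series


def simulate_versions(
    config: EvolutionConfig,
) -> list[tuple[OntologyVersion, AnnotationSet]]:
    """Generate the full version series (one ontology + annotation set per
    version). Deterministic in ``config.rng_seed``."""
    return _Generator(config).run()


def planted_branch_roots(
    config: EvolutionConfig, series: Sequence[tuple[OntologyVersion, AnnotationSet]]
) -> list[str]:
    """Branch-root term ids, in branch order, as found in the final version."""
    final = series[-1][0]
    roots = []
    for b_index in range(len(config.planted_branches)):
        name = f"planted branch {b_index}"
        matches = [t.id for t in final.terms.values() if t.name == name]
        if len(matches) != 1:
            raise ValueError(f"branch root {name!r} not uniquely present")
        roots.append(matches[0])
    return roots


def universe(config: EvolutionConfig) -> list[str]:
    """The canonical gene universe of the simulation."""
    return [gene_symbol(i) for i in range(config.n_genes)]


def simulate_signature(
    config: EvolutionConfig, branches: Sequence[int] = (0,)
) -> GeneSignature:
    """Signature = union of signal genes of the designated branches + noise.

    Noise genes are drawn uniformly from the universe outside every planted
    block; the total size must equal ``config.signature_size``.
    """
    config.validate()
    gen_blocks = []
    cursor = 0
    for b in config.planted_branches:
        gen_blocks.append(list(range(cursor, cursor + b.branch_genes)))
        cursor += b.branch_genes
    signal: set[int] = set()
    for b_index in branches:
        branch = config.planted_branches[b_index]
        signal |= set(gen_blocks[b_index][: branch.signal_genes])
    n_noise = config.signature_size - len(signal)
    if n_noise < 0:
        raise ValueError(
            f"signature_size {config.signature_size} < {len(signal)} signal genes"
        )
    if n_noise != config.noise_genes and len(branches) == 1:
        raise ValueError(
            f"signature_size - signal = {n_noise} does not match noise_genes "
            f"{config.noise_genes}"
        )
    ss = np.random.SeedSequence(config.rng_seed)
    sig_stream = ss.spawn(config.n_versions + 2)[1]
    rng = np.random.default_rng(sig_stream.spawn(max(branches) + 1)[min(branches)])
    free = sorted(set(range(config.n_genes)) - set(g for blk in gen_blocks for g in blk))
    noise = rng.choice(len(free), size=n_noise, replace=False)
    genes = {gene_symbol(i) for i in signal}
    genes |= {gene_symbol(free[int(i)]) for i in noise}
    name = "signature_" + "_".join(str(b) for b in sorted(branches))
    return GeneSignature(name=name, genes=frozenset(genes))


def simulate_signatures(config: EvolutionConfig) -> list[GeneSignature]:
    """One signature per planted branch."""
    return [
        simulate_signature(config, branches=(b,))
        for b in range(len(config.planted_branches))
    ]


# ---------------------------------------------------------------------------
# fixture writing


def write_fixtures(
    series: Sequence[tuple[OntologyVersion, AnnotationSet]],
    signatures: Sequence[GeneSignature],
    directory: str | Path,
    config: EvolutionConfig | None = None,
) -> dict[str, list[str]]:
    """Write one OBO + one GAF per version, signature lists, and a manifest."""
    if not series:
        raise ValueError("empty version series")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, list[str]] = {"obo": [], "gaf": [], "signatures": []}
    for ontology, aset in series:
        tag = ontology.version_label.replace("/", "-")
        obo_path = directory / f"ontology_{tag}.obo"
        with open(obo_path, "w") as fh:
            write_obo(ontology, fh)
        gaf_path = directory / f"annotations_{tag}.gaf"
        with open(gaf_path, "w") as fh:
            write_gaf(aset, fh)
        paths["obo"].append(str(obo_path))
        paths["gaf"].append(str(gaf_path))
    for sig in signatures:
        sig_path = directory / f"{sig.name}.txt"
        with open(sig_path, "w") as fh:
            for gene in sorted(sig.genes):
                fh.write(gene + "\n")
        paths["signatures"].append(str(sig_path))
    manifest = {
        "seed": config.rng_seed if config else None,
        "config": dataclasses.asdict(config) if config else None,
        # names only, so two runs into different directories compare equal
        "files": {kind: [Path(p).name for p in ps] for kind, ps in paths.items()},
    }
    manifest_path = directory / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = [str(manifest_path)]
    return paths
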