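"""Full-study orchestration: per-version statistics, bias and IC tables,
enrichment grids, consistency series and trajectory reports, with a run
manifest that documents exactly which versions and settings produced every
number — the provenance any reusable enrichment analysis should record.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .annotations import (
    AnnotationSet,
    GeneIdMap,
    bias_summary,
    build_gene_map,
    classify_genes,
    filter_enrichment_relevant,
    parse_gaf,
    remap_and_prune,
)
from .consistency import consistency_bias_correlation, consistency_series
from .enrichment import (
    GeneSignature,
    PvalueGrid,
    build_indices,
    grid_from_indices,
)
from .ontology import OntologyVersion, parse_obo
from .propagation import (
    build_ic_table,
    compare_class_ic,
    gene_mean_ic_table,
)
from . import simulate as sim

log = logging.getLogger("ontodrift")


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Missing or unreadable input data (CLI exit code 3)."""


# ---------------------------------------------------------------------------
# reports


def version_report(
    series: Sequence[tuple[OntologyVersion, AnnotationSet]],
    universe: Sequence[str],
    threshold: int = 10,
    include_iea: bool = False,
    gene_map: GeneIdMap | None = None,
) -> pd.DataFrame:
    """One row per version: ontology size, filtered annotation counts, and
    gene characterization-class counts at the given threshold."""
    if gene_map is None:
        gene_map = build_gene_map([a for _, a in series])
    rows = []
    for ontology, raw in series:
        filtered = filter_enrichment_relevant(raw, include_iea)
        filtered, n_unmapped = remap_and_prune(filtered, gene_map)
        table = classify_genes(filtered, universe, threshold)
        classes = table.class_counts()
        annotated = filtered.genes() & set(universe)
        rows.append(
            {
                "version": ontology.version_label,
                "n_terms": len(ontology.active_terms()),
                "n_relations": len(ontology.relations),
                "n_annotations_filtered": len(filtered),
                "n_unmapped_dropped": n_unmapped,
                "n_annotated_genes": len(annotated),
                "fraction_annotated": len(annotated) / len(universe),
                "n_uncharacterized": classes["uncharacterized"],
                "n_poorly_characterized": classes["poorly_characterized"],
                "n_well_characterized": classes["well_characterized"],
                "well_characterized_fraction": table.well_characterized_fraction(),
            }
        )
    return pd.DataFrame(rows)


def trajectory_report(
    grid: PvalueGrid,
    ontologies: Mapping[str, OntologyVersion],
    ic_tables: Mapping[tuple[str, str], pd.DataFrame],
    branch_roots: Sequence[str] = (),
    terms: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Annual-update (diagonal) trajectories of q-values, gene counts and IC.

    One row per (term, diagonal version pair). When ``terms`` is given,
    versions where a listed term has no tested row are reported with status
    ``absent``. Each row is labelled with the first listed branch root whose
    descendant closure contains the term in that version, else ``other``.
    """
    known = set()
    for ontology in ontologies.values():
        known |= set(ontology.terms)
    for root in branch_roots:
        if root not in known:
            raise ValueError(f"unknown branch root {root!r}")
    rows = []
    for ol, al in grid.diagonal_labels():
        res = grid.result(ol, al)
        ontology = ontologies[ol]
        ic = ic_tables.get((ol, al))
        closures = {}
        for root in branch_roots:
            if root in ontology.terms and not ontology.terms[root].is_obsolete:
                closures[root] = ontology.closure(root, "descendants")
        tested = res.table.index if terms is None else pd.Index(terms)
        for term in tested:
            present = term in res.table.index
            branch = "other"
            for root in branch_roots:
                if term in closures.get(root, ()):
                    branch = root
                    break
            if present:
                r = res.table.loc[term]
                ic_val = (
                    float(ic.at[term, "ic"]) if ic is not None and term in ic.index else float("nan")
                )
                rows.append(
                    (term, ol, al, "ok", float(r["p"]), float(r["q"]),
                     bool(r["significant"]), int(r["k"]), int(r["K"]), ic_val, branch)
                )
            else:
                rows.append(
                    (term, ol, al, "absent", float("nan"), float("nan"),
                     False, 0, 0, float("nan"), branch)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "term", "obo_version", "gaf_version", "status", "p", "q",
            "significant", "k_signature", "K_background", "ic", "branch",
        ],
    )


# ---------------------------------------------------------------------------
# input loading


def _load_series_from_files(
    obo_paths: Sequence[str], gaf_paths: Sequence[str]
) -> list[tuple[OntologyVersion, AnnotationSet]]:
    if len(obo_paths) != len(gaf_paths):
        raise ConfigError(
            f"{len(obo_paths)} ontology files but {len(gaf_paths)} annotation files"
        )
    series = []
    for obo_path, gaf_path in zip(obo_paths, gaf_paths):
        for p in (obo_path, gaf_path):
            if not Path(p).exists():
                raise DataError(f"missing input file for version pair: {p}")
        ontology = parse_obo(obo_path)
        aset = parse_gaf(gaf_path)
        series.append((ontology, aset))
    return series


def load_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """One gene symbol per line, or two tab-separated columns (name, gene)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"missing signature file {path}")
    genes = []
    sig_name = name or path.stem
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 2:
            sig_name, gene = parts
        else:
            gene = parts[0]
        genes.append(gene)
    if not genes:
        raise DataError(f"signature file {path} contains no genes")
    return GeneSignature(name=sig_name, genes=frozenset(genes))


# ---------------------------------------------------------------------------
# full run


_DEFAULTS = {
    "mode": "synthetic",
    "include_iea": False,
    "alpha": 0.05,
    "threshold": 10,
    "reference": "last",
    "ic_denominator": "namespace",
}


def _resolve_config(config) -> dict:
    if isinstance(config, (str, Path)):
        path = Path(config)
        if not path.exists():
            raise ConfigError(f"config file {path} not found")
        with open(path) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping or a YAML file path")
    cfg = dict(_DEFAULTS)
    cfg.update(config)
    if cfg["mode"] not in ("synthetic", "files"):
        raise ConfigError(f"mode must be 'synthetic' or 'files', got {cfg['mode']!r}")
    return cfg


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_full_analysis(config, out_dir: str | Path) -> Path:
    """Run the whole study and write every table plus a run manifest.

    ``config`` is a mapping (or YAML path) with keys: ``mode``
    ("synthetic" or "files"), ``synthetic`` (EvolutionConfig fields),
    ``obo_files``/``gaf_files``/``signature_files`` for file mode,
    ``include_iea``, ``alpha``, ``threshold``, ``reference`` ("last" or a
    version label). Deterministic for fixed inputs and seed.
    """
    cfg = _resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(cfg, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(cfg: dict, out: Path) -> Path:
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    branch_roots: list[str] = []
    if cfg["mode"] == "synthetic":
        syn = dict(cfg.get("synthetic") or {})
        branches = syn.pop("planted_branches", None)
        if branches is not None:
            syn["planted_branches"] = tuple(
                sim.PlantedBranch(**b) if isinstance(b, dict) else sim.PlantedBranch(*b)
                for b in branches
            )
        try:
            evo = sim.EvolutionConfig(**syn).validate()
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid synthetic config: {exc}") from exc
        log.info("stage=simulate seed=%s versions=%s", evo.rng_seed, evo.n_versions)
        series = sim.simulate_versions(evo)
        signatures = sim.simulate_signatures(evo)
        universe = sim.universe(evo)
        branch_roots = sim.planted_branch_roots(evo, series)
    else:
        series = _load_series_from_files(cfg.get("obo_files", ()), cfg.get("gaf_files", ()))
        signatures = [load_signature(p) for p in cfg.get("signature_files", ())]
        if not signatures:
            raise ConfigError("file mode requires signature_files")
        universe = cfg.get("universe_file") and [
            l.strip() for l in Path(cfg["universe_file"]).read_text().splitlines() if l.strip()
        ]
        if not universe:
            universe = sorted(
                {r.gene_symbol for _, a in series for r in a.records if r.gene_symbol != "-"}
            )
        evo = None

    labels = [o.version_label for o, _ in series]
    reference = labels[-1] if cfg["reference"] == "last" else cfg["reference"]
    if reference not in labels:
        raise ConfigError(f"reference {reference!r} is not a version label")

    gene_map = build_gene_map([a for _, a in series])
    log.info("stage=gene_map entries=%d", len(gene_map))

    report = version_report(
        series, universe, threshold=cfg["threshold"],
        include_iea=cfg["include_iea"], gene_map=gene_map,
    )
    _write_tsv(report, out / "version_report.tsv")
    log.info("stage=version_report rows=%d", len(report))

    # bias tables and the class-IC comparison at the final version
    final_ontology, final_raw = series[-1]
    final_filtered = filter_enrichment_relevant(final_raw, cfg["include_iea"])
    final_filtered, n_unmapped = remap_and_prune(final_filtered, gene_map)
    log.info("stage=filter version=%s unmapped_dropped=%d", labels[-1], n_unmapped)
    table = classify_genes(final_filtered, universe, cfg["threshold"])
    _write_tsv(
        bias_summary(table, range(5, 16)).assign(version=labels[-1]),
        out / "bias_summary.tsv",
    )

    indices = build_indices(
        [(l, o) for l, (o, _) in zip(labels, series)],
        [(l, a) for l, (_, a) in zip(labels, series)],
        include_iea=cfg["include_iea"],
        gene_map=gene_map,
    )
    ic_tables = {
        (l, l): build_ic_table(indices[(l, l)], denominator=cfg["ic_denominator"])
        for l in labels
    }
    for l in labels:
        df = ic_tables[(l, l)].reset_index()
        _write_tsv(df, out / f"ic_{l.replace('/', '-')}.tsv")

    mean_ics = gene_mean_ic_table(final_filtered, ic_tables[(labels[-1], labels[-1])])
    comparison = compare_class_ic(table, mean_ics)

    grids: dict[str, PvalueGrid] = {}
    for sig in signatures:
        grid = grid_from_indices(sig, indices, labels, labels, alpha=cfg["alpha"])
        grids[sig.name] = grid
        _write_tsv(grid.long_table(), out / f"grid_{sig.name}.tsv")
    log.info("stage=grid signatures=%d cells=%d", len(signatures), len(labels) ** 2)

    # consistency along the three axes
    axis_cells = {
        "ontology": [(ol, reference) for ol in labels],
        "annotation": [(reference, al) for al in labels],
        "both": [(l, l) for l in labels],
    }
    score_frames, median_frames = [], []
    correlation = None
    for axis, cells in axis_cells.items():
        sets = {
            name: {ol if axis == "ontology" else al if axis == "annotation" else ol:
                   g.result(ol, al).significant_terms() for ol, al in cells}
            for name, g in grids.items()
        }
        grid_c = consistency_series(sets, reference=reference, axis=axis, versions=labels)
        score_frames.append(grid_c.scores.assign(axis=axis))
        median_frames.append(grid_c.medians.assign(axis=axis))
        log.info(
            "stage=consistency axis=%s included=%d excluded=%d",
            axis, grid_c.n_included, len(grid_c.excluded),
        )
        if axis == "both":
            try:
                correlation = consistency_bias_correlation(
                    grid_c.median_series().to_numpy(),
                    report["well_characterized_fraction"].to_numpy(),
                )
            except ValueError:
                # all signatures excluded, or a degenerate series
                correlation = None
            excluded_both = grid_c.excluded
    _write_tsv(pd.concat(score_frames, ignore_index=True), out / "consistency_scores.tsv")
    _write_tsv(pd.concat(median_frames, ignore_index=True), out / "consistency_summary.tsv")

    if branch_roots:
        ontologies = {l: o for l, (o, _) in zip(labels, series)}
        for sig in signatures:
            traj = trajectory_report(
                grids[sig.name], ontologies, ic_tables, branch_roots=branch_roots,
                terms=branch_roots,
            )
            _write_tsv(traj, out / f"trajectory_{sig.name}.tsv")

    summary = {
        "versions": labels,
        "reference": reference,
        "consistency_bias_pearson_r": correlation,
        "excluded_signatures": excluded_both,
        "class_ic_comparison": None
        if comparison is None
        else {
            "statistic": comparison.statistic,
            "pvalue": comparison.pvalue,
            "mean_ic_poorly_characterized": comparison.mean_poor,
            "mean_ic_well_characterized": comparison.mean_well,
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")

    manifest = {
        "tool": "ontodrift",
        "tool_version": __version__,
        "started": started,
        "config": {
            k: (dataclasses.asdict(evo) if k == "synthetic" and evo is not None else v)
            for k, v in cfg.items()
        },
        "version_labels": labels,
        "reference": reference,
        "include_iea": cfg["include_iea"],
        "alpha": cfg["alpha"],
        "seed": evo.rng_seed if evo is not None else None,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    log.info("stage=done out=%s", out)
    return out
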