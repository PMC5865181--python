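#!/usr/bin/env python
"""Quantify how the ontology and its annotations changed across versions.

Reads the archive written by 01_simulate_archive.py, reports per-version
term/relation/annotation counts and gene characterization classes, and
diffs the first against the last ontology version (added / deleted /
mapped terms and relations). Writes version_report.tsv and
ontology_diff.tsv under results/.
"""

from pathlib import Path

import pandas as pd

from ontodrift import build_gene_map, diff_ontologies, parse_gaf, parse_obo, version_report

ROOT = Path(__file__).resolve().parent.parent / "results"
ARCHIVE = ROOT / "synthetic"


def load_series():
    obos = sorted(ARCHIVE.glob("ontology_*.obo"))
    gafs = sorted(ARCHIVE.glob("annotations_*.gaf"))
    return [(parse_obo(str(o)), parse_gaf(str(g))) for o, g in zip(obos, gafs)]


def main() -> None:
    series = load_series()
    gene_map = build_gene_map([a for _, a in series])
    universe = sorted(gene_map.canonical_symbols())
    report = version_report(series, universe, gene_map=gene_map)
    report.to_csv(ROOT / "version_report.tsv", sep="\t", index=False)

    diff = diff_ontologies(series[0][0], series[-1][0])
    pd.DataFrame([diff.summary()]).to_csv(ROOT / "ontology_diff.tsv", sep="\t", index=False)

    first, last = report.iloc[0], report.iloc[-1]
    print(f"versions: {first['version']} .. {last['version']}")
    print(
        f"terms grew {first['n_terms']} -> {last['n_terms']} "
        f"({last['n_terms'] / first['n_terms']:.1f}-fold), relations "
        f"{first['n_relations']} -> {last['n_relations']}"
    )
    print(
        f"filtered annotations {first['n_annotations_filtered']} -> "
        f"{last['n_annotations_filtered']} "
        f"({last['n_annotations_filtered'] / first['n_annotations_filtered']:.1f}-fold)"
    )
    print(
        f"fraction of universe annotated {first['fraction_annotated']:.2f} -> "
        f"{last['fraction_annotated']:.2f}"
    )
    print(
        "first->last diff:",
        ", ".join(f"{k}={v}" for k, v in diff.summary().items()),
    )


if __name__ == "__main__":
    main()
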