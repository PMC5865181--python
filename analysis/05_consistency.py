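#!/usr/bin/env python
"""Jaccard consistency of enrichment results over time, and its link to bias.

Reads the per-signature grids written by 04_enrichment_grid.py and scores
each signature's significant-term set against the final (reference) version
along three axes: ontology varied (annotation fixed), annotation varied
(ontology fixed), and both varied (annual updates). Writes
consistency_scores.tsv / consistency_summary.tsv and reports the Pearson
correlation between the per-version median consistency (annual updates) and
the fraction of well-characterized genes from version_report.tsv.
"""

from pathlib import Path

import pandas as pd

from ontodrift import consistency_bias_correlation, consistency_series

ROOT = Path(__file__).resolve().parent.parent / "results"
ALPHA = 0.05


def significant_sets(long: pd.DataFrame, cells: list[tuple[str, str]], keys: list[str]):
    out = {}
    for (ol, al), key in zip(cells, keys):
        at = long[(long["obo_version"] == ol) & (long["gaf_version"] == al)]
        out[key] = frozenset(at.loc[at["q"] <= ALPHA, "term"])
    return out


def main() -> None:
    grids = {
        p.stem.replace("grid_", ""): pd.read_csv(p, sep="\t")
        for p in sorted(ROOT.glob("grid_signature_*.tsv"))
    }
    labels = sorted(next(iter(grids.values()))["obo_version"].unique())
    reference = labels[-1]

    axis_cells = {
        "ontology": [(ol, reference) for ol in labels],
        "annotation": [(reference, al) for al in labels],
        "both": [(l, l) for l in labels],
    }
    scores, medians = [], []
    for axis, cells in axis_cells.items():
        sets = {name: significant_sets(long, cells, labels) for name, long in grids.items()}
        grid = consistency_series(sets, reference=reference, axis=axis, versions=labels)
        scores.append(grid.scores.assign(axis=axis))
        medians.append(grid.medians.assign(axis=axis))
        med = grid.median_series()
        print(
            f"axis={axis}: median consistency {med.iloc[0]:.2f} ({labels[0]}) -> "
            f"{med.iloc[-1]:.2f} ({reference}); "
            f"{grid.n_included} signatures included, {len(grid.excluded)} excluded"
        )
    pd.concat(scores, ignore_index=True).to_csv(
        ROOT / "consistency_scores.tsv", sep="\t", index=False
    )
    summary = pd.concat(medians, ignore_index=True)
    summary.to_csv(ROOT / "consistency_summary.tsv", sep="\t", index=False)

    report = pd.read_csv(ROOT / "version_report.tsv", sep="\t")
    diag = summary[summary["axis"] == "both"].set_index("version")["median_score"]
    r = consistency_bias_correlation(
        diag.loc[sorted(diag.index)].to_numpy(),
        report.sort_values("version")["well_characterized_fraction"].to_numpy(),
    )
    print(
        "Pearson R between annual-update median consistency and "
        f"well-characterized-gene fraction: {r:.3f}"
    )


if __name__ == "__main__":
    main()
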