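"""Jaccard consistency of significant-term sets across ontology/annotation
versions.

Enrichment results from two versions are compared by the Jaccard index of
their significant-term sets: 1 means identical result sets, 0 means no
overlap. A fixed recent version serves as the reference; signatures whose
reference analysis returns no significant terms are excluded from the
medians (and tallied), while a signature that finds nothing where the
reference finds something scores 0 — maximal inconsistency, not missing
data. Per-version consistency is summarised by the median over included
signatures, and its correlation with the well-characterized-gene fraction
links result stability to annotation bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

AXES = ("ontology", "annotation", "both")


def jaccard(a: frozenset | set, b: frozenset | set) -> float | None:
    """|A ∩ B| / |A ∪ B|; None (undefined) when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return None
    return len(a & b) / len(union)


@dataclass
class ConsistencyGrid:
    """Per-signature Jaccard scores against a reference version.

    ``scores`` has one row per (signature, version) with the score and an
    inclusion flag; ``medians`` one row per version with the median over
    included signatures and their count. Excluded signatures (empty
    significant set at the reference) are listed with a reason.
    """

    axis: str
    reference: str
    versions: list[str]
    scores: pd.DataFrame  # signature, version, score, included
    medians: pd.DataFrame  # version, median_score, n_included
    excluded: dict[str, str]

    @property
    def n_signatures(self) -> int:
        return self.scores["signature"].nunique() + len(self.excluded)

    @property
    def n_included(self) -> int:
        return self.scores["signature"].nunique()

    def median_series(self) -> pd.Series:
        return self.medians.set_index("version")["median_score"]


def consistency_series(
    significant_sets: Mapping[str, Mapping[str, frozenset[str]]],
    reference: str,
    axis: str = "both",
    versions: Sequence[str] | None = None,
) -> ConsistencyGrid:
    """Jaccard of each signature's per-version significant sets vs the reference.

    ``significant_sets`` maps signature name -> version label -> significant
    term set; every signature must have an entry for ``reference``.
    Signatures with an empty reference set are excluded (reason recorded); a
    non-empty reference against an empty compared set scores 0.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    if not significant_sets:
        raise ValueError("no signatures given")
    sig_names = list(significant_sets)
    if versions is None:
        versions = list(significant_sets[sig_names[0]])
    for name in sig_names:
        if reference not in significant_sets[name]:
            raise ValueError(f"signature {name!r} has no result at reference {reference!r}")

    excluded: dict[str, str] = {}
    rows = []
    for name in sig_names:
        ref_set = significant_sets[name][reference]
        if not ref_set:
            excluded[name] = "no significant terms at reference"
            continue
        for v in versions:
            score = jaccard(significant_sets[name][v], ref_set)
            # ref_set non-empty, so the union is never empty
            rows.append((name, v, float(score), True))
    scores = pd.DataFrame(rows, columns=["signature", "version", "score", "included"])
    med_rows = []
    for v in versions:
        at_v = scores.loc[scores["version"] == v, "score"]
        med_rows.append((v, float(at_v.median()) if len(at_v) else float("nan"), int(len(at_v))))
    medians = pd.DataFrame(med_rows, columns=["version", "median_score", "n_included"])
    return ConsistencyGrid(
        axis=axis,
        reference=reference,
        versions=list(versions),
        scores=scores,
        medians=medians,
        excluded=excluded,
    )


def consistency_bias_correlation(
    medians: Sequence[float], well_fraction: Sequence[float]
) -> float | None:
    """Pearson correlation of per-version median consistency with the
    well-characterized-gene fraction; None when either series is constant."""
    x = np.asarray(medians, dtype=float)
    y = np.asarray(well_fraction, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length series over at least 3 versions")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("series must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)
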