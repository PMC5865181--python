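# ontodrift

Gene Ontology (GO) enrichment analysis is the default way to interpret a
list of differentially expressed genes — and both of its inputs, the
ontology and the gene annotations, change continuously. A term that explains
your experiment may simply not exist in the GO version you used, or may
carry too few annotations to reach significance; re-running the same
analysis a few years later can tell a different biological story.

`ontodrift` is a pipeline for quantifying exactly that. For a set of gene
signatures and a series of ontology (OBO) and annotation (GAF) versions it
computes:

- **per-version statistics** — term/relation counts, version diffs
  (added / deleted / obsoleted-and-mapped terms), filtered annotation counts;
- **annotation bias** — per-gene annotation counts and the
  uncharacterized / poorly characterized (≤ *t* annotations) /
  well-characterized (> *t*, default *t* = 10) classes, swept over
  thresholds 5–15;
- **information content** — true-path propagated per-term gene counts and
  Resnik IC, `IC(t) = −log₂ P(t)` with `P(t) = genes(t) / genes(root)`, and a
  Mann–Whitney comparison of mean gene IC between well- and poorly
  characterized genes;
- **enrichment grids** — hypergeometric over-representation
  (`p = P(X ≥ k)` for `X ~ Hypergeom(N, K, n)`) with Benjamini–Hochberg FDR,
  run for every (ontology version × annotation version) pair; significance
  means `q ≤ 0.05`;
- **consistency over time** — the Jaccard index `|A∩B| / |A∪B|` between each
  version's significant-term set and a fixed reference version, its median
  across signatures, and the Pearson correlation of that median with the
  well-characterized-gene fraction.

Because archived GO/GOA snapshots are bulky external downloads, the package
ships a first-class synthetic evolution generator
(`ontodrift.simulate`) that writes real OBO/GAF files: a growing DAG with
term births and obsoletions, annotation sets growing under preferential
attachment (bias exponent γ), planted enriched branches that are absent
before their introduction version, and signatures of signal plus noise
genes. Every analysis step is exercised end to end on these archives.

## Worked example

Run the analysis scripts in order (each reads the previous step's output
from `results/`):

```bash
python analysis/01_simulate_archive.py     # 12-version synthetic archive
python analysis/02_version_statistics.py
python analysis/03_annotation_bias.py
python analysis/04_enrichment_grid.py
python analysis/05_consistency.py
```

The run prints, among other things:

```
terms grew 71 -> 300 (4.2-fold), relations 77 -> 359
filtered annotations 1045 -> 7282 (7.0-fold)
threshold 10: 24% of genes hold 60% of annotations
mean IC well-characterized 3.34 vs poorly 3.08 (Mann-Whitney U=90234, p=7.89e-06, n=225/669)
first version at which each signature's own planted branch is significant:
  signature_0: 2006-01-01   # branch introduced 2005 — a lag, not an error
  ...
axis=both: median consistency 0.00 (2004-01-01) -> 1.00 (2015-01-01)
Pearson R between annual-update median consistency and well-characterized-gene fraction: 0.969
```

Read it as the synthetic decade recapitulating what happens with the real
GO: the ontology and annotations grow several-fold; a quarter of the genes
end up holding more than half of the annotations; heavily annotated genes
also carry the more specific (higher-IC) terms; a planted "disease
mechanism" branch only becomes statistically significant one or more years
after its terms enter the ontology, because too few genes are annotated at
first; and enrichment results agree with the final reference version more
and more as the well-characterized-gene fraction rises — the two series are
correlated at R ≈ 0.97.

The same machinery runs on real archives through the CLI:

```bash
ontodrift simulate --seed 7 --out archive/          # or use real OBO/GAF files
ontodrift ontology-diff old.obo new.obo
ontodrift enrich new.obo new.gaf signature.txt --alpha 0.05
ontodrift grid --obo-dir obos/ --gaf-dir gafs/ --signatures signature.txt
ontodrift run --config config.yaml --out out/
```

All commands emit TSV; `ontodrift run` writes every table plus a JSON run
manifest recording the exact versions, filters, α and seed used.

## Layout

- `src/ontodrift/` — the library: `ontology` (OBO parsing, validation,
  closures, diffs), `annotations` (GAF parsing, filters, gene-id maps, bias),
  `propagation` (true-path index, IC), `enrichment` (hypergeometric test,
  BH-FDR, version grids), `consistency` (Jaccard series, correlations),
  `simulate` (synthetic evolution), `pipeline` + `cli` (orchestration).
- `analysis/` — the numbered study drivers shown above.
- `docs/methods.md` — model assumptions, parameter choices, limitations.
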