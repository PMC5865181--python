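# Methods

## Problem and scope

The pipeline measures how the evolution of an ontology and of its gene
annotations changes the outcome of over-representation analysis. Its unit
of work is the triple (gene signature, ontology version, annotation
version); everything else — bias statistics, information content,
consistency — is computed from sweeps over such triples. Signature
construction itself (differential expression, meta-analysis) is out of
scope: signatures are inputs, either plain gene lists or the synthetic
generator's output.

## Ontology model

An ontology version is a set of terms, each with a namespace
(`biological_process`, `molecular_function`, `cellular_component`) and a
lifecycle state, plus typed relations `(child, parent, type)`. Only `is_a`
and `part_of` propagate annotations (classical true-path semantics, the
behaviour of the over-representation tools of the era this pipeline
models); `regulates`-family relations are parsed and retained as type
`other` and never propagate, though the propagating set is a parameter of
`closure` and `propagate` for users who want otherwise.

Validation is strict at parse time: the propagating graph must be acyclic,
every relation endpoint must exist and be non-obsolete, obsolete terms may
carry `replaced_by`/`consider` pointers but no relations, and each
namespace must have exactly one root. The single-root requirement exists
because information content needs a well-defined `P(t)` denominator per
namespace; multi-root input is rejected rather than silently patched.

Version diffing is deliberately simple. Taking the active terms of the
older version as candidates: a term obsolete in the newer version with a
non-empty `replaced_by` is *mapped* (one pair per replacement); a term
absent from the newer file, or obsolete without replacement, is *deleted*;
terms present only in the newer version are *added*. Relation changes are
set differences on typed triples. Merge/split detection beyond
`replaced_by` is not attempted.

## Annotation model and filters

GAF 1.0 (15 columns) and GAF 2.x (17 columns) are accepted, keyed by column
count. The enrichment-relevance filter removes: `ND` records always, `IEA`
unless electronic annotations are explicitly included, cellular-component
(aspect `C`) records, `NOT`-qualified records (a negative assertion must
not support over-representation), and evidence-only duplicates — records
identical in (gene, term) — which collapse to one. The filter is an
exclusion list, not an evidence whitelist, and is idempotent.

Gene identity across versions is unified by pooling every
(object id → symbol) pair from all annotation versions, later versions
taking precedence; historical symbols map forward through their object id.
Records whose identity maps to no current gene are dropped and tallied —
the tally is a first-class output, because a signature full of unmappable
or unannotated genes silently weakens any enrichment result.

Gene characterization uses *direct* (unpropagated) annotation counts:
0 = uncharacterized, 1..t = poorly characterized, > t = well-characterized,
with t = 10 by default and a 5..15 sweep in `bias_summary`. Direct counts
are used because "annotations per gene" is a property of the annotation
file, whereas term-level gene counts explicitly include descendants.

## Propagation and information content

The propagated index assigns to each term every gene annotated to it or to
any descendant over the propagating relations; annotation terms obsolete in
the paired ontology are first chased through `replaced_by` chains (depth
≤ 5) and dropped (tallied) if still unplaced. Resnik information content is
`IC(t) = −log₂ P(t)` in bits, with `P(t) = gene_count(t) / gene_count(root
of t's namespace)`. The per-namespace denominator is the default because
cellular-component annotations are removed upstream and the remaining
namespaces are disjoint hierarchies; a global-denominator variant is
available (`denominator="global"`). Terms with zero propagated genes are
absent from the IC table rather than carrying an infinite IC. A gene's mean
IC is the arithmetic mean over its directly assigned in-table terms.

The comparison of mean IC between well- and poorly characterized genes is
a two-sided Mann–Whitney U test (normal approximation with tie correction,
as implemented in scipy), chosen for robustness to the skewed IC
distributions; fully tied input reports p = 1 by convention rather than a
0/0 statistic.

## Enrichment

For one triple: N = background genes with ≥ 1 propagated annotation, K of
them in the term's propagated set, n = annotated signature genes, k of them
in the term's set; `p = P(X ≥ k)` for `X ~ Hypergeometric(N, K, n)`,
computed through the survival function. The background defaults to "all
annotated genes of that annotation version" (the convention of classical
over-representation tools); an explicit universe may be supplied, in which
case unannotated universe genes are excluded from N since they can never be
drawn into any K. Signature genes outside the background or without
annotations are dropped from n and tallied. One row is emitted per term
with k ≥ 1 and K ≥ 1; Benjamini–Hochberg adjustment runs across exactly
those rows (biological process and molecular function jointly — one FDR per
analysis); a term is significant when `q ≤ 0.05`, boundary inclusive.
Under-representation is out of scope.

The version grid runs this analysis for every (ontology version ×
annotation version) pair; the diagonal — same year on both axes — is the
"annual update" series used by the trajectory reports.

## Consistency

Two analyses are compared by the Jaccard index of their significant-term
sets. Against a fixed reference version (default: the last), a signature
whose *reference* set is empty is excluded from the medians and listed with
a reason; a signature whose *compared* set is empty while the reference set
is not scores 0 — finding nothing where the reference finds something is
maximal inconsistency, not missing data (this choice is recorded in output
metadata). Per-version consistency is summarized by the median (not mean)
over included signatures, and `included + excluded = total` always holds.
The link to annotation bias is the Pearson correlation between the
per-version median consistency and the well-characterized-gene fraction;
it is undefined (None) for constant series. Semantic-similarity-weighted
overlap is deliberately not implemented.

## Synthetic evolution generator

The generator emulates the statistical structure of a decade of GO/GOA
archives at desk scale. Defaults (the study conditions of the analysis
scripts and the acceptance checks):

- **Universe**: 1,000 genes; 8 versions by default, 12 in the evolution-trend
  study (labelled 2004..2015 analogically).
- **Ontology**: two propagating namespaces seeded with a root + 30 terms
  each and a small cellular-component namespace (8 terms, so the aspect-C
  filter has work); Poisson(10) term births per namespace per version, new
  terms attaching uniformly to existing non-planted terms (`is_a` 80% /
  `part_of` 20%, second parent with probability 0.2, occasional
  non-propagating `regulates` edge); Poisson(1) leaf obsoletions per version
  with `replaced_by` pointing at the former parent.
- **Annotations**: 2,000 records in the first version plus 1,000 per later
  version, never deleted (the real archives grow monotonically). Genes are
  drawn with probability ∝ (1 + current count)^γ, γ = 1.5 — preferential
  attachment reproducing the concentration of annotations on well-studied
  genes. Weights update at version boundaries (draws within one version are
  multinomial at fixed weights), so γ = 0 is exactly a uniform multinomial.
  Terms are uniform over non-root, non-planted active terms. Evidence codes
  are drawn from a mix with 30% IEA and 10% ND; 5% of records spawn an
  evidence-only duplicate and 2% are NOT-qualified, so every filter rule is
  exercised. 10% of genes appear under historical alias symbols in the
  first two versions, and 20 first-version records carry orphan identifiers
  mappable to no current gene.
- **Planted branches**: six branches introduced at versions 1,2,3,5,6,7.
  Each consists of a branch root plus three child terms, absent from all
  earlier ontology versions, and 30 genes (10 of them signature signal
  genes) annotated along an interleaved signal/filler ramp that completes
  at the final version. All 30 genes are annotated to the branch root;
  signal genes are additionally assigned, in blocks of 3–4, to one child
  each, filling sequentially. This makes each branch converge to a nested
  staircase of decisively enriched terms — the signature's significant set
  grows toward the reference set rather than flickering around the
  significance boundary, which is what makes the rising-consistency trend
  detectable at this scale. The delay between a branch's introduction and
  its first significant version reproduces the annotation-lag phenomenon.
- **Signatures**: one per branch — its 10 signal genes plus 40 noise genes
  drawn uniformly from the universe outside all planted blocks. Noise genes
  may be unannotated; they are dropped from n and tallied, as with real
  signatures.
- **Determinism**: one seed sequence per run; per-version substreams are
  spawned by index, so extending a series never changes earlier versions,
  and fixture writing is byte-identical for a fixed seed.

What the generator does *not* emulate: the real GO's magnitudes (tens of
thousands of terms), literature bias, term merges/splits beyond
`replaced_by`, inter-namespace links, and biologically structured
co-annotation (noise genes cluster in terms only through the annotation
process itself). Passing tests therefore demonstrate that the pipeline's
statistics behave correctly under the modelled mechanisms — growth, bias,
late term birth — not that any particular real-data effect size will be
reproduced.

## Numerical and procedural choices

- Hypergeometric tails go through scipy's survival function; the test suite
  checks them against exhaustive subset enumeration for all N ≤ 12 at
  1e-12.
- BH-FDR is a step-up with an enforced monotone envelope, capped at 1;
  verified against statsmodels on random vectors.
- IC uses base-2 logarithms throughout; the base is recorded in the IC
  table metadata.
- Ties and degenerate inputs: empty p-vector → empty adjustment; both sets
  empty → Jaccard undefined (caller decides); constant series → correlation
  undefined; all-tied rank test → p = 1; zero-annotation bias table →
  fractions 0 with a warning flag.
- Problem sizes in the analysis scripts (12 versions, 1,000 genes, six
  branches) are the package's chosen desk-scale study conditions; every
  number printed by the scripts is recomputed from the generated archive on
  each run.

## Known limitations

- The OBO subset covers the tags the analysis needs ([Term], id, name,
  namespace, is_a, relationship, is_obsolete, replaced_by, consider); no
  logical definitions or cross-products.
- Background choice and joint-vs-per-namespace testing follow one defensible
  convention each; both are parameters, and results can shift under other
  conventions.
- Consistency treats term sets as unstructured: two versions naming a
  parent and its child are "inconsistent" even though they are semantically
  close.
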