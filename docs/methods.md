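# Methods

## Module definitions and the grammar

A metabolic module is an ordered conjunction of *blocks*, each block one
enzymatic step. Definitions are parsed under a compact boolean dialect over
KO identifiers (`K` + five digits, case-normalised):

* top-level space-separated terms are consecutive blocks;
* `,` separates alternative ways of completing a block (OR);
* `+` joins subunits of a complex (AND) and binds tighter than `,`;
* a component prefixed with `-` is optional: it never gates satisfaction and
  contributes no KO step;
* a bare `--` term denotes an undefined step and is skipped — it is not
  counted as a block. Whether such steps should instead count as present is
  genuinely open; skipping them is the documented choice here, so
  `blocks_total` counts only defined steps;
* parentheses group recursively; spaces inside parentheses form nested AND
  groups without splitting top-level blocks, which keeps the block count
  equal to the number of enzymatic steps.

Real KEGG flat-file `DEFINITION` lines parse under this dialect, but the
dialect as documented — not any web service's behaviour — is the contract.
Parsing flattens nested same-type nodes, giving every expression a canonical
shape; serialization emits complexes with `+` (parenthesising OR children)
so that parse ∘ serialize is the identity on structure. This is
property-tested with randomly generated expression trees, and satisfaction of
parsed expressions is cross-checked against an independent evaluator that
translates the raw definition string into a Python boolean expression —
fixing the `+` > `,` > space precedence by construction.

## Completeness grading

For one assembly (a KO set) and one module:

1. **Block grading.** A block is satisfied when some alternative of its
   expression is fully present (every required subunit of a complex).
   With `m` of `t` blocks missing: 0 → COMPLETE (grade 1), 1 → MISSING_1 (2),
   2 → MISSING_2 (3), ≥ 3 with at least one block present → INCOMPLETE (4),
   no block present → ABSENT (5).
2. **Step re-grading.** If any block is *partially* satisfied through a
   multi-KO expression — the best fraction of required KOs present lies
   strictly between 0 and 1 — a second category is computed on KO steps:
   each block contributes the step counts of its best alternative, missing
   steps are graded on the same 0/1/2/≥3 scale, and the final category is
   the better (numerically lower) of block and step grades. Because the step
   grade is COMPLETE only when every step is present (which implies every
   block is satisfied), re-grading can never promote a module with a missing
   step to grade 1. ABSENT is only ever final when the assembly carries none
   of the module's required KOs; any present KO yields a partial block and
   hence a step grade of 4 or better.
3. **Step-credit tie-breaks.** The "best alternative" of a block is chosen
   among the minimal satisfying KO sets of its expression by (i) the largest
   fraction present, (ii) the fewest total steps, (iii) the lexicographically
   smallest KO list. The first rule is forced by the semantics; the other
   two are conventions to make grading deterministic. Enumeration refuses
   blocks with more than 64 atoms (no real module approaches this).
4. **Standards.** *Strictly complete* means grade 1; *loosely complete*
   means grade ≤ 2 (at most one block missing).

Grades are computed per assembly independently — there is no cross-assembly
rescue of unannotated orthologues (e.g. by sequence search); the grade matrix
reflects annotation-derived presence only. Grading is validated against a
brute-force truth-table oracle (exhaustive subset enumeration per block) on
1,000 random module/KO-set pairs, and is provably monotone: adding a KO can
only turn atoms present, which can only increase block satisfaction and step
fractions (property-tested over random extensions).

One known divergence from interactive reconstruction tools: some suppress
the "1/2 blocks missing" categories for very short (e.g. two-block) modules.
That suppression is **not** replicated — a two-block module with one block
missing is MISSING_1 here.

## Cross-group comparison

* **Completion rates** are per-group fractions of assemblies in which a
  module is (by default loosely) complete. Only modules loosely complete in
  at least one assembly overall are profiled; others carry no signal.
* **Variability selection** uses the *population* standard deviation (n
  denominator) of the per-group rates — "standard deviation of the
  population" is read literally — with a default threshold of 0.2,
  selections sorted by SD descending then module id.
* **Core module sets** per group contain modules loosely complete in at
  least 50% (inclusive) of the group's assemblies; Venn-region counts are
  reported for every non-empty combination of groups and always sum to the
  size of the union of the group sets.
* **Phi association.** The association between binary presence (of a KO or a
  block) and a binary group indicator is the phi coefficient, computed from
  the 2×2 table closed form; it equals the Pearson correlation of the raw
  0/1 vectors (asserted to 1e-12 in tests). Phi is the natural choice here
  because perfect concordance and anti-concordance print as exactly ±1.
  When a margin of the table is zero the coefficient is undefined and is
  returned *flagged* rather than as a silent 0, which would corrupt
  downstream rankings. Presence can be taken at the orthologue or the block
  level (`block_presence_matrix` provides the latter); the caller chooses.
* **Classical tests.** Welch's t (unequal variances, Welch–Satterthwaite
  df) for two groups, one-way ANOVA F for more, and Levene's W for variance
  homogeneity, centred on the group mean (classic Levene) by default and
  switchable to median centring (Brown–Forsythe). Degenerate inputs — zero
  within-group variance with unequal means — return an error-flagged result
  instead of an unbounded statistic; identical groups return the natural
  limits (t = 0, p = 1).

## Duplication integration

Duplication events are read from the OrthoFinder `Duplications.tsv` dialect
and filtered at support ≥ 0.5 (inclusive — "at least 50%"). Two framings
coexist deliberately: node **totals** count events, while category
integration counts **distinct genes** — the duplicated gene set of a node is
the union of both descendant gene lists over its events (a gene under both
descendants counts once; union semantics are the documented resolution of an
ambiguity), and each distinct gene adds one count to each of its categories.
Genes without annotations are tallied, not dropped. Categories are opaque
namespaced identifiers (InterPro entry, GO term); no ontology traversal or
GO-ancestor propagation is performed. Exports include a per-node summary TSV
and an iTOL pie-chart annotation with radii proportional to log10 of the
event total and an optional top-k category cut (all categories by default,
since any display-level k is arbitrary).

## Assembly QC

The BUSCO parser extracts the `C/S/D/F/M/n` summary line and enforces the
rounding identities (C = S + D ± 0.1; C + F + M = 100 ± 0.2). The quality
gate passes an assembly when complete ≥ 35% **and** missing < 50%; the
strict `<` on missing follows the more precise of two inconsistent
formulations of the rule ("≤ 50" elsewhere), and both thresholds are
parameters. RepeatMasker `.tbl` parsing collates top-level categories into
retroelements, DNA transposons, simple repeats, unclassified, and "other"
(satellites, small RNA, low complexity, rolling-circles), ignoring indented
subcategory rows to avoid double counting. Protein statistics are the
sequence count and the unfiltered arithmetic mean length after stripping
stop characters.

## Synthetic data

The generator emulates the *structure* of a multi-class comparative study,
and its defaults are the standard conditions the test suite runs under:

| parameter | default | rationale |
|---|---|---|
| groups | 4 classes × 8 genome assemblies | enough groups for ANOVA/Venn, realistic class sizes |
| modules | 200, 2–6 blocks each | desk-scale stand-in for a few-hundred-module catalogue |
| P(OR alternative) / P(complex) | 0.3 / 0.2 | complexes and alternatives present but minority features, as in real catalogues |
| complex size | 2–4 subunits | typical enzyme-complex sizes |
| baseline KO presence | 0.9 | core metabolism is largely conserved; most modules complete in most assemblies |
| differential modules | 10, knockout probability 0.9 | clean class-specific pathway-loss signal |
| transcriptome dropout | 0.3 (1KP-like), 0.1 (MMETSP-like) | transcriptomes systematically lose annotatable genes, one source more than the other |
| duplications | 8–24 events/node, supports uniform on [0, 1] | a 0.5 support filter then keeps ~50% by construction |
| category enrichment odds | 5 against a uniform background of 8 categories | strong node-specific functional signal (e.g. a haem-peroxidase-like category concentrated on one clade's node) |

Presence is simulated at the KO level (completeness consumes KO sets); a
thin one-gene-per-KO wrapper exercises the annotation readers. The species
tree is a ladder so internal node labels are reproducible. All draws come
from a seeded integer-state generator (numpy PCG64) with independent
per-component streams, so a fixed seed reproduces every emitted file
byte-for-byte across platforms.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: sequence content, annotation error correlated
with phylogeny or assembly quality, partially-lost modules with realistic
within-pathway correlation, real KEGG module topologies, or duplication
supports correlated with node depth. Recovery results on planted signals are
upper bounds on real-data behaviour.

## Problem sizes

The test suite grades 200 modules × 32 assemblies, checks the grading oracle
on 1,000 random pairs and monotonicity on 500 random extensions, and runs in
a few seconds on one CPU. The acceptance script computes its quantities
analytically (n = 11 assemblies) in well under a second.

## Known limitations

* No BLAST/BLAT-style rescue of unannotated orthologues; grades can only be
  as good as the input annotations.
* No multiple-testing correction is applied anywhere (none is part of the
  workflow being reproduced); p-values are descriptive.
* The short-module category suppression of interactive reconstruction tools
  is not replicated (see above).
* Undefined phi values must be handled by the caller; they are flagged, not
  imputed.
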