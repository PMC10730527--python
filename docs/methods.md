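# Methods

This note documents the models, statistics and design choices behind
`anatomod`, in the order the pipeline applies them, together with the
synthetic study conditions the tests run under and what those tests do and
do not demonstrate.

## Ontology model and information content

The anatomy ontology is a DAG of terms with typed child→parent edges
restricted to `is_a`, `part_of` and `develops_from` — the subset needed to
say what a structure is, what it belongs to, and what it develops from.
Parsing (via `obonet`) drops obsolete terms, ignores other relationship
types with a warning, and rejects cyclic inputs.

Information content is annotation-based:

    IC(t) = −ln( (count(t) + c) / total )

* `count(t)` uses **closure-propagated** annotations (a protein annotated to
  a term is implicitly annotated to all its `is_a`/`part_of` ancestors).
  This is the true-path convention; it is what makes IC anti-monotone along
  the hierarchy, which the suite asserts as an invariant.
* `total` is the number of distinct proteins annotated anywhere in the
  ontology.
* `c` is a pseudocount (default **1**) that keeps `p(t) > 0` for unannotated
  terms; `p(t)` is capped at 1 so IC is never negative. With `c = 0` an
  unannotated term is a hard error by default (configurable to `+inf`).
* Natural log. Only ratios and orderings of IC reach the downstream scores,
  so the base is a pure convention.

## Term and protein similarity

Similarity maximises over the common-ancestor set `S(t1,t2)` taken over the
`{is_a, part_of}` closure. `develops_from` is deliberately excluded from
the similarity closure — developmental precursorship is not subsumption —
but *is* used when collecting a target entity's "originally annotated"
proteins (a protein on the fin bud belongs to the fin's seed set).

* `lin`: `max_{t∈S} 2·IC(t) / (IC(t1)+IC(t2))`, bounded in [0,1],
  symmetric, 1 on self-pairs with positive IC. The degenerate
  `IC(t1)+IC(t2)=0` case returns 0.
* `schlicker_printed`: the Lin term multiplied by `(1+IC(t))`. This form is
  **unbounded above**; it is kept verbatim as one of the two supported
  scores, and the semantic network min–max rescales such scores into [0,1]
  before integration.
* `schlicker_classic`: the Lin term multiplied by `(1−p(t))` with the raw
  (pseudocount-free) annotation probability — the bounded relevance variant,
  off by default.

Protein-level similarity aggregates term similarities over the two
annotation sets: `max` over the cross product by default (the simplest
order-preserving choice, exact for single-annotation proteins), with a
best-match-average (`bma`) variant. A protein without annotations has *no
defined similarity*; callers receive an explicit signal rather than a zero.

## Network integration

The PPI network is the backbone. For each PPI edge whose endpoints both have
defined semantic scores:

    w = α · w_ppi + (1 − α) · w_sem        (α default 0.5)

A defined-but-dissimilar pair contributes `w_sem = 0`; pairs where either
endpoint is unannotated keep `w_ppi` unchanged; pairs similar only
semantically are **not** added as edges. Edges with final weight below
`min_weight` (default 0 — no filtering) are removed as presumed spurious
interactions. The convex combination is this package's explicit choice: it
is symmetric, order-preserving in both inputs, and reproduces the pure-PPI
and pure-semantic limits at α = 1 and α = 0. STRING scores are accepted in
the integer 0–1000 dialect (divided by 1000) or already in [0,1],
auto-detected from the file's maximum; duplicate pairs keep the maximum
score and self-loops are dropped.

## Candidate scoring and cross-validation

The Hishigaki chi-square statistic for protein `u` against annotated set `A`:

    f = |A ∩ V| / |V|                      (background frequency)
    n = annotated weight in u's neighbourhood
    e = (total incident weight) · f
    score(u) = sign(n − e) · (n − e)² / e   (0 when e = 0)

Choices, each configurable:

* **Weighted mode by default** — on an integrated network the edge weights
  carry the evidence, and weighted degree is preferred over plain degree
  throughout the workflow; `count` mode recovers the original
  count-based formulation (and is invariant to edge weights, asserted in the
  suite; the weighted score scales with the weights).
* **Signed statistic** — an unsigned chi-square would rank
  annotation-depleted neighbourhoods spuriously high.
* **Background over network nodes**, not the whole annotation corpus: only
  network nodes are scoreable.

Leave-one-out cross-validation scores each annotated protein with its own
annotation removed from both the neighbourhood and the background count
(strict LOO), and every non-annotated node once against the full set.
ROC/PR curves are built over the pooled ranking with tied scores grouped
(threshold sweep over distinct values, so the result is order-independent);
AUC is trapezoidal, which under grouped ties equals the Mann–Whitney
pair-count statistic with ties worth ½ — the suite asserts that equality.
The candidate cutoff is the *lowest* score (maximal recall) whose
cross-validated precision meets the requested threshold (≥ comparison);
negatives are scored with the full annotated set.

## Modules, ranking and comparison

A module is the union of originally annotated proteins (labelled
`original_direct` or `original_part_or_precursor`) and predicted candidates,
intersected with the network; originals absent from the network are reported
as `lost`. Ranking uses weighted degree **within the module's induced
subgraph** (hub-ness is treated as a modular property; a flag switches to
whole-network degree), descending, with lexicographic tie-breaks for
reproducible rank files.

Cross-species comparison maps modules through an ortholog table. A protein
is *conserved* when at least one ortholog lies in the other species' module;
with one-to-many orthology **all** in-module orthologs are retained, so the
two species' conserved counts can differ — both per-side sets and the
matched pair list are reported rather than a single collapsed count.
Normalised weighted degree divides by module size (a monotone transform, so
within-module order is preserved). The conserved-vs-specific comparison uses
a two-sided Wilcoxon rank-sum test by default (one-sided available):
exact when the pooled sample is small (n1+n2 ≤ 14) and tie-free, otherwise
the normal approximation with tie and continuity corrections; a pooled
sample with zero spread short-circuits to p = 1. When either group is empty
the test is skipped with a warning but the partitions are still reported.

## Enrichment

Over-representation uses the one-sided Fisher exact test — the
hypergeometric upper tail `P(X ≥ k)` for `k` of `n` study proteins carrying
a term held by `K` of `N` background proteins — with annotations propagated
over `{is_a, part_of}` before counting. The `enriched` flag thresholds the
**raw** p-value at α = 0.05 (the over-representation convention this
workflow follows); Benjamini–Hochberg-adjusted values are always emitted
alongside. The default background is the species' full annotated protein
set, configurable to e.g. network nodes. The same engine serves GO-BP-style
tables: a GO corpus is just another ontology + annotation pair. The fate
report maps one species' module-specific proteins through the ortholog table
(all targets retained, unmapped proteins counted) and enriches the mapped
set against the other species' annotations.

## Synthetic worlds: what is emulated, and what is not

`anatomod.synthetic` generates the study conditions end to end:

* **Ontology** — an `is_a` tree (depth 3, branching 2 → 15 terms by
  default) with two designated target entities, each given a `part_of` part
  and a `develops_from` precursor (rooted through an embryonic-structure
  term), mirroring the entity/part/bud pattern of real anatomy ontologies.
* **Annotations** — `annotated_fraction` (default 0.75) of each planted
  module is annotated to the target, its part or its precursor; the rest are
  *hidden* ground truth for prediction and carry only a coarser annotation
  to the target's `is_a` parent — emulating the coarse-granularity
  annotations genuinely understudied proteins tend to have, which is what
  makes the shared-enrichment validation between seed and predicted proteins
  informative. Background proteins get one off-target annotation each.
* **Networks** — planted-partition graphs: module pairs connect with
  `p_in = 0.3` (plus `hub_bias = 0.1` when either endpoint is conserved)
  and weights from U(0.6, 0.9); background pairs with `p_out = 0.01` and
  U(0.05, 0.2); 1% spurious edges on top. Uniform weight ranges were chosen
  over e.g. Beta distributions as the simplest parameterisation with
  controllable separation.
* **Orthology** — a cross-species bijection backbone plus duplicates: each
  B-gene gains a second A-copy with probability `duplication_rate = 0.25`,
  emulating post-duplication one-to-many orthology. Conserved module members
  are wired module-to-module; module-specific members map only into the
  other species' background, and duplicate copies sit outside the module, so
  the planted conserved labels are exactly the ortholog-recoverable ones.

Defaults: 500 proteins per species, module size 60,
`conserved_fraction = 0.3`. These sizes are scaled-down study conditions
chosen once: 500/60 keeps a full pipeline pass around a second while leaving
the module a small minority of the network, and module size 60 follows an
a-priori power calculation — at `hub_bias = 0.1` the conserved-vs-specific
weighted-degree contrast is ≈ 3.1 against a between-protein SD of ≈ 2.8,
giving the rank-sum test ≈ 0.97 power per species at α = 0.05, so the
planted effect is reliably recoverable rather than marginal.

What passing these simulations shows: the statistics are exact, the
estimators are calibrated (type-I error of the hub test sits at its nominal
5% when `hub_bias = 0`), and the pipeline recovers planted structure under
its own assumptions. What it does **not** show: performance on real
networks, whose degree distributions are heavy-tailed (the generator is
deliberately not scale-free), whose annotations are biased toward
well-studied proteins, and whose ortholog calls carry error.

## Numerical and degeneracy conventions

* Seeding: one integer seed drives a `SeedSequence` tree; identical seeds
  give byte-identical output files (asserted down to GraphML exports).
* Ties: grouped in ROC/PR; lexicographic in rankings; exact Wilcoxon
  declines tied data in favour of the corrected normal approximation.
* Degenerate inputs: empty annotation tables, unannotated proteins,
  single-member CV sets, empty conserved/specific groups and empty ortholog
  maps all produce explicit errors, warnings or skips — never silent zeros.
* STRING scores written by the generator are quantised to integer
  thousandths, so file round-trips agree to 5e-4.

## Known limitations

* The PPI/semantic combination rule is a stated stand-in (convex, α = 0.5);
  other monotone integration rules would change edge weights but not the
  package's contracts.
* Exact rank-sum enumeration under ties is not implemented (the corrected
  normal approximation is used instead).
* One planted module per entity per species; no scale-free degree
  structure; two species only.
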