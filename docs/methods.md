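# Methods

## Scope and model

`phenomatch` scores human disease phenotype profiles against
model-organism phenotype profiles across a pair of species-specific
ontologies, ranks model-species genes per disease, and evaluates the
ranking per disease category with a simulation null. It consumes
ontologies as OBO (is_a subset), annotation/association/orthology/bridge
tables as TSV, and per-category disease lists as one file per category.
It does no OWL reasoning: bridge mappings are consumed as precomputed
exact-equivalence tables, and anything not exactly mapped is resolved at
query time by ancestor fallback.

## Ontologies and closures

An ontology is a rooted DAG of terms under is_a; other relation types
are ignored. Obsolete terms are dropped entirely. The reflexive
transitive ancestor closure of every term is precomputed once; a cycle
is a hard load error. Multi-rooted inputs get a synthetic root
(`SYNTH:0000000`) inserted above all parent-less terms, because both the
closure semantics and MICA lookup require a single top element.

## Information content

`IC(t) = −ln(count(t)/N)` in natural-log units, where `count(t)` is the
number of distinct corpus entities annotated to `t` or any descendant
and `N` the corpus size. The corpus for a model species is all model
entities of that species plus all diseases contributing through their
bridged images, so disease–model scores share one scale. There are no
pseudo-counts: a term nothing annotates is simply absent from the table
and the MICA maximisation ranges over corpus-covered common ancestors
only, with the root (IC 0 whenever every entity subsumes to it) as a
guaranteed floor. The log base is a uniform rescaling and does not
affect rankings; natural log is fixed for reproducibility.

## Term and profile scoring

`score(t1,t2) = sqrt(simJ(t1,t2) · IC(MICA(t1,t2)))` combines ancestor
overlap with informativeness; `score(t,t) = sqrt(IC(t))`. The profile
score bridges every human term into the model ontology (a term mapping
to several targets participates through each, best one wins), takes best
matches in both directions — the symmetric mean deliberately penalises
models carrying many extraneous phenotypes — and normalises by the
self-match of the disease's bridged image:

```
percentage = min(100, 50·(raw_max/self_max + raw_mean/self_mean))
```

The cap at 100 absorbs rare bridged-image asymmetries (a disease term
with several images contributes once on the disease side but each image
counts in the self-mean). A disease whose image is only an IC-0 root
gets percentage 0 with a warning rather than being dropped: an
uninformative bridge should look like a non-match, not like missing
data. Genes aggregate over their models by max — one faithful mutant
suffices to implicate a gene. Every "best" choice breaks ties by higher
score, then lexicographically smaller identifier, so runs are
deterministic across platforms.

## Evaluation

Per category, all (disease, gene, score, label) records are pooled into
one ROC (micro-averaging; a macro per-disease average is available as
`macro_average_auc`). Thresholds are distinct score values, not integer
ranks, so tied genes fall at the same threshold and the AUC equals the
Mann–Whitney statistic with ties at 1/2 — this removes any ordering
nondeterminism among ties. The candidate universe per disease is the
whole gene catalog; a positive is a gene with a known, ortholog-mapped
association to that disease, every other gene a negative (some
"negatives" may be undiscovered associations; this biases AUC slightly
downward and is accepted).

The null for a category of size k draws, 50 times by default, k
diseases uniformly without replacement from the full evaluable pool —
the category's own diseases are not excluded, which is the simpler
reading of random matched-size sets — and records the pooled AUC of each
draw. The observed AUC is converted to `z = (auc − mean)/sd` (sample SD,
n−1) and a two-sided Gaussian p-value; an empirical add-one tail p is
available for comparison. The test is two-sided on purpose: a category
can be significantly *worse* than a random set of diseases, and that
pattern is diagnostically as important as being better. Sub-seeds per
category derive from SHA-256 of (master seed, species, category), so the
table is reproducible and insensitive to evaluation order. The pooled
all-diseases row carries no p-value (its matched-size null is
degenerate by construction). Categories below the minimum size (default
10, configurable) are reported with absent AUC/p rather than silently
dropped.

## Reports

Per-category phenotype frequency tables count direct annotations only —
no closure propagation — because "most frequent clinical phenotype"
refers to what curators actually annotated. Best-match reports score one
human term's bridged image against every model term in use and return
all terms tied at the top (exact tie by default; an epsilon is available
for floating-point grouping), each flagged `exact` or
`ancestor-fallback`. Under this score an in-use ancestor image term
itself strictly beats its descendants (`simJ(t,t)=1 > simJ(t,child)`),
so the characteristic missing-equivalence signature is a flagged tie
among the image's equally-deep in-use descendants — the realistic case,
since generic mid-level terms are rarely direct annotations.

## Synthetic worlds

The generator builds one random rooted template DAG (each term picks
1–`max_parents` parents among earlier terms), clones it per species with
relabelled identifiers, and re-draws a small fraction of model-side
parent sets (`edge_perturbation`, default 0.05) to emulate imperfect
structural homology. Exact bridge entries cover a `bridge_coverage`
fraction of human terms (root always mapped). Diseases draw 4–8 terms
uniformly from non-root human terms; each true gene's model profile is a
corrupted copy of the *template counterpart* of its disease profile —
the biological correspondence exists regardless of how complete the
curated bridge is, which is exactly what lets an incomplete bridge
degrade scoring without touching the underlying signal. Decoy genes draw
independent profiles.

The noise model (`corrupt_profile`): each term is kept with probability
*fidelity*; kept terms are generalised to a parent or swapped for a
sibling with the respective rates (default 0.1 each); a dropped term is
replaced with a uniformly random term with probability `dropout`
(default 1.0 — a model phenotyped broadly records *something*, keeping
profile sizes realistic and making fidelity interpolate cleanly between
a perfect phenocopy and a random profile) and removed otherwise; an
emptied profile is padded with the root.

Categories (default five, planted fidelities 0.35–0.9 spanning the
poorly- to well-modelled range seen in real cross-species use) are
assigned uniformly; with probability `co_assignment_prob` a disease
receives a second category and inherits the *maximum* fidelity of its
categories — a disease genuinely spanning areas should not be penalised
twice. A fish-like species duplicates a human gene with probability 0.3,
and only one duplicate carries the phenocopying model, a recoverable
difficulty factor mimicking genome duplication.

What the generator does *not* emulate: real ontology depth profiles and
annotation-frequency skew, curation biases that correlate across
categories, diseases sharing genes, and multi-gene models. Passing tests
therefore demonstrate correctness of the machinery and recoverability of
planted effects, not real-data performance levels.

## Problem sizes and numerics

Default test/evaluation worlds use 80–150 terms per ontology, 100–200
diseases, one model per gene and 40–100 decoy genes; these sizes give
stable AUC estimates (chance-level worlds land in [0.45, 0.55]; planted
perfect signal above 0.99) while keeping any single run in seconds.
Null simulations use 50 draws, matching the default reported mean/SD
convention. Term-pair scores and bridged images are memoised per
context; pooled ROC uses a vectorised threshold sweep. Floating-point
output is written with fixed formats so identical seeds give
byte-identical files.

## Known limitations

- The pairwise score is one defensible realisation of simJ×IC profile
  matching; absolute percentages are not comparable to other
  implementations, only rankings within a context are meaningful.
- The Gaussian p-value rests on a 50-draw null; very small categories
  give noisy SDs (the empirical p option is more honest there but
  bounded below by 1/(n_sim+1)).
- Bridge fallback walks is_a ancestors only; part-of or cross-product
  rescue paths are out of scope.
- One world covers one model species; multi-species runs are separate
  worlds/pipelines.
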