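# Methods

## Model

A hierarchical ontology is held as one rooted DAG per namespace, with
parent → child edges pointing away from the root.  The three relation
types commonly distinguished in such vocabularies (`is_a`, `part_of`,
`regulates`) are merged into a single edge set and treated identically;
the subset kept is configurable per run.  Obsolete terms are removed at
load time together with their edges, and acyclicity is validated.

**Levels.**  Level(t) is the length of the *longest* directed path from
t's namespace root to t.  The longest-path convention is a deliberate
design choice: it is the only depth definition that guarantees
Level(parent) < Level(child) on every edge of an arbitrary DAG, which in
turn keeps every ratio Level(i)/Level(c_j) in the level-coefficient
recursion strictly below 1 and the coefficients inside [0, 1].
Shortest-path depth can invert that ratio on multi-parent terms.  An
implementation using shortest-path depths would produce different
coefficients on multi-parent ontologies; results are therefore only
comparable between runs using the same convention.

**Level coefficients.**  LC(leaf) = 1; for an internal term the LC is the
mean over children of LC(child) · Level(term)/Level(child), evaluated in
reverse topological order so every child is finished before its parents.
Roots get LC = 0 (their level is 0, so every ratio vanishes).  The result
is a pure function of the DAG — independent of tie order among terms at
the same level — and is stored at full float precision.

**Annotation classes.**  The term universe is the lexicographically
sorted list of *all* non-obsolete terms of the loaded namespaces, not
just terms with annotations.  The chance-agreement cell p22 of the
agreement table needs weights for unannotated terms, so restricting the
universe to annotated terms would change the statistic; the full-ontology
universe is the default and the annotated-only variant can be obtained by
loading a pruned ontology.  A gene's class marks its direct terms plus
all ancestors.  Genes with zero surviving annotations are excluded
rather than scored: kappa is undefined for an all-zero vector.

**Kappa, SE, Z.**  The 2×2 agreement table accumulates LC mass per cell;
κ = (P_o − P_e)/(1 − P_e) on the cell proportions.  The standard error is
the Fleiss–Cohen–Everitt large-sample (non-null) variance of κ̂ — the
same formula the R `vcd` package uses — with the effective sample size N
taken as the table's total LC mass, treating weighted sums as
pseudo-counts.  This choice is not forced by the statistic; N equal to
the raw term count is available through the `effective_n` argument.  Z =
κ/SE is the headline score.  Degenerate tables (all mass in one cell,
P_e = 1) yield NaN throughout; a pair with perfect agreement and mixed
bits has SE = 0 and Z = +∞, which sorts first in rankings as intended.
By default one table spans all namespaces ("all-ontologies"); the
per-namespace variants mask the universe to a single namespace.

Cell orientation (p12 = first argument only, p21 = second only) is fixed
for reproducibility but cosmetic — κ, SE and Z are invariant to swapping.

## Comparator measures

* **Unweighted kappa** (the DAVID classification statistic): Cohen's
  kappa on the raw binary vectors.  It equals the LC-weighted kappa with
  every weight forced to 1; that equivalence is exercised as an oracle
  test against an independent brute-force kappa.
* **IC table**: P(t) = (genes whose closure contains t) / (genes with ≥ 1
  annotation in t's namespace); IC = −log P.  Counting is gene-level and
  descendant-inclusive (the standard Resnik convention).  Terms reached
  by no gene have undefined IC and are dropped from IC-based scoring
  with a logged count.
* **Lin**: 2·IC_ms/(IC(t₁)+IC(t₂)) with IC_ms the maximum IC over common
  ancestors, each term counting among its own ancestors.  Cross-namespace
  pairs and pairs whose subsumers are all uninformative score 0.
* **Relevance**: Lin × (1 − e^(−IC_ms)); always ≤ Lin.
* **funSimMax**: mean of the row-wise-max average and column-wise-max
  average of the pairwise similarity matrix (best-match average).
* **Hausdorff-style**: max over one group of the min over the other,
  outer max of the two directions, applied to *similarities* exactly as
  the method is defined.  Applied to similarities the max/min rule
  rewards a single well-matched outlier; the semantic oddity is kept
  as-is rather than "fixed".
* **dot**: cosine of the IC-weighted closure vectors.  The original
  description names this method without printing a formula; the cosine
  form here is a reconstruction and is documented as such, so its values
  should not be compared against other implementations.

Gene-level IC scores are computed per namespace on the *direct*
annotation terms (a pathway's enriched terms are themselves a direct term
list) and summed over the three namespaces; namespaces without scoreable
terms on either side contribute nothing, and a pair with no scoreable
namespace is NaN.

## Benchmark harness

For each gene set: (1) one-sided hypergeometric enrichment of every term
with at least one member hit, membership being closure-based, against the
annotated-gene background; (2) per namespace, the k = 20 smallest
p-values (ties broken lexicographically by term id) pooled into the
representative term group — rank-based selection, no multiple-testing
correction, because a fixed-size group is wanted rather than a
significance cutoff; (3) every annotated gene scored against the group;
(4) ROC AUC via the Mann–Whitney rank statistic with midranks for ties,
positives being the annotated pathway members, and a two-sample KS test
comparing member and non-member scores.  Pathways with fewer than 5
annotated genes are skipped.  The enrichment step is a classic
hypergeometric test; ontology-aware enrichment algorithms that decorrelate
parent/child terms (elim/weight style) are deliberately out of scope, and
published results obtained with them may select somewhat different term
groups.

## Synthetic data

The generator emulates the structure the method needs — rooted DAGs with
multi-parent terms, and gene modules that share coherent term
neighbourhoods — not the size statistics of any real ontology.  Defaults:
3 namespaces × 60 terms, max depth 6, branching 2–4, multi-parent
probability 0.1, 150 genes in 5 modules of 30, 8 planted terms per
module, 3–6 direct annotations per gene, annotation noise 0.1 (the
probability that a draw is replaced by a uniformly random term), ~15 %
IEA evidence codes so evidence filtering has something to act on.  These
sizes make the full nine-method benchmark run in seconds while leaving
each module enough signal to be recoverable; they were chosen once as the
package's standard study conditions.  All generators are pure functions
of (spec, seed) and reruns are byte-identical.

One property of the harness is worth stating plainly: the enriched term
group is derived from the members' own annotations, so even with fully
random annotations (noise 1.0) the members of a set score above chance
against "their" group — selection leakage that is inherent to the
enrich-on-members design at any scale, and especially visible at toy
scale.  Tests that need a leakage-free read of the planted signal
therefore score genes against the *planted* module subtrees, which are
independent of the evaluated genes; under that reading noise 1.0 gives
AUC ≈ 0.5 as it should.  Passing benchmark tests consequently show that
the pipeline ranks related genes highly under the generator's planted
signal; they do not show how any method behaves on real annotation
corpora, whose term-count distributions, annotation depths and
inter-namespace correlations the generator does not attempt to match.

## Numerical choices and degenerate inputs

* LC and kappa are exact float computations; no rounding anywhere.
* Agreement-table cells sum to the universe LC mass to ~1e-9 by
  construction; the toy fixture values are asserted to 1e-9 and oracle
  equivalences to 1e-12.
* Ties in enrichment p-values and in search scores break
  lexicographically; ROC uses midranks, so AUC equals the tie-aware
  pair-counting fraction exactly.
* Empty gene sets, single-class label vectors, empty term groups,
  unknown genes/terms, cyclic ontologies and orphan terms all raise
  typed errors rather than returning silent defaults.
* Ancestor sets, per-gene annotation classes and pairwise term
  similarities are memoized; the caches assume the DAG and annotation
  set are not mutated after construction.

## Limitations

* No OWL parsing, no cross-namespace relations, no species ID mapping,
  no annotation downloads; graphics are out of scope (tabular exports
  only).
* Evidence codes support filtering but not weighting.
* The "dot" comparator is a reconstruction (see above).
* IC-based comparisons require both entities to be scored against the
  same annotation corpus; the LC-based score has no such dependence,
  which is its main practical advantage.
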