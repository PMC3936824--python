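# Methods

## Model

The unit of data is a patient case: a set of phenotype concepts from a
rooted subclass DAG (a deep, HPO-style hierarchy) plus one diagnosis
concept from a shallow, two-level disease hierarchy (root → disorder
groups → disorders). Cases are mined as transactions of typed items under
a constrained Apriori: candidate and frequent itemsets carry at most one
disease item, and only itemsets with exactly one disease item and at least
one phenotype item generate a class association rule
{phenotypes} → disorder.

Frequency counting during mining is always exact-match support; semantic
measures are attached *after* discovery. Mining is configured by an
absolute minimum support count (default 5, i.e. a relative threshold of
5/N) and a maximum itemset size (default 10).

## Taxonomic distances

All distances are edge counts, with `depth(root) = 0`. A path between two
distinct concepts must ascend from each concept to a common ancestor (each
concept counts as its own ancestor); the taxonomic distance is the minimum
total ascent over all common ancestors. On trees this equals
`depth(c1) + depth(c2) − 2·depth(LCA)`; on DAGs with multiple inheritance
it can be smaller, which is why it is computed directly. LCA ties under
multiple inheritance break by maximal depth, then lexicographic concept ID;
MICA ties by maximal information content, then depth, then ID. All
tie-breaks are deterministic so reruns are byte-identical.

## Similarity metrics

The custom metric is `depth(LCA) / (Dist + depth(LCA))` with
`Dist = 2^l` for distinct phenotypes and `10^(l−2)` for distinct diseases
(`l` the taxonomic distance); `Dist = 0` for identical non-root concepts
(similarity 1) and, by convention, 1 for the root compared with itself
(similarity 0, since the root's depth is already 0). The exponential
transform makes similarity decay faster than distance; the disease base of
10 with offset 2 reflects the two-level hierarchy, giving intra-group
disorders 0.5 and cross-group disorders 0.

Information content is `−ln(freq(c)/N)` over *non-propagated* per-case
annotation frequencies: a case counts once per concept it is annotated
with, and nothing is propagated to ancestors. This is a deliberate
modelling choice — it reproduces the documented failure modes of the
IC-based metrics on clinical corpora, where generic ancestors are rarely
annotated directly:

* a pair whose common ancestors all have frequency 0 has an undefined
  (infinite-IC) MICA and is treated as completely dissimilar (similarity 0)
  for Resnik, Lin and Jiang–Conrath;
* the MICA can be *rarer* than the concepts themselves, driving Lin above
  1 (the reconstructed 2.19 case) and the Jiang–Conrath distance negative.
  Lin values pass through the [0,1] clamp before entering semantic
  support; negative JC distances are clamped to 0, making the JC
  similarity `1/(1 + max(0, d))` equal to 1 there. The printed form of the
  JC similarity in the source material is ambiguous; the standard JC
  distance with a bounded inversion is used.

Cross-kind pairs (phenotype vs disease item) score 0 under every metric.

## Semantic support and measures

`SemSupport(I) = (1/n) Σ_t Π_{i∈I} max_{v∈t} ‖sim(i,v)‖`, with the max
over an empty transaction defined as 0 and the product over an empty
itemset as 1. The "arg max" of the defining expression is read as the
maximum similarity value, and ‖·‖ as the [0,1] clamp — the only reading
under which the product is well typed and bounded. The support of a rule's
antecedent-plus-consequent is computed on the union itemset in one pass,
not factored.

Every measure takes a pluggable support function, so each has a
traditional and a semantic variant that coincide exactly under the
exact-match similarity. Degenerate denominators: conviction at confidence
1 returns a +∞ sentinel (a ceiling-confidence rule is maximally
interesting by conviction's own logic; the sentinel dominates finite vote
weights); the correlation coefficient returns 0 when any variance factor
vanishes; cosine and correlation denominators take square roots, as in
their standard definitions.

For any itemset whose items are non-root concepts, each best-match factor
dominates the exact-match indicator, so semantic support ≥ traditional
support. The single exception is the ontology root, whose self-similarity
is 0 by the distance convention; roots are bookkeeping concepts and are
never used as annotations by the generator or in realistic corpora.

## Classification and evaluation

Rule firing on a new case is semantic: the match score is the product over
antecedent items of the best similarity against the case's phenotypes, and
a rule fires when the score exceeds a threshold (default 0). With the
exact-match similarity this reduces to subset firing. Partial firing is
what lets a rule mined on *Short stature* fire on a case annotated with
*Rhizomelic short stature* — the behaviour exact-match classifiers lack.

Fired rules are grouped by antecedent; each group votes once for the
consequent of its best rule under the configured measure. Simple voting
adds 1 per group; weighted voting adds the group's maximum measure value,
additionally multiplied by the group's match score in semantic mode (so
weaker partial matches carry proportionally less weight). Ranking ties
break lexicographically on disease ID.

Evaluation is stratified 5-fold cross-validation (stratified by diagnosis
and seed-controlled: with 15 classes, unstratified folds can lose classes
entirely). Accuracy at cut-off K counts a case as correct only when the
exact true disorder — not a sub- or superclass — appears in the top K.
Paired classifiers are compared on identical folds; the discordant cells
of the 2×2 correctness table feed McNemar's chi-squared statistic with
continuity correction, `(max(0, |b−c|−1))² / (b+c)`, the correction
clamped at 0 so perfect agreement cannot yield a positive statistic. The
p-value is the upper tail of χ²(1).

## Synthetic data

The generator emulates the kind of annotated rare-disease corpus the
method targets: defaults of 15 disorders × 26 cases (390 cases), a
depth-4, branching-5 phenotype tree (781 concepts, 625 leaves), 5 disorder
groups, per-disorder profiles of 30 leaf phenotypes biased 80% toward one
top-level branch, and a truncated-Poisson (minimum 1) number of phenotypes
per case with mean 4.49. These defaults land the cohort-level statistics
near their published analogues (≈480–510 distinct phenotypes in play; mean
phenotypes per case within ±0.5 of 4.49 across seeds).

Noise is *sibling substitution*: with probability ε (default 0.3) a
sampled profile phenotype is replaced by a same-parent sibling outside the
profile. This is exactly the situation the semantic measures exist for:
exact matching sees an unrelated concept, structural similarity sees a
near match. At ε = 0 every case is a subset of its disorder's profile; at
ε = 1 traditional support of profile–disorder pairs collapses toward 0
while semantic support remains positive.

What the generator does **not** emulate: correlated phenotype
co-occurrence within a case, hierarchy-level (parent/child rather than
sibling) annotation drift, class imbalance, multi-ontology annotation
noise, and the lexical variability of real clinical text. Passing tests
therefore demonstrate the machinery and the direction of the
semantic-vs-traditional gap under structured noise, not clinical
performance on real corpora.

## Numerical and design choices

* Natural logarithm for IC throughout; Lin is log-base invariant, the
  others are only compared within one base.
* The benchmark problem sizes used in tests (cohorts of 90–390 cases,
  ontologies of tens to hundreds of concepts, 5 seeds for the directional
  semantic-vs-traditional comparison) keep the full suite in the
  ten-second range while exercising every code path; similarity values and
  per-itemset supports are memoised, which is what makes semantic scoring
  of hundreds of rules over hundreds of transactions cheap.
* Obsolete OBO terms and non-`is_a` relationships are ignored on load;
  only class–subclass structure enters any formula.
* Mining output order (size, then lexicographic IDs) and all tie-breaks
  are fixed, so rule files are byte-reproducible.

## Limitations

* No true-path propagation of annotations, by design; corpora whose IC
  should be propagated need preprocessing before `CorpusStats`.
* IC-based metrics require a corpus; they fall back to "dissimilar" rather
  than guessing when frequencies are missing.
* The disease distance transform assumes the two-level group hierarchy; a
  deeper disease ontology would need a different exponent offset.
* No rule pruning or probability calibration: vote totals rank disorders
  but are not probabilities.
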