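# semrules

Semantic interestingness measures for class association rule mining over
ontology-annotated patient cases.

## The problem

Rare-disease cohorts (the motivating domain is skeletal dysplasias) are
stored as patient cases annotated with phenotype concepts from a deep
ontology such as the Human Phenotype Ontology, and a diagnosis concept from
a shallow disease ontology of disorder groups. Association rule mining over
such data discovers rules {clinical features} → {disorder}, but classical
interestingness measures match concepts *exactly*: *Rhizomelic short
stature* and *Neonatal short-limb short stature* count as unrelated even
though they are siblings in the hierarchy. `semrules` replaces exact
matching with similarity computed from ontology structure, and evaluates
the effect with a voting classifier and McNemar's paired test.

## The method

**Support and semantic support.** For an itemset *I* over a database of *n*
transactions, traditional support is the fraction of transactions
containing every item of *I*. Semantic support relaxes containment to
best-match similarity:

    SemSupport(I) = (1/n) Σ_t Π_{i∈I} max_{v∈t} ‖sim(i, v)‖

with ‖·‖ the clamp into [0, 1]. With the exact-match indicator as `sim`
this reduces identically to traditional support. Substituting SemSupport
for Support inside confidence, lift, conviction, leverage, Jaccard, cosine
and the correlation coefficient yields the semantic variant of each
measure.

**Similarity.** The custom metric is
`sim(c1,c2) = depth(LCA) / (Dist(c1,c2) + depth(LCA))`, where `Dist` grows
exponentially in the taxonomic path length *l* between the concepts —
`2^l` for phenotypes, `10^(l−2)` for the two-level disease hierarchy (so
intra-group disorders score 0.5). The classic baselines Resnik, Lin,
Jiang–Conrath (corpus information content, `IC = −ln p`) and Wu & Palmer
are included, with undefined-MICA pairs treated as completely dissimilar.

**Mining and classification.** A constrained Apriori admits at most one
disease item per itemset; each frequent itemset with exactly one disease
and ≥1 phenotype becomes a rule. Rules fire on a new case by (possibly
partial) antecedent matching, are grouped by antecedent, and vote — simply
or weighted by their interestingness — for a disorder ranking, evaluated
by stratified cross-validated top-K accuracy.

## Worked example

`examples/` holds one short script per capability. The three-patient
knowledge base (`examples/01_worked_example.py`):

```
p1: ['Abnormality of the ribs', 'Neonatal short-limb short stature'] -> Achondroplasia
p2: ['Narrow chest', 'Neonatal short-limb short stature'] -> Achondroplasia
p3: ['Abnormality of the ribs', 'Rhizomelic short stature'] -> Achondroplasia

support({cf1, cf3, bd1}) = 0.33
confidence({cf1, cf3} -> Achondroplasia) = 1.00
```

One patient in three carries the full pattern (support 1/3), and every
patient with both features has the disorder (confidence 1). On a noisy
synthetic cohort (`examples/04_evaluate_voting.py`, 135 cases, 9
disorders, 40% sibling-substitution noise):

```
K   traditional   semantic   (mean accuracy %, 5-fold CV)
1         70.37      74.07
3         81.48      99.26
5         81.48      99.26
```

Semantic matching recovers the cases whose annotations drifted to sibling
concepts, which exact-match rules cannot fire on.

A thin CLI wraps the same pipeline:

```sh
semrules fixture --out fx/
semrules mine --phenotypes fx/phenotypes.obo --diseases fx/diseases.obo \
    --cases fx/cases.tsv --min-support-count 1 --max-size 3 --out rules.tsv
semrules simulate --seed 1 --eps 0.4 --out cohort/
semrules compare --phenotypes cohort/phenotypes.obo --diseases cohort/diseases.obo \
    --cases cohort/cases.tsv --metric custom --k 5 --seed 1
```

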