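"""Cross-validated diagnosis ranking with the voting classifier.

Evaluates weighted confidence voting in both modes on a noisy synthetic
cohort: 5-fold stratified cross-validation, accuracy at recall cut-offs
K = 1..5.
"""

import semrules as sr

cfg = sr.SyntheticConfig(
    pheno_depth=3, pheno_branching=4, n_groups=3, n_diseases=9,
    cases_per_disease=15, profile_size=6, phenotypes_per_case_mean=4.0,
    sibling_noise_eps=0.4, seed=7,
)
pheno = sr.generate_phenotype_ontology(cfg)
disease = sr.generate_disease_ontology(cfg)
db, _ = sr.generate_cohort(cfg, pheno, disease)
sim = sr.SimilarityFunction(
    metric="custom", phenotype_graph=pheno, disease_graph=disease
)

reports = {}
for mode, s in (("traditional", None), ("semantic", sim)):
    config = sr.VotingConfig(scheme="weighted", measure="confidence",
                             mode=mode, sim=s)
    reports[mode] = sr.cross_validate(
        db, config, min_support_count=3, max_size=6, folds=5,
        k_values=(1, 2, 3, 4, 5), seed=7,
    )

print(f"{db.n} cases, {cfg.n_diseases} disorders, sibling noise "
      f"eps={cfg.sibling_noise_eps}\n")
print("K   traditional   semantic   (mean accuracy %, 5-fold CV)")
for k in range(1, 6):
    print(f"{k}   {reports['traditional'].accuracy_at_k[k]:>11.2f}"
          f"   {reports['semantic'].accuracy_at_k[k]:>8.2f}")
print("\nsemantic matching recovers cases whose annotations drifted to")
print("sibling concepts, which exact-match rules cannot fire on")
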