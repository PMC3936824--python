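"""The three-patient worked example: traditional support and confidence.

Builds the miniature knowledge base of three Achondroplasia patients, each
annotated with two clinical-feature concepts, and computes the exact-match
support of the itemset {neonatal short-limb short stature, abnormality of
the ribs, Achondroplasia} and the confidence of the derived rule.
"""

import semrules as sr
from semrules.measures import interestingness, support_function

pheno, disease, db, _ = sr.worked_example_fixture()

for t in db:
    names = sorted(pheno.labels.get(i.concept, i.concept) for i in t.phenotypes)
    print(f"{t.case_id}: {names} -> {disease.labels[t.disease.concept]}")

cf1 = sr.Item("HP:0008921", "phenotype")
cf3 = sr.Item("HP:0000772", "phenotype")
bd1 = sr.Item("BDO:Achondroplasia", "disease")
itemset = frozenset({cf1, cf3, bd1})

s = sr.support(itemset, db)
print(f"\nsupport({{cf1, cf3, bd1}}) = {s:.2f}")
print("-> exactly one of the three patients carries this full pattern")

rule = sr.ClassAssociationRule(
    antecedent=frozenset({cf1, cf3}), consequent=bd1, support=s
)
conf = interestingness(rule, "confidence", support_function(db))
print(f"confidence({{cf1, cf3}} -> Achondroplasia) = {conf:.2f}")
print("-> every patient showing both features has Achondroplasia")
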