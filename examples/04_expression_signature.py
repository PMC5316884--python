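"""Differential expression, signature PCA and the grade classifier.

Generates a synthetic cohort, normalises the expression matrix, runs the
stratified moderated test, and prints the signature size, the grade
silhouette on the signature PCs and the random-forest out-of-bag error.
"""

import pandas as pd

from meningomics.expression import (
    batch_adjust,
    moderated_de,
    quantile_normalize,
    rf_grade_classifier,
    signature_and_pca,
)
from meningomics.synthetic import CohortConfig, generate_cohort

paths, truth = generate_cohort(CohortConfig(n_atypical=12, n_benign=12, seed=5), "scratch/example_expr")
matrix = pd.read_csv(paths["expression.tsv"], sep="\t", index_col=0)
grades = dict(zip(truth.samples["sample_id"], truth.samples["grade"]))
batches = dict(zip(truth.samples["sample_id"], truth.samples["batch"]))
strata = {s: ("NF2" if g.startswith("NF2") else "non-NF2")
          for s, g in zip(truth.samples["sample_id"], truth.samples["subgroup"])}

matrix = batch_adjust(quantile_normalize(matrix), batches)
de = moderated_de(matrix, grades, strata=strata)
signature, coords, silhouette = signature_and_pca(de, matrix, grades)
_, oob_error, _ = rf_grade_classifier(matrix, grades, de, n_top=25, n_trees=1000, seed=5)

planted = set(truth.de_genes)
print(f"signature genes: {len(signature)} (planted {len(planted)}, "
      f"recovered {len(planted & set(signature))})")
print(f"grade silhouette on signature PCs: {silhouette:.2f}")
print(f"random-forest OOB error on top 25 genes: {oob_error:.1%}")
# The empirical-Bayes moderated test recovers essentially all planted genes
# at FDR 0.05; a silhouette well above 0 means the signature PCs separate
# atypical from benign samples, and the OOB error is the classifier's
# internal estimate of prediction error.
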