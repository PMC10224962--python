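"""Classify the eight call types from their acoustic parameters and test
distinctness against a permutation null.

Pipeline: standardize -> correlation PCA -> keep components with
eigenvalue > 1 -> linear discriminant (equal priors) -> leave-one-out
correct-classification rate (CCR), compared with the CCR distribution under
random call-type label shuffles.
"""

import numpy as np

from dovekie import repertoire, synth

table = synth.sample_feature_table(synth.default_specs(), n_per_type=30,
                                   seed=11)
model = repertoire.fit_pca(table)
print("eigenvalues:", np.round(model.eigenvalues, 2).tolist())
print(f"retained (Kaiser, eigenvalue > 1): {len(model.retained)} components")

result = repertoire.permutation_test(table, n_permutations=200, seed=0)
print(f"\nobserved LOO-CCR:  {result.observed_ccr:.1%}")
print(f"chance level:      {result.chance_expectation:.1%} "
      "(permutation-null mean; 1/8 = 12.5% for a balanced design)")
print(f"p-value:           {result.p_value:.4f}")

print("\nThe observed rate sits far above the ~12.5% null, so the eight "
      "types are acoustically distinct even in synthetic data that carries "
      "only the published per-type parameter distributions.")
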