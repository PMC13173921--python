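"""Simulate a paired training/testing cohort with platform shift.

Builds an RNA-seq-like training cohort (counts) and a microarray-like
test cohort (log2 intensities) sharing one disease signal, and prints
what the ground truth contains.
"""

import numpy as np

from wbtdc import simulate_cohort_pair

train_m, train_p, test_m, test_p, truth = simulate_cohort_pair(seed=7)

print(f"training: {train_m.n_genes} genes x {train_m.n_samples} samples "
      f"({train_m.value_scale})")
print(f"testing:  {test_m.n_genes} genes x {test_m.n_samples} samples "
      f"({test_m.value_scale})")
print(f"DE genes: {len(truth.de_genes_up)} up + {len(truth.de_genes_down)} down")
effects = np.abs(list(truth.effect_sizes.values()))
print(f"|log2 effect| range: {effects.min():.2f} .. {effects.max():.2f}")
print("platform shift:", truth.platform_shift)
# The two cohorts share the disease signal but not the measurement scale:
# per-gene offsets/slopes, a global compression and a detection floor
# distort the test cohort the way an array distorts an RNA-seq signature.
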