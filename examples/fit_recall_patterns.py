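"""Fit the dual-retrieval model to three-test recall pattern counts.

Simulates one condition's item patterns from a known parameter set, fits
the model by maximum likelihood, and prints the estimates next to the
truth together with the G^2(1) goodness-of-fit test.
"""

import numpy as np

from dualrecall import (
    DualRetrievalParams,
    PARAM_NAMES,
    critical_value,
    fit,
    simulate_patterns,
)

truth = DualRetrievalParams.from_array([0.37, 0.06, 0.54, 0.64, 0.84, 0.20])
counts = simulate_patterns(truth, n_items=1600, seed=42)  # 40 participants x 40 words

print("observed pattern counts (EEE..CCC):", counts.counts.tolist())

result = fit(counts, n_starts=20, seed=0)
print(f"\n{'param':>6} {'truth':>7} {'estimate':>9}")
for name, t, e in zip(PARAM_NAMES, truth.to_array(), result.estimates.to_array()):
    print(f"{name:>6} {t:7.3f} {e:9.3f}")
print(
    f"\nG2(1) = {result.g_squared:.3f}, p = {result.p_value:.3f} "
    f"(fit acceptable below the chi-square criterion {critical_value():.2f})"
)
# Estimates within sampling error of the truth and a small G2 indicate the
# six-parameter model reproduces the 8-cell pattern distribution.
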