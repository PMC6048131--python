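"""Expected spectra under selection, dominance and selfing.

The Poisson random field model predicts the expected number of segregating
sites per frequency class.  Purifying selection (gamma = N_e s < 0) removes
variation, recessivity (h < 0.5) hides it from selection in outcrossers, and
full selfing (F = 1) exposes homozygotes so the spectrum becomes independent
of h with selection effectively doubled.
"""

import numpy as np

from domfit import DemographicModel, expected_sfs, selfing_effective_params

dem = DemographicModel()  # constant population size
n, theta = 12, 1.0

neutral = expected_sfs(dem, 0.0, 0.5, 0.0, n, theta)
print("neutral:            ", np.round(neutral.counts, 3), "(theta/i)")

selected = expected_sfs(dem, -5.0, 0.5, 0.0, n, theta)
print("gamma=-5, additive: ", np.round(selected.counts, 3),
      "(variation suppressed)")

recessive = expected_sfs(dem, -5.0, 0.05, 0.0, n, theta)
print("gamma=-5, recessive:", np.round(recessive.counts, 3),
      "(selection hidden in heterozygotes -> more variation)")

selfing = expected_sfs(dem, -5.0, 0.05, 1.0, n, theta)
print("gamma=-5, selfing:  ", np.round(selfing.counts, 3),
      "(h irrelevant at F=1; equals additive at 2*gamma)")
print("selfing effective parameters for s=-0.001:",
      selfing_effective_params(-0.001))
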