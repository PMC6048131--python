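"""Cache a (N_e s, h) spectrum table and integrate a DFE over it.

Fitting requires the expected nonsynonymous SFS for arbitrary DFE and h-s
parameters; precomputing spectra on a coarse (gamma, h) lattice and spline-
refining it makes each likelihood evaluation a cheap 1-D quadrature.
"""

import numpy as np

from domfit import (DemographicModel, GammaDFE, HSRelationship, build_coarse,
                    expected_nonsyn_sfs, refine, theta_nonsyn_from_syn)

dem = DemographicModel()
N_e = 2000.0
coarse = build_coarse(dem, n=12, N_e=N_e, gamma_points=30, h_points=12,
                      pts=300, extrap=False)
fine = refine(coarse, 300, 120)
print(f"coarse {coarse.spectra.shape} -> fine {fine.spectra.shape}")

dfe = GammaDFE(shape=0.3, scale=5e-3 / 0.3)  # mean |s| = 0.005
rel = HSRelationship("inverse", theta_intercept=0.5, theta_rate=4.8e4)
print("h(s) along the DFE: h(-1e-5)=%.3f h(-1e-3)=%.4f h(-1e-2)=%.5f"
      % tuple(rel.h_of_s(np.array([-1e-5, -1e-3, -1e-2]))))

theta_ns = theta_nonsyn_from_syn(100.0)  # theta_S=100 -> theta_NS=231
e = expected_nonsyn_sfs(fine, dfe, rel, N_e, theta_ns)
print("expected nonsynonymous SFS:", np.round(e.counts, 2))
print("(compare the additive model: the recessive h-s relationship retains "
      "more low-frequency variation)")
e_add = expected_nonsyn_sfs(fine, dfe, HSRelationship("additive"), N_e,
                            theta_ns)
print("additive expectation:      ", np.round(e_add.counts, 2))
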