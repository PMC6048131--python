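"""Build, fold, project and serialise site frequency spectra.

A folded SFS records, for each minor-allele count, how many variable sites
were seen at that count.  Folding avoids calling an ancestral allele;
hypergeometric projection reconciles datasets of different sample sizes.
"""

import numpy as np

from domfit import (SpectrumCounts, fold, neutral_spectrum, project,
                    read_spectrum, write_spectrum)

# the equilibrium neutral expectation is theta/i: here theta = 100
syn = neutral_spectrum(26, theta=100.0)
print("unfolded neutral spectrum (first 5):", np.round(syn.counts[:5], 2))

folded = fold(syn)
print("folded to", len(folded), "minor-allele classes; total conserved:",
      round(folded.total(), 2), "=", round(syn.total(), 2))

# 26 sampled allele copies projected down to 22 (13 -> 11 folded entries)
projected = fold(project(syn, 22))
print("projected+folded entries:", len(projected.counts),
      "| still neutral: entry j ~ theta/j + theta/(n-j):",
      np.round(projected.counts[:3], 2))

write_spectrum(projected, "/tmp/example_syn.fs")
back = read_spectrum("/tmp/example_syn.fs")
print("round-tripped through .fs text format, max diff:",
      float(np.max(np.abs(back.counts - projected.counts))))
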