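"""The expression-cost model: why loss-of-function mutations are recessive.

Fitness gains from gene expression saturate while costs grow linearly, so
optimally expressed genes sit on the flat part of the fitness curve: halving
expression (a heterozygous knockout) barely moves fitness, abolishing it (a
homozygous knockout) can move it a lot.  Dominance then falls out of the
fitness curve instead of being a free parameter.
"""

import numpy as np
from scipy.stats import spearmanr

from domfit import GeneExpressionModel, simulate_ensemble

gene = GeneExpressionModel(c=0.001, intercept=0.95, scale=0.1)
x_opt = gene.optimal_expression()
s, h = gene.s_and_h()
print(f"essential-ish gene (intercept 0.95): x_opt = {x_opt:.3f}, "
      f"s = {s:.4f}, h = {h:.4f}  -> strongly recessive")

# ensemble: 5000 genes, intercept ~ U(0.9, 1), scale ~ |N(0.1, 0.1)|
df = simulate_ensemble(n_genes=5000, seed=7)
kept = df[df.s < 0].dropna(subset=["h"])
rho, _ = spearmanr(-kept.s, kept.h)
print(f"{len(kept)} genes with a positive expression optimum;"
      f" all h < 0.5: {bool((kept.h < 0.5).all())}")
print(f"Spearman correlation of |s| with h: {rho:.3f} "
      "(more deleterious -> more recessive)")
for scale in (0.03, 0.1, 0.3):
    hs = [GeneExpressionModel(0.001, i, scale).s_and_h()[1]
          for i in np.linspace(0.9, 0.99, 20)]
    print(f"scale {scale:4.2f}: mean h = {np.mean(hs):.4f}")
print("(genes needing many molecules -> larger scale -> more additive, the "
      "pattern seen for highly expressed / highly connected genes)")
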