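"""Downstream analyses: three-layer network topology and rewiring.

Assembles a toy modulator -> TF -> target network, reports per-role counts,
degrees and TF-core betweenness, then runs the context-specific rewiring
analysis on a gated pair: samples are binned by the modulator's expression,
the pair's Pearson correlation is computed per bin, bins are categorised
low/high by 1-D 2-means, and a permutation test scores the modulator's
effect.
"""

import numpy as np

from tfanet import (
    ExpressionMatrix,
    ModulationTriplet,
    RegulatoryPair,
    assemble_three_layer,
    degree_summary,
    generate_modulated_triplet,
    node_betweenness,
    rewiring_analysis,
)

pairs = [RegulatoryPair("TF1", "TF2", 0.6, 1e-5),
         RegulatoryPair("TF2", "TG1", 0.5, 1e-5),
         RegulatoryPair("TF2", "TG2", 0.4, 1e-5)]
trips = [ModulationTriplet("MOD1", "TF2", "TG1", 0.1, 0.5, 0.001)]
net = assemble_three_layer(pairs, trips)
print("network summary:", net.summary())
print("TF out-degrees:", {t: degree_summary(net)["per_node"][t]["out_regulation"]
                          for t in sorted(net.tfs)})
print("betweenness:", {k: v for k, v in node_betweenness(net).items() if v > 0})

m, x, y = generate_modulated_triplet(600, gate_strength=1.5, noise_sd=0.2,
                                     seed=5)
expr = ExpressionMatrix(["GENE_A", "GENE_B", "MOD"],
                        [f"S{j}" for j in range(600)], np.vstack([x, y, m]))
res = rewiring_analysis(expr, "GENE_A", "GENE_B", "MOD", n_bins=10,
                        n_perm=2000, seed=6)
print("per-bin PCC (sorted by modulator):",
      np.round(res.pcc_per_bin, 2).tolist())
print("bin categories:", res.category_per_bin)
print(f"CMI = {res.cmi:.3f}, permutation p = {res.p_value:.4g}")
print("Correlation switches on only in the high-modulator bins: the pair "
      "is rewired by the modulator's context.")
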