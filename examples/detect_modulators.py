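"""Step 2: conditional-mutual-information modulator detection.

Simulates a modulator-gated pair (the TF drives its target only when the
modulator is highly expressed), computes the MI on the bottom-35% and
top-35% modulator splits, their difference (the CMI), and a permutation
p-value. A large positive CMI with a small p-value is the signature of a
modulator.
"""

from tfanet import conditional_mi, generate_modulated_triplet, permutation_pvalue

m, x, y = generate_modulated_triplet(M_samples=500, gate_strength=1.0,
                                     noise_sd=0.3, seed=42)
mi_low, mi_high, cmi = conditional_mi(x, y, m, fraction=0.35)
p = permutation_pvalue(x, y, m, n_perm=1000, seed=7)

print(f"MI(TF, target | modulator low)  = {mi_low:.3f} nats")
print(f"MI(TF, target | modulator high) = {mi_high:.3f} nats")
print(f"CMI = MI_high - MI_low          = {cmi:.3f} nats")
print(f"permutation p-value (1000 perms) = {p:.4g}")
print("The TF-target dependency exists only in the high-modulator samples, "
      "so the CMI is large and the permutation test rejects the no-"
      "modulation null (minimum attainable p is 1/1001).")
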