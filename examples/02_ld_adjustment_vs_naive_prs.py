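"""Why adjust for LD?  A naive PRS double-counts correlated SNPs.

We simulate one gene of 6 SNPs in strong LD (rho = 0.9) where only the
first SNP is causal.  The discovery scan then hands back a *marginal*
effect for every SNP — the causal signal leaks into all of its LD
partners.  A naive PRS sums all six marginal effects and so counts the
same signal repeatedly; the LD-adjusted weights w = Q(L + kI)^-1 Q'beta
divide the signal among the correlated SNPs instead.

The printout shows (a) marginal betas that are all inflated away from the
truth, (b) adjusted weights concentrated near the causal SNP, and (c) the
correlation of each score with the true causal genotype — both scores
track the signal, but the naive score has a larger variance for the same
signal because of the double counting.
"""

import numpy as np

from polaris import synthetic_data as synth
from polaris.polaris_core import ld_correlation, polaris_score, polaris_weights

cfg = synth.SimConfig(
    seed=7,
    n_target=2000,
    n_discovery=8000,
    blocks=[synth.LDBlockSpec(6, 0.9)],
    causal=[synth.CausalGeneSpec(0, 1, 0.4)],  # only SNP 1 of the block is causal
    fst=0.0, pc_liability=0.0, dosage_noise=0.0,
    include_overlap_gene=False, include_filtered_genes=False,
)

# discovery cohort -> marginal per-SNP effects
gm_d = synth.simulate_genotypes(cfg, "discovery")
cov_d = synth.simulate_phenotypes(gm_d, cfg, "discovery")
ss = synth.make_discovery_summary_stats(gm_d, cov_d)
betas = ss.table["beta"].to_numpy()

# target cohort -> LD estimate and scores
gm = synth.simulate_genotypes(cfg, "target")
ids = gm.variant_ids()
ld = ld_correlation(gm, ids)
w = polaris_weights(ld, betas, k=1.0)

print("SNP-to-causal-SNP LD (r with rs000001):",
      np.round(ld.R[0], 2))
print()
print(f"{'SNP':>10} {'marginal beta':>14} {'adjusted weight':>16}")
for vid, b, wj in zip(ids, betas, w):
    print(f"{vid:>10} {b:>14.3f} {wj:>16.3f}")

g = gm.calls.astype(float)
gc = g - g.mean(axis=0)
naive = gc @ betas                                   # classical centered PRS
adjusted = polaris_score(gm, ids, w).scores          # LD-adjusted gene score
causal = gc[:, 0]

print()
print(f"corr(naive PRS,    causal genotype) = {np.corrcoef(naive, causal)[0, 1]:.3f}")
print(f"corr(adjusted,     causal genotype) = {np.corrcoef(adjusted, causal)[0, 1]:.3f}")
print(f"sd(naive)/sd(adjusted)              = {naive.std() / adjusted.std():.2f}")
print()
print("The marginal betas are all of similar size (LD leakage), while the")
print("adjusted weights shrink the redundant SNPs toward zero; the naive")
print("score inflates its scale by re-counting the same signal.")
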