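"""Serial-founder chain simulation and its expected signatures.

A west-to-east chain of haploid demes is colonized by successive founder
events; microsatellites mutate stepwise at motif-dependent rates and the
two SNPs arise (at most once each) on the expansion front.  Averaged
over replicate chains, the between-end-deme Dad statistic orders by
motif mutability and derived SNP frequency climbs eastward.
"""

import numpy as np
from scipy.stats import spearmanr

from ychap import SimConfig, dad_statistic, haplotype_diversity, simulate_founder_chain

one, hist = simulate_founder_chain(SimConfig(seed=4))
print(f"single chain (seed 4): {one.k} haplotypes over {one.n} males in "
      f"{len(one.counts.columns)} demes")
print("per-deme haplotype diversity of this one realization (drift and "
      "founder events make single chains noisy):")
for deme in one.counts.columns:
    print(f"  {deme}: h = {haplotype_diversity(one, deme).h:.2f}")

n_reps = 50
dads, clines = [], []
for seed in range(n_reps):
    table, history = simulate_founder_chain(SimConfig(seed=seed))
    d = dad_statistic(table, "deme01", "deme12").differences
    dads.append([d["penta"], d["tri"], d["mono"]])
    clines.append(
        [
            history["derived_freq"][f"deme{i + 1:02d}"]["sry_snp"]
            + history["derived_freq"][f"deme{i + 1:02d}"]["str_snp"]
            for i in range(12)
        ]
    )
mean_dad = np.asarray(dads).mean(axis=0)
print(f"\nmean end-deme Dad over {n_reps} chains: "
      f"penta {mean_dad[0]:.2f}, tri {mean_dad[1]:.2f}, mono {mean_dad[2]:.2f}")
print("  -> ordered by motif mutability, as in the empirical table")

mean_cline = np.asarray(clines).mean(axis=0)
rho, p = spearmanr(range(12), mean_cline)
print(f"mean derived-SNP frequency by deme: {np.round(mean_cline, 3)}")
print(f"west-to-east cline rank correlation: rho = {rho:.2f} (p = {p:.1g})")
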