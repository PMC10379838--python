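"""Founder-effect simulation: drift law and detection power.

Shows (1) the closed-form two-stage variance of a destination haplotype
frequency, p(1-p)(1/n_founders + 1/n_sampled), against simulation, and
(2) how the power of the regional M comparison falls as migrating groups
get larger, vanishing to the alpha level when migration is massive.
"""

import numpy as np

import haplomig as hm

src = hm.SourcePopulation()
p = src.coib_freqs[hm.FOCAL_HAPLOTYPE]
print(f"source frequency of the focal haplotype: {p}")
print("\nfounder size | simulated var | closed form  (n_sampled = 50)")
for nf in (50, 500):
    scn = hm.MigrationScenario(source=src, n_founders=nf, n_sampled=50)
    freqs = hm.simulate_destination_frequencies(
        scn, 20_000, np.random.default_rng(nf))
    theory = hm.founder_variance(p, nf, 50)
    print(f"{nf:12d} | {freqs.var(ddof=1):.6f}      | {theory:.6f}")

grid = hm.run_power_analysis([5, 50, 500, 100_000], replicates=300,
                             alpha=0.05, seed=7)
print("\nrejection rate of the North/South M comparison "
      "(north = one founder wave per study):")
print(grid.table[["founder_size", "rejection_rate",
                  "m_sd_destination"]].to_string(index=False))
print("\nAt founder size 5 the regional test detects drift in most "
      "studies; at 100000 founders drift is negligible and the rate is "
      "the nominal 5% false-positive level.")
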