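"""Locus-specific F_ST and recovery of a known divergence parameter.

F_ST at a SNP is the variance of the per-population allele frequencies
divided by its maximum possible value under the pooled frequency.  For
two populations drawn around shared ancestral frequencies with
Balding-Nichols inflation F, the mean locus F_ST sits near F/2; the
moment inversion F = 2R/(1+R) recovers the simulation parameter.
"""

import numpy as np

from haplosweep import differentiation as diff

print("locus F_ST examples:")
for freqs in ([0.3, 0.3], [0.8, 0.3], [1.0, 0.0]):
    print(f"  frequencies {freqs} -> F_ST = {diff.locus_fst(freqs):.4f}")

print("\nBalding-Nichols recovery (1,000 loci, 2 populations):")
rng = np.random.default_rng(2)
for F in (0.01, 0.05, 0.1):
    p = rng.uniform(0.1, 0.9, 1000)
    scale = (1 - F) / F
    q = rng.beta(p * scale, (1 - p) * scale, size=(2, 1000))
    mean_fst = float(np.mean([diff.locus_fst(q[:, i]) for i in range(1000)]))
    estimate = diff.divergence_estimate(mean_fst, 2)
    print(
        f"  true F {F:.2f}: mean locus F_ST {mean_fst:.4f}, "
        f"recovered F {estimate:.4f}"
    )

print(
    "\nThe raw mean halves the two-population divergence parameter; the "
    "inversion corrects for that and lands within Monte-Carlo error of F."
)
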