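"""Closed-form theory of F2-family pool genotypes.

An F2 family from a pair cross carries four parental allele copies, so its
"pool genotype" is an allele frequency in quarters.  This script prints the
pool-genotype distribution, the mating table it derives from, the genetic
variances on the individual and pool scales, and the sequencing-noise /
attenuation quantities at a few depths.
"""

import numpy as np

from poolassoc import (
    LocusModel,
    attenuation_factor,
    binomial_noise_variance,
    explained_variance,
    genetic_variance_individual,
    genetic_variance_pool,
    mating_table,
    poisson_missing_prob,
    pool_genotype_probs,
)

p = 0.3
model = LocusModel(p=p, b=1.0, sigma_e=4.0)

dist = pool_genotype_probs(p)
print(f"Pool-frequency distribution at parental allele frequency p={p}:")
for freq, prob in zip(dist.support, dist.probs):
    print(f"  g_F2 = {freq:4.2f}: {prob:.4f}")
print("  (probabilities of the five family types; they sum to 1)\n")

print("Mating table (aggregating by pool frequency gives the same distribution):")
for row in mating_table(p):
    print(f"  {row.mating:8s} freq={row.mating_freq:.4f} -> pool freq {row.pool_freq}")

v_ind = genetic_variance_individual(model)
v_pool, v_freq = genetic_variance_pool(model)
print(f"\nGenetic variance, individuals: {v_ind:.4f}  (2p(1-p)a^2)")
print(f"Genetic variance, pools:       {v_pool:.4f}  (half of the individual one)")
print(f"Pool-frequency variance:       {v_freq:.4f}  (p(1-p)/4)")
print(f"Explained variance at sigma_e=4: {explained_variance(model):.4f}")
print("  (the tiny fraction of phenotypic variance one locus explains)\n")

print("Sequencing depth -> noise variance and slope attenuation:")
for depth in (3, 7, 15, 30):
    print(
        f"  S_T={depth:2d}: noise var {binomial_noise_variance(p, depth):.5f}, "
        f"slope shrinks to {attenuation_factor(depth):.3f} of its true value"
    )
print("\nZero-read (missing family) probability under Poisson depth:")
for lam in (5, 6, 7):
    print(f"  mean depth {lam}: {100 * poisson_missing_prob(lam):.1f} %")
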