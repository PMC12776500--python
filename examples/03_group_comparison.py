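"""Compare two genotype groups with the Wasserstein-ratio permutation test.

Builds a cohort of 4 wild-type-like and 4 mutant-like embryos (higher
orientation noise in the mutant), summarizes GOA per embryo and tests the
group difference with the ratio of between-group to within-group pairwise
1-D Wasserstein distances, permuting labels over embryos.
"""

import numpy as np

from misalign import EmbryoSample, angular_difference, permutation_test, sample_orientations

rng = np.random.default_rng(7)
AXIS = 90.0

samples = []
for group, sigma in (("wt", 10.0), ("mut", 25.0)):
    for e in range(1, 5):
        theta = sample_orientations(400, "wrapped_normal", AXIS, sigma, rng)
        goa = angular_difference(theta, AXIS)
        samples.append(EmbryoSample(f"{group}-emb{e}", group, "tibia", goa))
        print(f"{group}-emb{e}: median GOA = {np.median(goa):5.2f} deg")

result = permutation_test(samples, n_permutations=999, seed=1)
print(
    f"\nWasserstein-ratio statistic = {result.statistic:.2f} "
    f"(between-group / within-group mean pairwise distance)"
)
print(
    f"p = {result.p_value:.4f} over {result.n_permutations} "
    f"{'exhaustive' if result.exhaustive else 'random'} relabelings"
)
print(
    "\nA ratio near 1 would mean the genotypes differ no more than embryos\n"
    "within a genotype do; here the broader mutant GOA distributions drive\n"
    "the ratio well above 1. The embryo is the exchangeable unit, so cells\n"
    "are never pseudoreplicated."
)
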