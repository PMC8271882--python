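"""Why a joint-distribution metric: identical marginals, opposite coupling.

Draws paired samples (X, Y) with Y = +X for one law and Y = -X for the
other. Both laws have standard-normal marginals in each coordinate, so the
marginal MMD on either coordinate cannot separate them — but the tensor-
space joint metric can.
"""

import numpy as np

from ehecco import WeightedSampleSet, ehecco_squared, median_heuristic_bandwidth, mmd_squared

rng = np.random.default_rng(0)
n = 200
x1, x2, x3 = (rng.normal(size=(n, 1)) for _ in range(3))

same_a = WeightedSampleSet(primary=x1, latent=+x1)   # law A, replicate 1
same_b = WeightedSampleSet(primary=x2, latent=+x2)   # law A, replicate 2
opposite = WeightedSampleSet(primary=x3, latent=-x3)  # law B

sigma = median_heuristic_bandwidth(np.vstack([x1, x2, x3]))

within = ehecco_squared(same_a, same_b, sigma, sigma)
between = ehecco_squared(same_a, opposite, sigma, sigma)
mmd_marginal = mmd_squared(x1, x3, sigma)

print(f"joint distance^2, same law        : {within:.5f}")
print(f"joint distance^2, opposite coupling: {between:.5f}")
print(f"marginal MMD^2 on X alone          : {mmd_marginal:.5f}")
print()
print("The joint metric separates the two laws by an order of magnitude")
print("while the marginal MMD sees only sampling noise: the difference")
print("lives entirely in the dependence between the two coordinates.")
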