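"""Choose delay-embedding parameters for a chaotic flow.

Generates the canonical Lorenz benchmark (250 s of the X component at
40 Hz), picks the embedding delay from the first minimum of the auto-mutual
information and the dimension from the false-nearest-neighbor drop, and
cross-checks with the stochastic (Ragwitz) route on an AR(1) series.
"""

import numpy as np

import nlts

ts, _ = nlts.generate_lorenz(nlts.LorenzParams(seed=1))

ami, tau = nlts.auto_mutual_information(ts, max_lag=50)
print(f"first AMI minimum at lag {tau} samples "
      f"({tau / ts.fs * 1000:.0f} ms): the delay at which successive "
      "coordinates become maximally independent")

fracs, dim = nlts.false_nearest_neighbors(ts, tau=tau)
print("FNN fraction per dimension:",
      ", ".join(f"{d}: {f:.1%}" for d, f in enumerate(fracs, start=1)))
print(f"suggested embedding dimension: {dim} "
      "(lowest dimension whose false-neighbor fraction falls below 1%)")

# A stochastic signal is better served by the prediction-error criterion:
rng = np.random.default_rng(3)
x = np.zeros(5000)
for i in range(1, x.size):
    x[i] = 0.8 * x[i - 1] + rng.standard_normal()
_, _, _, (d_opt, tau_opt) = nlts.ragwitz_optimize(x, dims=range(1, 5),
                                                  taus=(1, 2, 3), k=50)
print(f"Ragwitz optimum for an AR(1) process: dim={d_opt}, tau={tau_opt} "
      "(one-step memory correctly identified)")
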