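"""Dynamic invariants of the Lorenz attractor.

Estimates the correlation dimension (Grassberger-Procaccia) and the largest
Lyapunov exponent (Kantz) from a delay embedding of the X component alone,
and compares them with the known values D2 ~ 2.05 and lambda ~ 0.91 / s.
"""

import numpy as np

import nlts
from nlts import EmbeddingSpec, delay_embed

ts, _ = nlts.generate_lorenz(nlts.LorenzParams(seed=1))

d2s = []
for dim in (3, 5, 7, 9):
    ps = delay_embed(ts, EmbeddingSpec(dim, 8))
    curve = nlts.correlation_sum(ps, theiler=20)
    d2s.append(nlts.correlation_dimension(curve)[dim])
    print(f"dim {dim}: D2 = {d2s[-1]:.3f}")
print(f"plateau D2 = {np.median(d2s):.2f}  (fractal dimension of the "
      "attractor; invariance across embedding dimensions signals determinism)")

ps = delay_embed(ts, EmbeddingSpec(3, 8))
curve = nlts.lyapunov_curve(ps, "kantz", epsilon=0.005 * ps.diameter(),
                            iterations=120, theiler=20, max_references=3000)
nlts.lyapunov_fit(curve, (24, 120))
print(f"largest Lyapunov exponent = {curve.lam_per_second:.3f} / s "
      "(positive: nearby states diverge exponentially - chaos)")

scales, F, alpha = nlts.dfa(ts)
print(f"DFA scaling exponent alpha = {alpha:.2f} "
      "(long-range correlation strength of the raw signal)")
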