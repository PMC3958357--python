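"""Perturbation robustness of a community solution vs a random graph.

Rewires increasing fractions of edges (degree-preserving double-edge
swaps), re-runs community detection, and measures variation of
information (VI) from the original partition.  A genuine community
structure stays flat under light perturbation; a size-matched random
graph falls apart immediately.
"""

import numpy as np

from gimmesub import random_baseline, robustness_curve
from gimmesub.modularity import modularity_partition
from gimmesub.subgroups import _modal_partition

rng = np.random.default_rng(0)

# a two-block network: 2 communities of 15, dense within, sparse between
n = 30
A = (np.random.default_rng(1).random((n, n)) < 0.1).astype(np.int8)
A[:15, :15] = 1
A[15:, 15:] = 1
A = np.triu(A, 1)
A = A + A.T

original = _modal_partition([modularity_partition(A, rng) for _ in range(100)])
levels = np.array([0.0, 0.05, 0.1, 0.2, 0.5, 1.0])
curve = robustness_curve(A, original, rng=rng, levels=levels, reps=20,
                         detection_runs=20)

B = random_baseline(A, rng)
orig_b = _modal_partition([modularity_partition(B, rng) for _ in range(100)])
curve_b = robustness_curve(B, orig_b, rng=rng, levels=levels, reps=20,
                           detection_runs=20, is_random_baseline=True)

print("level   VI(structured)  VI(random)   %changed(structured)")
for lv, v, vb, f in zip(levels, curve.vi_mean, curve_b.vi_mean,
                        curve.frac_changed_mean):
    print(f" {lv:4.2f}      {v:6.3f}        {vb:6.3f}         {100 * f:5.1f}%")
print("-> VI in bits; the structured network stays put under light")
print("   perturbation (and degrades once its blocks are destroyed),")
print("   while the degree-matched random graph reorganizes immediately.")
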