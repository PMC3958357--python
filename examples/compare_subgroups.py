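"""Compare connection weights across detected subgroups with FDR control.

Each subgroup's mean beta on every group path is contrasted against the
pooled mean of the other subgroups (two-sample t), with Storey q-values
controlling the false discovery rate across all contrasts at alpha=.05.
"""

import numpy as np

from gimmesub import compare_subgroup_paths, diagnostic_comparison

rng = np.random.default_rng(0)

# 3 subgroups of 20; subgroup 0 runs high on path 0, subgroup 2 low on path 4
betas = 0.5 + rng.normal(0, 0.05, size=(60, 6))
labels = np.repeat([0, 1, 2], 20)
betas[labels == 0, 0] += 0.2
betas[labels == 2, 4] -= 0.2

table = compare_subgroup_paths(betas, labels, alpha=0.05)
sig = table.contrasts[table.contrasts["verdict"] != "similar"]
print("significant subgroup-vs-rest contrasts (q <= .05):")
print(sig[["path", "subgroup", "subgroup_mean", "others_mean",
           "q_value", "verdict"]].to_string(index=False))

# the traditional two-group comparison misses structure that cuts across
# an arbitrary binary label
arbitrary = rng.integers(0, 2, size=60)
diag = diagnostic_comparison(betas, arbitrary)
print(f"\ntwo-group comparison on an arbitrary binary label: "
      f"{int(diag['significant'].sum())} significant paths")
print("-> subgroup-blind comparisons wash out differences that the")
print("   data-driven subgroups isolate.")
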