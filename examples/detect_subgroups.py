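"""Data-driven subgroup detection from connectivity betas.

Builds an inter-individual similarity network from two noisy beta
profiles, scans binarization thresholds r = 0...1, selects the most
stable threshold before the reachability drop, and reports the detected
communities.
"""

import numpy as np

from gimmesub import detect_subgroups_from_betas, matched_accuracy

rng = np.random.default_rng(0)

# two subgroups with distinct 9-path beta profiles (+/-0.2 deviations)
profile_a = np.array([0.7, 0.3, 0.7, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5])
profile_b = np.array([0.5, 0.5, 0.5, 0.5, 0.3, 0.7, 0.3, 0.5, 0.5])
betas = np.vstack([profile_a + rng.normal(0, 0.04, 9) for _ in range(15)]
                  + [profile_b + rng.normal(0, 0.04, 9) for _ in range(15)])
true_labels = np.repeat([0, 1], 15)

partition, scan, net = detect_subgroups_from_betas(betas, rng=rng)

print(f"selected threshold r* = {scan.selected_r:.2f} "
      f"(reachability drops at r = {scan.grid[scan.drop_index]:.2f})")
print(f"modularity Q = {partition.Q:.3f}, "
      f"{partition.n_communities} communities of sizes "
      f"{np.bincount(partition.canonical()).tolist()}")
print(f"accuracy vs ground truth: "
      f"{100 * matched_accuracy(true_labels, partition.labels):.1f}%")
print("-> r* is the densest similarity cutoff at which 100 repeated")
print("   modularity runs agree perfectly (std(Q) = 0).")
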