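"""Simulate a subgroup-structured panel and recover its connectivity maps.

Generates 24 individuals (2 subgroups) of 10-ROI time series from the
structural-VAR design, runs the GIMME group+individual search, and
reports which directed paths were recovered.
"""

import numpy as np

from gimmesub import (SimulationDesign, connection_recovery, generate_panel,
                      run_gimme)

design = SimulationDesign(
    n_individuals=24, n_subgroups=2, n_timepoints=150,
    unique_paths=[(5, 0), (6, 1)], seed=1,
)
panel, truth = generate_panel(design)
maps = run_gimme(panel)

print("group-level contemporaneous paths (source -> target):")
for i, j in maps.group.contemporaneous_paths():
    print(f"  ROI{j} -> ROI{i}")
print(f"autoregressive paths freed for all ROIs: "
      f"{int(np.diag(maps.group.group_Phi).sum())}/10")

extras = [int(im.indiv_A.sum() + im.indiv_Phi.sum()) for im in maps.individuals]
print(f"individual-level paths per person: mean {np.mean(extras):.2f} "
      f"(these absorb the subgroup-unique connections)")

rec = connection_recovery(maps, truth)
print(f"connection recovery (presence + direction): {100 * rec:.2f}%")
print("-> of all true directed paths across individuals, this fraction")
print("   appears in the fitted maps with the correct direction.")
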