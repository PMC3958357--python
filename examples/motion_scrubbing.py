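"""Framewise-displacement scrubbing of a motion-contaminated series.

Computes FD from 6 rigid-body realignment parameters, replaces frames
with FD > 0.2 mm by missing-value placeholder rows (temporal order is
retained), and shows how the lag embedding drops pairs spanning them.
"""

import numpy as np

from gimmesub import compute_fd, scrub_frames
from gimmesub.usem import embed_lag

rng = np.random.default_rng(0)
T = 120

realign = np.cumsum(rng.normal(0, 0.02, size=(T, 6)), axis=0)
realign[40] += 0.5   # a head jerk at frame 40
realign[41] -= 0.3

fd = compute_fd(realign)
print(f"FD: median {np.median(fd):.3f} mm, max {fd.max():.3f} mm, "
      f"{int((fd > 0.2).sum())} frames above 0.2 mm")

series = rng.normal(size=(T, 5))
scrubbed = scrub_frames(series, fd, threshold=0.2)
n_scrubbed = int(np.isnan(scrubbed).any(axis=1).sum())
pairs, n_used = embed_lag(scrubbed)
print(f"scrubbed {n_scrubbed} frames -> {n_used} usable lag-1 pairs "
      f"(complete series would give {T - 1})")
print("-> each scrubbed frame removes the two transitions that span it,")
print("   but the remaining scan order is preserved for the lagged model.")
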