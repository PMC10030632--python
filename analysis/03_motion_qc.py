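#!/usr/bin/env python
"""Motion quality control on simulated scan sessions.

Children move more than adults in the scanner; here each simulated child
receives more motion spikes than each adult. Framewise displacement sums
absolute translation differences with 50 mm arc-length-converted rotation
differences, and exceedances of the 0.5 mm threshold are counted.
Writes results/motion_qc.csv.
"""

import numpy as np
import pandas as pd

from retmap.qc import count_exceedances, framewise_displacement
from retmap.synth import simulate_motion

N_VOLUMES = 384  # four runs of 96 volumes
rng = np.random.default_rng(0)
rows = []
for group, lam in [("adult-like", 1.0), ("child-like", 10.5)]:
    for i in range(12):
        n_spikes = int(rng.poisson(lam))
        frames = sorted(
            rng.choice(np.arange(1, N_VOLUMES), size=n_spikes, replace=False)
        )
        trace = simulate_motion(
            N_VOLUMES, spike_frames=frames, spike_mm=0.6,
            jitter_sd=0.02, seed=100 + i,
        )
        fd = framewise_displacement(trace)
        rows.append(
            {
                "group": group,
                "subject": f"{group}-{i:02d}",
                "spikes_injected": n_spikes,
                "fd_exceedances": count_exceedances(fd),
                "fd_median_mm": float(np.median(fd.fd)),
            }
        )
df = pd.DataFrame(rows)
df.to_csv("results/motion_qc.csv", index=False)
print(df.groupby("group")[["fd_exceedances", "fd_median_mm"]].median())
print("\nevery injected spike is recovered:",
      bool((df.spikes_injected == df.fd_exceedances).all()))
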