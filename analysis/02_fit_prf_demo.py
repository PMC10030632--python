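#!/usr/bin/env python
"""Fit the pRF model to simulated vertex time series and report recovery.

Simulates BOLD responses for 40 V1 vertices of a synthetic hemisphere at a
noise level calibrated to median R^2 ~ 0.6 (the regime of good retinotopy
data), runs the four-stage coarse-to-fine fit, and tabulates parameter
recovery. Writes results/prf_recovery.csv.
"""

import numpy as np

from retmap.io import fits_to_frame
from retmap.prf import fit_prf_many
from retmap.stimulus import ApertureConfig, downsample_to_tr, make_bar_aperture
from retmap.synth import GroundTruthConfig, build_hemisphere, noise_sd_for_r2, simulate_bold

movie = downsample_to_tr(make_bar_aperture(ApertureConfig()))
hemi = build_hemisphere(GroundTruthConfig(seed=0))
ecc = hemi.retinotopy.ecc
v1 = hemi.labels["V1"]
pool = v1[(ecc[v1] >= 0.5) & (ecc[v1] <= 5.5)]
rng = np.random.default_rng(0)
ids = rng.choice(pool, size=40, replace=False)

data = simulate_bold(
    hemi.mesh, hemi.retinotopy, movie,
    noise_sd=noise_sd_for_r2(0.6), seed=1, vertex_ids=ids,
)
fits = fit_prf_many(data, movie)
df = fits_to_frame(fits)
df["vertex_id"] = ids
df["true_x"] = hemi.retinotopy.x[ids]
df["true_y"] = hemi.retinotopy.y[ids]
df["true_sigma"] = hemi.retinotopy.sigma[ids]
df.to_csv("results/prf_recovery.csv", index=False)

dx = np.abs(df.x - df.true_x)
dy = np.abs(df.y - df.true_y)
ds = np.abs(df.sigma / df.true_sigma - 1)
print(f"fitted {len(df)} vertices at noise calibrated to R^2 = 0.6")
print(f"median |dx| = {dx.median():.3f} deg   median |dy| = {dy.median():.3f} deg")
print(f"median sigma error = {100 * ds.median():.1f}%")
print(f"median R^2 = {df.r2.median():.2f}  (map threshold for boundary use: 0.10)")
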