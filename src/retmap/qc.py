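"""Motion and data-quality summaries.

Framewise displacement (FD) condenses six rigid-motion parameters into one
mm-scale scalar per frame transition: the sum of absolute framewise
translation differences over the three axes plus the arc-length-converted
absolute rotation differences, using a 50 mm head radius for the
degrees-to-mm conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synth import MotionTrace, VertexRetinotopy

__all__ = [
    "FdSeries",
    "framewise_displacement",
    "count_exceedances",
    "median_map_r2",
    "hemisphere_symmetry",
]

HEAD_RADIUS_MM = 50.0
FD_THRESHOLD_MM = 0.5


@dataclass
class FdSeries:
    fd: np.ndarray  # mm, length n_frames - 1
    threshold: float = FD_THRESHOLD_MM
    head_radius: float = HEAD_RADIUS_MM


def framewise_displacement(
    trace: MotionTrace,
    head_radius: float = HEAD_RADIUS_MM,
    rotation_units: str = "degrees",
) -> FdSeries:
    """FD_t = sum |delta translation| + sum |r * (pi/180) * delta rotation|.

    Rotations are taken in degrees by default and converted to arc length at
    ``head_radius``; pass ``rotation_units='radians'`` for traces already in
    radians (converted via r * delta).
    """
    t = np.asarray(trace.translations, dtype=float)
    r = np.asarray(trace.rotations, dtype=float)
    if t.shape[0] < 2:
        return FdSeries(fd=np.zeros(0), head_radius=head_radius)
    dt = np.abs(np.diff(t, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(r, axis=0))
    if rotation_units == "degrees":
        arc = head_radius * (np.pi / 180.0) * dr
    elif rotation_units == "radians":
        arc = head_radius * dr
    else:
        raise ValueError("rotation_units must be 'degrees' or 'radians'")
    return FdSeries(fd=dt + arc.sum(axis=1), head_radius=head_radius)


def count_exceedances(fd: FdSeries, threshold: float = FD_THRESHOLD_MM) -> int:
    """Number of frame transitions whose FD strictly exceeds the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return int(np.sum(fd.fd > threshold))


def median_map_r2(retinotopy: VertexRetinotopy, roi: np.ndarray) -> float:
    """Median variance explained over an ROI's vertices."""
    roi = np.asarray(roi)
    if roi.size == 0:
        raise ValueError("roi must be nonempty")
    return float(np.median(retinotopy.r2[roi]))


def hemisphere_symmetry(
    areas_lh: np.ndarray, areas_rh: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation (two-tailed) between per-subject left- and
    right-hemisphere map surface areas. Returns (r, p)."""
    a = np.asarray(areas_lh, dtype=float)
    b = np.asarray(areas_rh, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
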