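"""Areal cortical magnification as a function of eccentricity.

m(r) is measured with an adaptive annulus: at each sample eccentricity r the
half-width delta_r is grown until the annulus [r - delta_r, r + delta_r]
captures 20% of the ROI's vertices; the summed vertex surface area is then
divided by the visual-field area of the annulus (scaled by the fraction of
the field the hemisphere represents). The Horton-Hoyt law
M(E) = (scale/(E + e0))^2 serves as the adult reference curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synth import SurfaceMesh

__all__ = [
    "CMagCurve",
    "areal_cmag",
    "horton_hoyt_areal",
    "fraction_within",
    "HH_SCALE",
    "HH_E0",
]

HH_SCALE = 17.3  # mm
HH_E0 = 0.75  # deg


@dataclass
class CMagCurve:
    r: np.ndarray  # deg
    m: np.ndarray  # mm^2 / deg^2
    delta_r: np.ndarray  # deg, adaptive half-width per sample


def areal_cmag(
    mesh: SurfaceMesh,
    ecc: np.ndarray,
    roi: np.ndarray,
    r_grid: np.ndarray | None = None,
    vertex_fraction: float = 0.2,
    hemifield_fraction: float = 0.5,
    depth: str = "midgray",
) -> CMagCurve:
    """Adaptive-annulus areal magnification curve over an ROI.

    ``ecc`` is per-vertex eccentricity (fitted or ground truth); the 20%
    count weights vertices equally. Annuli extending below 0 deg are clipped
    (with a warning); the hemifield fraction scales the annulus visual area
    to the part of the field the hemisphere represents.
    """
    roi = np.asarray(roi, dtype=int)
    if roi.size == 0:
        raise ValueError("roi is empty")
    r_grid = np.arange(1.0, 7.0 + 1e-9, 0.25) if r_grid is None else np.asarray(r_grid)
    e = np.asarray(ecc, dtype=float)[roi]
    areas = mesh.vertex_area[depth][roi]
    k = max(1, int(np.ceil(vertex_fraction * roi.size)))

    m = np.empty_like(r_grid)
    dr = np.empty_like(r_grid)
    clipped = False
    for i, r in enumerate(r_grid):
        dist = np.abs(e - r)
        ordered = np.sort(dist)
        dk = ordered[k - 1]
        # place the ring boundary midway between the k-th included distance
        # and the next distinct one, so it falls between sample
        # eccentricities rather than exactly on one (unbiased when the map
        # is discretized; identical in the continuous limit)
        larger = ordered[ordered > dk + 1e-12]
        delta = (dk + larger[0]) / 2.0 if larger.size else dk
        inner = r - delta
        if inner < 0:
            clipped = True
            inner = 0.0
        ring_deg2 = np.pi * ((r + delta) ** 2 - inner**2) * hemifield_fraction
        m[i] = areas[dist <= delta].sum() / ring_deg2
        dr[i] = delta
    if clipped:
        warnings.warn("annulus clipped at 0 deg eccentricity", RuntimeWarning)
    return CMagCurve(r=r_grid, m=m, delta_r=dr)


def horton_hoyt_areal(
    E: np.ndarray | float, scale: float = HH_SCALE, e0: float = HH_E0
) -> np.ndarray | float:
    """Areal magnification (scale/(E + e0))^2 in mm^2/deg^2."""
    E = np.asarray(E, dtype=float)
    if np.any(E + e0 <= 0):
        raise ValueError("E + e0 must be positive")
    out = (scale / (E + e0)) ** 2
    return float(out) if out.ndim == 0 else out


def _area_integral(E: float, e0: float) -> float:
    """Antiderivative of E/(E+e0)^2 evaluated at E (constant dropped)."""
    return np.log(E + e0) + e0 / (E + e0)


def fraction_within(
    E_max: float,
    E_full: float = 90.0,
    scale: float = HH_SCALE,
    e0: float = HH_E0,
) -> float:
    """Fraction of total map surface area within E_max, per the areal law.

    Uses the closed form int_0^E M(e) 2*pi*e de
    = 2*pi*scale^2 [ln(e + e0) + e0/(e + e0)]_0^E.
    """
    if not 0 < E_max <= E_full:
        raise ValueError("require 0 < E_max <= E_full")
    f0 = _area_integral(0.0, e0)
    return float(
        (_area_integral(E_max, e0) - f0) / (_area_integral(E_full, e0) - f0)
    )
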