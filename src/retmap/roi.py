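"""Visual-area delineation and whole-map surface-area summaries.

On real data V1-V3 borders are drawn by hand at the polar-angle reversals;
here detection is automated: reversal ridges are vertices where the polar
angle map folds back at a meridian (local minimum of angular distance to the
meridian with same-signed neighbors), and V1 is the connected map region
between the two vertical-meridian ridges that contains a smooth horizontal
crossing.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .synth import SurfaceMesh, VertexRetinotopy

__all__ = [
    "circ_diff",
    "detect_reversals",
    "v1_from_reversals",
    "map_surface_area",
    "coefficient_of_variation",
    "group_mean_bootstrap",
]

R2_MIN_DEFAULT = 0.10

MERIDIAN_NAMES = {
    0.0: "right-horizontal",
    90.0: "upper-vertical",
    180.0: "left-horizontal",
    270.0: "lower-vertical",
}


def circ_diff(a: np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """Signed circular difference a - b wrapped to [-180, 180)."""
    return (np.asarray(a, dtype=float) - b + 180.0) % 360.0 - 180.0


def detect_reversals(
    mesh: SurfaceMesh,
    retinotopy: VertexRetinotopy,
    r2_min: float = R2_MIN_DEFAULT,
    angle_tol: float = 20.0,
    ridge_slack: float = 3.0,
) -> dict[str, np.ndarray]:
    """Find polar-angle reversal ridges at the four meridians.

    A vertex is a ridge candidate for a meridian when its angular distance
    to the meridian is below ``angle_tol``, within ``ridge_slack`` degrees
    of the smallest distance among its valid neighbors (a near-local
    minimum; the slack keeps noisy ridges contiguous), and its off-ridge
    neighbors sit on one side of the meridian — the signature of a fold
    rather than a smooth crossing. Vertices with r2 < r2_min are ignored.
    """
    angles = retinotopy.angle
    valid = retinotopy.r2 >= r2_min
    nbrs = mesh.neighbors()
    out: dict[str, np.ndarray] = {name: np.array([], dtype=int) for name in MERIDIAN_NAMES.values()}
    if not valid.any():
        warnings.warn("no vertices at or above r2_min; no reversals found", RuntimeWarning)
        return out

    for m, name in MERIDIAN_NAMES.items():
        s = circ_diff(angles, m)
        d = np.abs(s)
        found = []
        for v in np.flatnonzero(valid & (d < angle_tol)):
            nb = nbrs[v][valid[nbrs[v]]]
            if nb.size == 0 or d[v] > d[nb].min() + ridge_slack:
                continue
            signs = np.sign(s[nb][np.abs(s[nb]) > 2.0])
            if signs.size and np.abs(signs.sum()) < 0.6 * signs.size:
                continue  # smooth crossing, not a fold
            found.append(v)
        out[name] = np.array(sorted(found), dtype=int)

    if all(v.size == 0 for v in out.values()):
        warnings.warn("no polar-angle reversals detected", RuntimeWarning)
    return out


def v1_from_reversals(
    mesh: SurfaceMesh,
    retinotopy: VertexRetinotopy,
    reversals: dict[str, np.ndarray],
    r2_min: float = R2_MIN_DEFAULT,
) -> np.ndarray:
    """V1 vertex ids: the connected component between the vertical-meridian
    ridges that contains a smooth horizontal-meridian crossing, plus the
    bounding ridge vertices themselves."""
    ridge = np.concatenate(
        [reversals.get("upper-vertical", []), reversals.get("lower-vertical", [])]
    ).astype(int)
    if ridge.size == 0:
        raise ValueError("no vertical-meridian reversals supplied")

    angles = retinotopy.angle
    hm = 0.0 if mesh.hemisphere == "left" else 180.0
    s = circ_diff(angles, hm)
    e, _ = mesh.edges()
    keep = ~np.isin(e, ridge).any(axis=1)
    n = mesh.n_vertices
    g = coo_matrix(
        (np.ones(keep.sum()), (e[keep, 0], e[keep, 1])), shape=(n, n)
    )
    _, comp = connected_components(g, directed=False)

    # Seed vertices: local minima of angular distance to the horizontal
    # meridian whose neighbors straddle it (a smooth crossing, the signature
    # of the V1 interior; at the V2/V3 border the map folds instead).
    ok = retinotopy.r2 >= r2_min
    nbrs = mesh.neighbors()
    d = np.abs(s)
    seeds = []
    for v in np.flatnonzero(ok & (d < 10.0)):
        nb = nbrs[v][ok[nbrs[v]]]
        if nb.size == 0 or np.any(d[nb] < d[v] - 1e-9):
            continue
        signs = np.sign(s[nb][np.abs(s[nb]) > 2.0])
        if signs.size >= 2 and 0.3 <= np.mean(signs > 0) <= 0.7:
            seeds.append(v)
    if not seeds:
        raise ValueError("no horizontal-meridian crossing found; cannot seed V1")
    seed_comps, counts = np.unique(comp[np.array(seeds)], return_counts=True)
    v1_comp = seed_comps[np.argmax(counts)]
    ids = np.flatnonzero(comp == v1_comp)
    # grow back across the ridge band up to its center: under noise the
    # detected reversal is a few vertices thick and the cut removed it all
    grown = set(ids.tolist())
    for _ in range(2):
        add = [r for r in ridge if any(n in grown for n in nbrs[r])]
        grown.update(add)
    return np.array(sorted(grown), dtype=int)


def map_surface_area(
    mesh: SurfaceMesh,
    vertex_ids: np.ndarray,
    depth: str = "midgray",
    ecc: np.ndarray | None = None,
    ecc_window: tuple[float, float] | None = None,
) -> float:
    """Summed per-vertex surface area of an ROI at a cortical depth,
    optionally restricted to an eccentricity window [lo, hi]."""
    if depth not in mesh.vertex_area:
        raise ValueError(f"unknown depth {depth!r}")
    ids = np.asarray(vertex_ids, dtype=int)
    if ids.size == 0:
        raise ValueError("roi is empty")
    if ecc_window is not None:
        if ecc is None:
            raise ValueError("ecc values required for ecc_window filtering")
        lo, hi = ecc_window
        ids = ids[(ecc[ids] >= lo) & (ecc[ids] <= hi)]
    return float(mesh.vertex_area[depth][ids].sum())


def coefficient_of_variation(values: np.ndarray) -> float:
    """Sample SD (n-1 denominator) divided by the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    m = v.mean()
    if m <= 0:
        raise ValueError("mean must be positive")
    return float(v.std(ddof=1) / m)


def group_mean_bootstrap(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Bootstrap of the group-mean difference, as percent of group b's mean.

    Returns (point estimate, percentile CI95). Both groups are resampled
    with replacement independently.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    rng = np.random.default_rng(seed)
    ai = rng.integers(0, a.size, size=(n_boot, a.size))
    bi = rng.integers(0, b.size, size=(n_boot, b.size))
    boot = (a[ai].mean(axis=1) - b[bi].mean(axis=1)) / b[bi].mean(axis=1) * 100.0
    point = float((a.mean() - b.mean()) / b.mean() * 100.0)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return point, (float(lo), float(hi))
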