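"""Synthetic cortical hemispheres with analytically known retinotopy.

The generator builds a flat triangulated "hemisphere" strip containing V1,
V2, and V3 whose local areal magnification follows the Horton-Hoyt law

    M(E) = (s / (E + e0))^2   [mm^2 / deg^2],

optionally modulated by a smooth multiplicative angular-magnification
profile that injects known horizontal-vertical (HVA) and vertical-meridian
(VMA) surface-area asymmetries. Because the mapping from visual field
(eccentricity E, polar angle theta) to cortex is closed-form, every
downstream measurement (wedge areas, magnification curves, asymmetry
indices) can be checked against quadrature of the generating law.

Construction. With u = s*ln((E+e0)/e0) and v = s*(E/(E+e0))*G(p) where G is
the cumulative angular gain (radians), the area element du dv equals
gain * M(E) * E dE dtheta exactly, i.e. the mesh realizes the target areal
magnification up to discretization. The strip parameter p spans +-270 deg:
|p| <= 90 is V1 (a full contralateral hemifield), 90 < |p| <= 180 the V2
quarterfields, |p| > 180 the V3 quarterfields, with polar-angle reversals at
the shared borders, as on a real occipital surface.

The angular gain is a sum of raised-cosine lobes of 45 deg half-width
centered on the four meridians, normalized to preserve total area; lobe
amplitudes are solved in closed form so that the +-25 deg wedge integrals
reproduce the requested HVA/VMA indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .prf import HRFParams, apply_hrf
from .stimulus import ApertureMovie

__all__ = [
    "GroundTruthConfig",
    "SurfaceMesh",
    "VertexRetinotopy",
    "MotionTrace",
    "Hemisphere",
    "angular_gain",
    "gain_cumulative_deg",
    "solve_lobe_amplitudes",
    "wedge_gain_integral",
    "build_hemisphere",
    "simulate_bold",
    "noise_sd_for_r2",
    "simulate_motion",
    "add_map_noise",
]

LOBE_HALF_WIDTH = 45.0  # deg; angular support of each meridian lobe
INDEX_WEDGE = 25.0  # deg; wedge half-width at which HVA/VMA targets are set
FOVEAL_CUT = 0.2  # deg; innermost mesh row (a 0-deg apex would degenerate)

DEPTH_SCALE = {"midgray": 1.0, "pial": 1.2, "white": 0.85}


@dataclass(frozen=True)
class GroundTruthConfig:
    """Ground-truth parameters of a synthetic hemisphere pair."""

    hh_scale: float = 17.3  # mm
    hh_e0: float = 0.75  # deg
    ecc_range: tuple[float, float] = (0.0, 8.0)  # deg
    hva_amp: float = 0.0  # target Eq.-1 style index (0..200)
    vma_amp: float = 0.0  # target Eq.-2 style index (-200..200)
    sigma_slope: float = 0.25  # deg sigma per deg ecc
    sigma_intercept: float = 0.5  # deg
    mesh_density: int = 9000  # vertices per hemisphere (V1 ~ one third)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hh_e0 <= 0:
            raise ValueError("hh_e0 must be positive")
        if self.mesh_density < 500:
            raise ValueError("mesh_density must be >= 500")
        if not (0 <= self.hva_amp < 200):
            raise ValueError("hva_amp must lie in [0, 200)")
        if not (-200 < self.vma_amp < 200):
            raise ValueError("vma_amp must lie in (-200, 200)")
        if not (0 <= self.ecc_range[0] < self.ecc_range[1]):
            raise ValueError("ecc_range must be increasing and nonnegative")


@dataclass
class SurfaceMesh:
    """Flat triangulated cortical sheet with per-vertex areas at three depths."""

    vertex_coords: np.ndarray  # (N, 2) mm
    faces: np.ndarray  # (M, 3) int
    vertex_area: dict[str, np.ndarray]  # depth -> (N,) mm^2
    hemisphere: str  # 'left' | 'right'

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    def total_area(self, depth: str = "midgray") -> float:
        return float(self.vertex_area[depth].sum())

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique undirected edges and their Euclidean lengths."""
        f = self.faces
        e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [0, 2]]])
        e = np.unique(np.sort(e, axis=1), axis=0)
        d = self.vertex_coords[e[:, 0]] - self.vertex_coords[e[:, 1]]
        return e, np.linalg.norm(d, axis=1)

    def neighbors(self) -> list[np.ndarray]:
        """Adjacency list (cached)."""
        if not hasattr(self, "_nbrs"):
            e, _ = self.edges()
            nbr: list[list[int]] = [[] for _ in range(self.n_vertices)]
            for a, b in e:
                nbr[a].append(b)
                nbr[b].append(a)
            self._nbrs = [np.array(sorted(n), dtype=int) for n in nbr]
        return self._nbrs


@dataclass
class VertexRetinotopy:
    """Per-vertex pRF parameters. Angle convention: degrees in [0, 360),
    0 = right horizontal, 90 = upper vertical, counterclockwise."""

    x: np.ndarray
    y: np.ndarray
    sigma: np.ndarray
    r2: np.ndarray

    @property
    def ecc(self) -> np.ndarray:
        return np.hypot(self.x, self.y)

    @property
    def angle(self) -> np.ndarray:
        return np.degrees(np.arctan2(self.y, self.x)) % 360.0

    @classmethod
    def from_polar(
        cls, angle_deg: np.ndarray, ecc: np.ndarray, sigma: np.ndarray,
        r2: np.ndarray,
    ) -> "VertexRetinotopy":
        th = np.radians(angle_deg)
        return cls(ecc * np.cos(th), ecc * np.sin(th), sigma, r2)


@dataclass
class MotionTrace:
    """Six-parameter rigid motion per volume: translations in mm,
    rotations in degrees (one row per volume)."""

    translations: np.ndarray  # (n, 3)
    rotations: np.ndarray  # (n, 3)


@dataclass
class Hemisphere:
    """A built synthetic hemisphere: mesh + ground truth + area labels."""

    mesh: SurfaceMesh
    retinotopy: VertexRetinotopy
    labels: dict[str, np.ndarray]  # 'V1' | 'V2' | 'V3' -> vertex ids
    config: GroundTruthConfig
    param: np.ndarray  # (N,) strip parameter p in deg
    boundaries: dict[str, np.ndarray]  # ground-truth reversal vertex ids


# --------------------------------------------------------------------------
# angular gain profile


def _lobe(delta_deg: np.ndarray) -> np.ndarray:
    """Raised-cosine lobe, unit peak, half-width LOBE_HALF_WIDTH."""
    d = np.asarray(delta_deg, dtype=float)
    out = 0.5 * (1 + np.cos(np.pi * d / LOBE_HALF_WIDTH))
    return np.where(np.abs(d) <= LOBE_HALF_WIDTH, out, 0.0)


def _lobe_cumulative(x_deg: np.ndarray) -> np.ndarray:
    """Integral of the unit lobe from -inf to x (degrees)."""
    w = LOBE_HALF_WIDTH
    x = np.clip(np.asarray(x_deg, dtype=float), -w, w)
    return (x + w) / 2 + (w / (2 * np.pi)) * np.sin(np.pi * x / w)


def wedge_gain_integral(half_width_deg: float) -> float:
    """Integral of the unit lobe over a +-half_width wedge about its center."""
    w = LOBE_HALF_WIDTH
    h = min(half_width_deg, w)
    return 2 * (h / 2 + (w / (2 * np.pi)) * np.sin(np.pi * h / w))


def solve_lobe_amplitudes(hva_amp: float, vma_amp: float) -> dict[float, float]:
    """Closed-form lobe amplitudes at the four meridians such that the
    +-25 deg wedge integrals of the gain reproduce the requested indices.

    The gain integrates to 360 over the circle (area preserving) by the
    constraint 2*a_H + a_U + a_L = 0. Raises if the combination would drive
    the gain nonpositive somewhere.
    """
    I = wedge_gain_integral(INDEX_WEDGE)
    a_h = hva_amp / (4 * I)
    den = 100.0 - 2 * a_h * I
    if den <= 0:
        raise ValueError(
            f"hva_amp={hva_amp} infeasible; requires hva_amp < {200.0:.0f} "
            "with positive vertical wedge area"
        )
    diff = vma_amp * den / (200 * I)
    a_l = -a_h + diff / 2
    a_u = -a_h - diff / 2
    lo = 1 + min(0.0, a_h, a_u, a_l)
    if lo <= 0.01:
        raise ValueError(
            "unreachable (hva_amp, vma_amp) combination: gain profile would "
            f"reach {lo:.3f} <= 0; reduce the requested asymmetries"
        )
    return {0.0: a_h, 90.0: a_u, 180.0: a_h, 270.0: a_l}


def angular_gain(
    theta_deg: np.ndarray, hva_amp: float, vma_amp: float
) -> np.ndarray:
    """Multiplicative angular magnification at visual polar angle theta.

    Smooth, periodic, positive, and area preserving:
    integral over [0, 360) equals 360.
    """
    amps = solve_lobe_amplitudes(hva_amp, vma_amp)
    th = np.asarray(theta_deg, dtype=float) % 360.0
    g = np.ones_like(th)
    for m, a in amps.items():
        d = (th - m + 180.0) % 360.0 - 180.0
        g = g + a * _lobe(d)
    return g


def _strip_lobe_amplitudes(amps: dict[float, float]) -> dict[float, float]:
    """Lobe centers/amplitudes in strip-parameter space p in [-270, 270].

    V1 occupies |p| <= 90 with angle = p; mirror reversals put the upper
    vertical lobe at p = +-270's counterpart etc. (left hemisphere; the
    right hemisphere is an exact reflection so shares the profile).
    """
    a_h, a_u, a_l = amps[0.0], amps[90.0], amps[270.0]
    return {
        -270.0: a_l, -180.0: a_h, -90.0: a_l,
        0.0: a_h, 90.0: a_u, 180.0: a_h, 270.0: a_u,
    }


def gain_cumulative_deg(
    p_deg: np.ndarray, hva_amp: float, vma_amp: float
) -> np.ndarray:
    """Closed-form cumulative gain integral along the strip parameter,
    G(p) = int_0^p gain(angle(q)) dq (degrees), with G(0) = 0."""
    amps = _strip_lobe_amplitudes(solve_lobe_amplitudes(hva_amp, vma_amp))
    p = np.asarray(p_deg, dtype=float)
    out = p.astype(float).copy()
    for m, a in amps.items():
        out = out + a * (_lobe_cumulative(p - m) - _lobe_cumulative(-m))
    return out


def param_to_angle(p_deg: np.ndarray, hemisphere: str = "left") -> np.ndarray:
    """Visual polar angle in [0, 360) for strip parameter p (deg).

    The map folds at |p| = 90 (V1/V2, vertical meridian) and again at
    |p| = 180 (V2/V3, horizontal meridian), so each quarterfield map is a
    mirror image of its neighbor, as on real cortex.
    """
    p = np.asarray(p_deg, dtype=float)
    q = np.abs(p)
    a = np.where(q <= 90, q, np.where(q <= 180, 180 - q, q - 180))
    signed = np.sign(p) * a
    if hemisphere == "right":
        signed = 180 - signed
    return signed % 360.0


# --------------------------------------------------------------------------
# mesh construction


def _grid_shape(mesh_density: int) -> tuple[int, int]:
    n_r = max(10, int(round(np.sqrt(mesh_density / 3.0))))
    n_p = 6 * max(6, int(round(n_r / 2))) + 1  # includes 0 and +-90 exactly
    return n_r, n_p


def build_hemisphere(
    config: GroundTruthConfig, hemisphere: str = "left"
) -> Hemisphere:
    """Build one synthetic hemisphere (V1+V2+V3 strip) with ground truth.

    The returned labels partition the strip into V1 (full hemifield), and
    V2/V3 quarterfield pairs meeting V1 at polar-angle reversals. Pial and
    white vertex areas are the midgray areas scaled by fixed depth factors.
    """
    if hemisphere not in ("left", "right"):
        raise ValueError("hemisphere must be 'left' or 'right'")
    s, e0 = config.hh_scale, config.hh_e0
    e_lo = max(config.ecc_range[0], FOVEAL_CUT)
    e_hi = config.ecc_range[1]
    n_r, n_p = _grid_shape(config.mesh_density)
    if n_r < 10:
        raise ValueError("mesh_density too low to resolve eccentricity bands")

    u = np.linspace(s * np.log((e_lo + e0) / e0), s * np.log((e_hi + e0) / e0), n_r)
    E = e0 * (np.exp(u / s) - 1.0)
    p = np.linspace(-270.0, 270.0, n_p)
    G_rad = np.radians(gain_cumulative_deg(p, config.hva_amp, config.vma_amp))

    EE, PP = np.meshgrid(E, p, indexing="ij")
    UU = np.repeat(u[:, None], n_p, axis=1)
    VV = s * (EE / (EE + e0)) * np.repeat(G_rad[None, :], n_r, axis=0)
    if hemisphere == "right":
        VV = -VV
    coords = np.column_stack([UU.ravel(), VV.ravel()])

    idx = np.arange(n_r * n_p).reshape(n_r, n_p)
    a, b = idx[:-1, :-1].ravel(), idx[1:, :-1].ravel()
    c, d = idx[:-1, 1:].ravel(), idx[1:, 1:].ravel()
    faces = np.vstack([np.column_stack([a, b, c]), np.column_stack([b, d, c])])

    tri = coords[faces]
    cross = (tri[:, 1, 0] - tri[:, 0, 0]) * (tri[:, 2, 1] - tri[:, 0, 1]) - (
        tri[:, 1, 1] - tri[:, 0, 1]
    ) * (tri[:, 2, 0] - tri[:, 0, 0])
    tri_area = 0.5 * np.abs(cross)

    # Barycentric area shares, accumulated within visual-area compartments:
    # a triangle's area is split among its vertices that belong to the same
    # area (by the triangle's parameter centroid), so vertices on the
    # V1/V2/V3 borders carry only their own area's share. Total area is
    # conserved exactly; the compartmenting removes a coarse-mesh border
    # bias that vanishes at realistic vertex counts.
    pp_flat = PP.ravel()
    v_label = np.clip(np.ceil(np.abs(pp_flat) / 90.0 - 1e-9), 1, 3).astype(int)
    t_label = np.clip(
        np.ceil(np.abs(pp_flat[faces].mean(axis=1)) / 90.0 - 1e-9), 1, 3
    ).astype(int)
    varea = np.zeros(n_r * n_p)
    same = v_label[faces] == t_label[:, None]
    n_same = same.sum(axis=1)
    use_all = n_same == 0
    share = np.where(same | use_all[:, None], 1.0, 0.0)
    share = share / share.sum(axis=1, keepdims=True) * tri_area[:, None]
    np.add.at(varea, faces.ravel(), share.ravel())

    mesh = SurfaceMesh(
        vertex_coords=coords,
        faces=faces,
        vertex_area={k: varea * f for k, f in DEPTH_SCALE.items()},
        hemisphere=hemisphere,
    )

    pp = PP.ravel()
    angle = param_to_angle(pp, hemisphere)
    ecc = EE.ravel()
    sigma = config.sigma_intercept + config.sigma_slope * ecc
    retino = VertexRetinotopy.from_polar(
        angle, ecc, sigma, np.ones_like(ecc)
    )

    ap = np.abs(pp)
    labels = {
        "V1": np.flatnonzero(ap <= 90.0 + 1e-9),
        "V2": np.flatnonzero((ap > 90.0 + 1e-9) & (ap <= 180.0 + 1e-9)),
        "V3": np.flatnonzero(ap > 180.0 + 1e-9),
    }
    tol = 1e-6
    boundaries = {
        "v1v2_upper": np.flatnonzero(np.abs(pp - 90.0) < tol),
        "v1v2_lower": np.flatnonzero(np.abs(pp + 90.0) < tol),
        "v1_horizontal": np.flatnonzero(np.abs(pp) < tol),
        "v2v3_upper": np.flatnonzero(np.abs(pp - 180.0) < tol),
        "v2v3_lower": np.flatnonzero(np.abs(pp + 180.0) < tol),
        "v3_outer_upper": np.flatnonzero(np.abs(pp - 270.0) < tol),
        "v3_outer_lower": np.flatnonzero(np.abs(pp + 270.0) < tol),
    }
    return Hemisphere(mesh, retino, labels, config, pp, boundaries)


# --------------------------------------------------------------------------
# BOLD and motion simulation


def noise_sd_for_r2(target_r2: float) -> float:
    """Noise SD (relative to unit-SD signal) giving expected R^2 = target."""
    if not 0 < target_r2 <= 1:
        raise ValueError("target_r2 must lie in (0, 1]")
    return float(np.sqrt(1.0 / target_r2 - 1.0))


def simulate_bold(
    mesh: SurfaceMesh,
    retinotopy: VertexRetinotopy,
    movie: ApertureMovie,
    hrf: HRFParams | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    vertex_ids: np.ndarray | None = None,
    batch: int = 256,
) -> np.ndarray:
    """Per-vertex BOLD series: forward-model prediction (scaled to unit SD
    where nonzero) plus seeded Gaussian noise. Units are percent signal.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    hrf = hrf or HRFParams()
    ids = np.arange(mesh.n_vertices) if vertex_ids is None else np.asarray(vertex_ids)
    X, Y = movie.grid
    flat = movie.frames.reshape(movie.n_frames, -1)
    out = np.zeros((len(ids), movie.n_frames))
    for lo in range(0, len(ids), batch):
        sel = ids[lo : lo + batch]
        gx = retinotopy.x[sel][:, None]
        gy = retinotopy.y[sel][:, None]
        sg = retinotopy.sigma[sel][:, None]
        g = np.exp(
            -((X.ravel()[None, :] - gx) ** 2 + (Y.ravel()[None, :] - gy) ** 2)
            / (2 * sg**2)
        ) / (2 * np.pi * sg**2)
        ov = (g * movie.pixel_scale**2) @ flat.T
        for row, o in zip(range(lo, lo + len(sel)), ov):
            pred = apply_hrf(o, hrf, movie.tr)
            sd = pred.std()
            out[row] = pred / sd if sd > 0 else 0.0
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return out


def simulate_motion(
    n_frames: int,
    spike_frames: list[int] | tuple[int, ...] = (),
    spike_mm: float = 0.6,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> MotionTrace:
    """Motion trace with baseline jitter plus step-like spikes.

    Each spike is a persistent level shift at the named frame, so the
    framewise displacement exceeds the net spike size at exactly that
    transition (alternating sign avoids runaway drift).
    """
    for f in spike_frames:
        if not 1 <= f < n_frames:
            raise ValueError("spike frames must lie in [1, n_frames)")
    rng = np.random.default_rng(seed)
    diffs = (
        rng.normal(0.0, jitter_sd, size=(n_frames - 1, 3))
        if jitter_sd > 0
        else np.zeros((n_frames - 1, 3))
    )
    for i, f in enumerate(sorted(spike_frames)):
        diffs[f - 1, 0] += spike_mm * (1 if i % 2 == 0 else -1)
    translations = np.vstack([np.zeros(3), np.cumsum(diffs, axis=0)])
    rotations = np.zeros((n_frames, 3))
    return MotionTrace(translations=translations, rotations=rotations)


def add_map_noise(
    retinotopy: VertexRetinotopy,
    angle_noise_deg: float = 10.0,
    ecc_noise_frac: float = 0.03,
    r2_beta: tuple[float, float] = (6.0, 4.0),
    seed: int = 0,
) -> VertexRetinotopy:
    """Emulate a pRF-fitted map: wrapped-Gaussian polar-angle noise,
    multiplicative eccentricity noise, and Beta-distributed R^2 whose
    median sits near the 0.6 regime of good retinotopy data."""
    rng = np.random.default_rng(seed)
    n = len(retinotopy.x)
    angle = (retinotopy.angle + rng.normal(0, angle_noise_deg, n)) % 360.0
    ecc = retinotopy.ecc * np.clip(1 + rng.normal(0, ecc_noise_frac, n), 0.1, None)
    r2 = rng.beta(*r2_beta, size=n)
    return VertexRetinotopy.from_polar(angle, ecc, retinotopy.sigma.copy(), r2)
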