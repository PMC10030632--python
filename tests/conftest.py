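import numpy as np
import pytest

from retmap.stimulus import ApertureConfig, downsample_to_tr, make_bar_aperture
from retmap.synth import DEPTH_SCALE, GroundTruthConfig, SurfaceMesh, build_hemisphere


@pytest.fixture(scope="session")
def movie96():
    """Default 96-volume movie at TR resolution (4 cardinal sweeps)."""
    return downsample_to_tr(make_bar_aperture(ApertureConfig()))


@pytest.fixture(scope="session")
def movie_full():
    """Untruncated 8-sweep movie (192 volumes) at TR resolution."""
    return downsample_to_tr(make_bar_aperture(ApertureConfig(n_volumes=None)))


@pytest.fixture(scope="session")
def hemi_sym():
    """Left hemisphere with no injected asymmetry."""
    return build_hemisphere(GroundTruthConfig(seed=0), hemisphere="left")


@pytest.fixture(scope="session")
def hemi_adult():
    """Left hemisphere with the adult-like (HVA=80, VMA=52) asymmetry."""
    return build_hemisphere(
        GroundTruthConfig(hva_amp=80.0, vma_amp=52.0, seed=0), hemisphere="left"
    )


def barycentric_mesh(coords: np.ndarray, faces: np.ndarray, hemisphere="left"):
    """SurfaceMesh from raw 2D geometry with plain barycentric vertex areas."""
    tri = coords[faces]
    cross = (tri[:, 1, 0] - tri[:, 0, 0]) * (tri[:, 2, 1] - tri[:, 0, 1]) - (
        tri[:, 1, 1] - tri[:, 0, 1]
    ) * (tri[:, 2, 0] - tri[:, 0, 0])
    area = 0.5 * np.abs(cross)
    varea = np.zeros(len(coords))
    np.add.at(varea, faces.ravel(), np.repeat(area / 3.0, 3))
    return SurfaceMesh(
        vertex_coords=coords,
        faces=faces,
        vertex_area={k: varea * f for k, f in DEPTH_SCALE.items()},
        hemisphere=hemisphere,
    )


def flat_grid_mesh(nx: int, ny: int, spacing: float = 1.0):
    """Regular flat grid mesh (quads split into triangles), plus the (nx, ny)
    index grid for locating rows/columns."""
    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    coords = np.column_stack([X.ravel(), Y.ravel()])
    idx = np.arange(nx * ny).reshape(nx, ny)
    a, b = idx[:-1, :-1].ravel(), idx[1:, :-1].ravel()
    c, d = idx[:-1, 1:].ravel(), idx[1:, 1:].ravel()
    faces = np.vstack([np.column_stack([a, b, c]), np.column_stack([b, d, c])])
    return barycentric_mesh(coords, faces), idx
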