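"""File formats: NIfTI aperture movies, GIFTI surfaces, FreeSurfer labels,
TSV confounds, and tabular fits."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .prf import PRFFit
from .stimulus import ApertureMovie
from .synth import DEPTH_SCALE, MotionTrace, SurfaceMesh, VertexRetinotopy

__all__ = [
    "save_aperture_nifti",
    "load_aperture_nifti",
    "save_mesh_gifti",
    "load_mesh_gifti",
    "write_label",
    "read_label",
    "read_motion_tsv",
    "save_retinotopy_csv",
    "load_retinotopy_csv",
    "fits_to_frame",
]


def save_aperture_nifti(movie: ApertureMovie, path: str | Path) -> None:
    """Aperture frames as a 4D NIfTI (x, y, 1, time) with a JSON sidecar
    holding pixel scale, field radius, TR and timestamps."""
    path = Path(path)
    data = np.moveaxis(movie.frames, 0, -1)[:, :, None, :]
    img = nib.Nifti1Image(data.astype(np.float32), affine=np.eye(4))
    nib.save(img, path)
    sidecar = {
        "pixel_scale": movie.pixel_scale,
        "field_radius": movie.field_radius,
        "tr": movie.tr,
        "timestamps": movie.timestamps.tolist(),
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar))


def load_aperture_nifti(path: str | Path) -> ApertureMovie:
    path = Path(path)
    img = nib.load(path)
    frames = np.moveaxis(np.asarray(img.dataobj)[:, :, 0, :], -1, 0)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    return ApertureMovie(
        frames=frames,
        pixel_scale=meta["pixel_scale"],
        timestamps=np.asarray(meta["timestamps"]),
        field_radius=meta["field_radius"],
        tr=meta["tr"],
    )


def save_mesh_gifti(mesh: SurfaceMesh, path: str | Path) -> None:
    """Surface as GIFTI POINTSET/TRIANGLE (flat meshes get z = 0), with the
    midgray vertex areas as a shape array."""
    coords = mesh.vertex_coords
    if coords.shape[1] == 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])
    img = nib.gifti.GiftiImage()
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
        )
    )
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
        )
    )
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            mesh.vertex_area["midgray"].astype(np.float32),
            intent="NIFTI_INTENT_SHAPE",
        )
    )
    img.meta["AnatomicalStructurePrimary"] = (
        "CortexLeft" if mesh.hemisphere == "left" else "CortexRight"
    )
    nib.save(img, path)


def load_mesh_gifti(path: str | Path) -> SurfaceMesh:
    img = nib.load(path)
    coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    shape = img.get_arrays_from_intent("NIFTI_INTENT_SHAPE")
    if shape:
        midgray = shape[0].data.astype(float)
    else:  # recompute from geometry
        tri = coords[faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        tri_area = 0.5 * np.linalg.norm(np.atleast_2d(n), axis=-1)
        midgray = np.zeros(len(coords))
        np.add.at(midgray, faces.ravel(), np.repeat(tri_area / 3.0, 3))
    hemi = "left"
    if img.meta.get("AnatomicalStructurePrimary") == "CortexRight":
        hemi = "right"
    return SurfaceMesh(
        vertex_coords=coords[:, :2].astype(float)
        if np.allclose(coords[:, 2], 0)
        else coords.astype(float),
        faces=faces.astype(int),
        vertex_area={k: midgray * f for k, f in DEPTH_SCALE.items()},
        hemisphere=hemi,
    )


def write_label(
    vertex_ids: np.ndarray, mesh: SurfaceMesh, path: str | Path
) -> None:
    """FreeSurfer label file: header, count, then 'id x y z value' rows."""
    ids = np.asarray(vertex_ids, dtype=int)
    coords = mesh.vertex_coords
    if coords.shape[1] == 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])
    lines = [f"#!ascii label, {len(ids)} vertices", str(len(ids))]
    for v in ids:
        x, y, z = coords[v]
        lines.append(f"{v}  {x:.3f}  {y:.3f}  {z:.3f} 0.0000000000")
    Path(path).write_text("\n".join(lines) + "\n")


def read_label(path: str | Path) -> np.ndarray:
    return np.sort(nib.freesurfer.read_label(str(path)))


def read_motion_tsv(path: str | Path) -> MotionTrace:
    """Six-column whitespace/TSV confounds: translations (mm) then
    rotations (degrees unless handled downstream)."""
    arr = pd.read_csv(path, sep=r"\s+", header=None).to_numpy(dtype=float)
    if arr.shape[1] != 6:
        raise ValueError("expected 6 motion columns")
    return MotionTrace(translations=arr[:, :3], rotations=arr[:, 3:])


def save_retinotopy_csv(retino: VertexRetinotopy, path: str | Path) -> None:
    pd.DataFrame(
        {
            "vertex_id": np.arange(len(retino.x)),
            "x": retino.x,
            "y": retino.y,
            "sigma": retino.sigma,
            "r2": retino.r2,
        }
    ).to_csv(path, index=False)


def load_retinotopy_csv(path: str | Path) -> VertexRetinotopy:
    df = pd.read_csv(path)
    return VertexRetinotopy(
        x=df.x.to_numpy(),
        y=df.y.to_numpy(),
        sigma=df.sigma.to_numpy(),
        r2=df.r2.to_numpy(),
    )


def fits_to_frame(fits: list[PRFFit]) -> pd.DataFrame:
    """Per-vertex fit table (vertex_id, x, y, sigma, r2)."""
    return pd.DataFrame(
        [
            {
                "vertex_id": i,
                "x": f.params.x,
                "y": f.params.y,
                "sigma": f.params.sigma,
                "r2": f.r2,
            }
            for i, f in enumerate(fits)
        ]
    )
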