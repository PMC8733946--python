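"""MRI-style morphological measures on a labelled forefoot volume.

Three measures characterize the first-ray anatomy:

* tissue depth under MH1 - vertical distance from the lowest MH1 bone voxel
  to the outer skin surface directly below it (unloaded configuration);
* lateral sesamoid offset - distance from the medial edge of MH1 to the
  medial edge of the medial sesamoid, reported as a percentage of MH1
  width, plus a normal/displaced classification (displaced when the medial
  sesamoid edge lies lateral to the lateral MH1 edge);
* average principal curvature of the medial-plantar quarter of the MH1
  head, estimated by fitting local quadric patches to a triangulated
  surface and averaging the mean curvature (k1+k2)/2 area-weighted over the
  selected quarter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure as _skmeasure

from . import labels as L
from .phantom import VoxelLabelMap


class ResolutionError(ValueError):
    """Surface patch too small / too coarse for a stable estimate."""


@dataclass
class MorphometricsRecord:
    tissue_depth_mh1: float                       # mm
    mh1_width: float                              # mm
    sesamoid_lateral_offset_pct: Optional[float]  # % of MH1 width
    sesamoid_position_class: Optional[str]        # 'normal' | 'displaced'
    mh1_curvature: Optional[float] = None         # 1/mm


# ---------------------------------------------------------------------------
# depth and offset
# ---------------------------------------------------------------------------

def measure_depth_and_offset(vmap: VoxelLabelMap):
    """Tissue depth under MH1, MH1 width, sesamoid offset and its class.

    Returns ``(depth_mm, width_mm, offset_pct, position_class)``; the last
    two are ``None`` when no sesamoid label is present.
    """
    lab = vmap.labels
    h = vmap.spacing
    mh1 = lab == L.MH1
    if not mh1.any():
        raise ValueError("label map contains no MH1 bone label")

    ix = np.nonzero(mh1.any(axis=(1, 2)))[0]
    width = (ix[-1] - ix[0] + 1) * h

    vox = np.argwhere(mh1)
    ixs, iys, izs = vox[np.argmin(vox[:, 1])]
    col = lab[ixs, :, izs]
    foot = np.isin(col, L.BONES + (L.SOFT_TISSUE, L.SKIN))
    iy_out = int(np.argmax(foot))            # lowest foot voxel in the column
    depth = (iys - iy_out) * h

    ses = np.isin(lab, L.SESAMOIDS)
    if not ses.any():
        return float(depth), float(width), None, None
    ix_ses = np.nonzero(ses.any(axis=(1, 2)))[0]
    offset = max(0.0, (ix_ses[0] - ix[0]) * h)
    offset_pct = 100.0 * offset / width
    pos = "displaced" if ix_ses[0] > ix[-1] else "normal"
    return float(depth), float(width), float(offset_pct), pos


# ---------------------------------------------------------------------------
# curvature of the medial-plantar quarter of the MH1 head
# ---------------------------------------------------------------------------

def _quadric_mean_curvature(mesh: trimesh.Trimesh, vertex_ids: np.ndarray,
                            fit_radius: Optional[float] = None):
    """Per-vertex mean curvature by local quadric fitting.

    For each vertex a height-field quadric is fitted in the local tangent
    frame over all vertices within ``fit_radius`` (default: five times the
    median edge length, which keeps the estimate scale-free and damps
    voxelization noise).  Sign convention: positive for locally convex
    surfaces with outward normals.
    """
    from scipy.spatial import cKDTree

    V = mesh.vertices
    N = mesh.vertex_normals
    if fit_radius is None:
        fit_radius = 3.0 * float(np.median(mesh.edges_unique_length))
    tree = cKDTree(V)
    out = np.full(len(vertex_ids), np.nan)
    for k, vi in enumerate(vertex_ids):
        ids = [j for j in tree.query_ball_point(V[vi], fit_radius) if j != vi]
        if len(ids) < 8:
            continue
        ids = np.asarray(ids, dtype=int)
        n = N[vi]
        t1 = np.cross(n, [1.0, 0.0, 0.0])
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.cross(n, [0.0, 1.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(n, t1)
        p = V[ids] - V[vi]
        u, w, q = p @ t1, p @ t2, p @ n
        A = np.column_stack([u**2, u * w, w**2, u, w])
        try:
            coef, *_ = np.linalg.lstsq(A, q, rcond=None)
        except np.linalg.LinAlgError:
            continue
        a, b, c, d, e = coef
        H = (((1 + e**2) * 2 * a - 2 * d * e * b + (1 + d**2) * 2 * c)
             / (2.0 * (1 + d**2 + e**2) ** 1.5))
        out[k] = -H       # outward normals: convex -> positive curvature
    return out


def _orient_outward(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Return the mesh with face normals pointing away from the body."""
    c = mesh.vertices.mean(axis=0)
    s = float(np.einsum("ij,ij->i", mesh.triangles_center - c,
                        mesh.face_normals).mean())
    if s < 0:
        mesh = trimesh.Trimesh(mesh.vertices.copy(), mesh.faces[:, ::-1].copy(),
                               process=False)
    return mesh


def _vertex_areas(mesh: trimesh.Trimesh) -> np.ndarray:
    areas = np.zeros(len(mesh.vertices))
    fa = mesh.area_faces / 3.0
    for j in range(3):
        np.add.at(areas, mesh.faces[:, j], fa)
    return areas


def _mh1_head_surface(vmap: VoxelLabelMap, smooth_sigma: float = 1.0):
    """Triangulated MH1 surface plus the z-window of the head lobe."""
    mask = vmap.labels == L.MH1
    if not mask.any():
        raise ValueError("label map contains no MH1 bone label")
    h = vmap.spacing
    # per-slice equivalent radius along z; the head is the widest distal lobe
    counts = mask.sum(axis=(0, 1)).astype(float)
    rho = np.sqrt(counts * h**2 / np.pi)
    iz_head = int(np.argmax(rho))
    r_head = rho[iz_head]

    vol = ndimage.gaussian_filter(np.pad(mask, 2).astype(float), sigma=smooth_sigma)
    verts, faces, *_ = _skmeasure.marching_cubes(vol, level=0.5, spacing=(h, h, h))
    verts = verts + vmap.origin - 2 * h
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    mesh = _orient_outward(mesh)
    z_head = vmap.origin[2] + iz_head * h
    return mesh, (z_head - 0.45 * r_head, z_head + 0.45 * r_head)


def mh1_curvature(map_or_mesh: Union[VoxelLabelMap, trimesh.Trimesh, tuple],
                  fit_radius: Optional[float] = None,
                  smooth_sigma: float = 1.0) -> float:
    """Area-weighted average mean curvature of the medial-plantar quarter.

    Accepts a label map (MH1 surface is extracted by marching cubes on a
    lightly smoothed mask), a :class:`trimesh.Trimesh`, or a
    ``(vertices, faces)`` tuple.  The quarter is selected as the vertices
    medial of the medio-lateral centroid AND plantar of the dorso-plantar
    centroid of the head surface.  Raises :class:`ResolutionError` when the
    selected patch has fewer than 10 vertices.
    """
    z_window = None
    if isinstance(map_or_mesh, VoxelLabelMap):
        mesh, z_window = _mh1_head_surface(map_or_mesh, smooth_sigma)
    elif isinstance(map_or_mesh, trimesh.Trimesh):
        mesh = map_or_mesh
    else:
        verts, faces = map_or_mesh
        mesh = trimesh.Trimesh(vertices=np.asarray(verts, float),
                               faces=np.asarray(faces, int), process=True)
        mesh = _orient_outward(mesh)

    V = mesh.vertices
    sel = np.ones(len(V), dtype=bool)
    if z_window is not None:
        sel &= (V[:, 2] >= z_window[0]) & (V[:, 2] <= z_window[1])
        if not sel.any():
            raise ResolutionError("no surface vertices inside the MH1 head window")
    cx, cy = V[sel, 0].mean(), V[sel, 1].mean()
    sel &= (V[:, 0] < cx) & (V[:, 1] < cy)
    ids = np.nonzero(sel)[0]
    if len(ids) < 10:
        raise ResolutionError(
            f"medial-plantar quarter has only {len(ids)} vertices; "
            "increase surface resolution")

    kappa = _quadric_mean_curvature(mesh, ids, fit_radius=fit_radius)
    areas = _vertex_areas(mesh)[ids]
    ok = np.isfinite(kappa)
    if not ok.any():
        raise ResolutionError("quadric fits failed on the selected patch")
    return float(np.average(kappa[ok], weights=areas[ok]))


def measure(vmap: VoxelLabelMap, curvature: bool = True) -> MorphometricsRecord:
    """All three morphological measures for one subject."""
    depth, width, off, cls = measure_depth_and_offset(vmap)
    kap = mh1_curvature(vmap) if curvature else None
    return MorphometricsRecord(depth, width, off, cls, kap)
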