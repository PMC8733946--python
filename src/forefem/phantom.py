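"""Parametric voxel forefoot phantoms.

This module replaces the MR segmentation stage of the pipeline with a
parametric construction.  A :class:`PhantomSpec` describes one synthetic
forefoot: five metatarsals (shaft + head + fused phalanx stub), two
sesamoids under/beside the first metatarsal head (MH1), a bulk soft-tissue
envelope and a skin shell.  The clinically meaningful controls are

* ``tissue_depth_mh1`` - plantar tissue depth under MH1 (mm),
* ``sesamoid_offset_frac`` - lateral offset of the medial sesamoid edge from
  the medial MH1 edge, as a fraction of MH1 width,
* ``mh1_medial_plantar_radius`` - radius (mm) of the medial-plantar quarter
  of the MH1 head, i.e. the inverse of the target surface curvature,
* body mass / BMI, which drive the midstance load model downstream.

:func:`dress_phantom` adds the worn layers exactly as the modelling protocol
prescribes: a 2 mm sock by in-plane dilation of the skin, a total-contact
orthosis filling the gap between the sock plantar surface and a flat sole
top with a 3 mm minimum thickness, a 6 mm sole slab and a 3 mm upper shell.

Axis convention: x medial->lateral, y plantar->dorsal, z proximal->distal;
arrays are indexed ``labels[ix, iy, iz]`` with isotropic spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from . import labels as L


class InfeasibleGeometryError(ValueError):
    """A PhantomSpec requests geometry that cannot be realized."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VoxelLabelMap:
    """3D labelled volume with isotropic spacing (mm).

    ``labels`` holds the integer codes of :mod:`forefem.labels`.
    ``origin`` is the world position (mm) of voxel ``(0, 0, 0)``.
    """

    labels: np.ndarray
    spacing: float
    origin: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")

    @property
    def shape(self):
        return self.labels.shape

    def world(self, idx) -> np.ndarray:
        """World coordinates (mm) of voxel indices (may be fractional)."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def index(self, xyz) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.labels.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing

    def region_volumes(self) -> dict:
        """Voxel-count volume (mm^3) per label present."""
        vals, counts = np.unique(self.labels, return_counts=True)
        v = self.spacing**3
        return {int(k): float(c) * v for k, c in zip(vals, counts) if k != L.BACKGROUND}

    # -- invariants ---------------------------------------------------------
    def bone_enclosed_in_plane(self) -> bool:
        """Every bone voxel's in-plane (x-y) neighbours are foot voxels.

        The proximal/distal cut planes legitimately expose bone, so the
        enclosure check is in-plane only.
        """
        foot = np.isin(self.labels, L.BONES + (L.SOFT_TISSUE, L.SKIN))
        bone = np.isin(self.labels, L.BONES)
        st = np.zeros((3, 3, 1), dtype=bool)
        st[1, :, 0] = True
        st[:, 1, 0] = True
        grown = ndimage.binary_dilation(bone, structure=st)
        return bool(np.all(foot[grown]))

    # -- I/O ----------------------------------------------------------------
    def save(self, path) -> None:
        """Write as NIfTI with a JSON sidecar holding the label table."""
        import nibabel as nib

        path = str(path)
        affine = np.diag([self.spacing] * 3 + [1.0])
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(self.labels.astype(np.int16), affine)
        nib.save(img, path)
        side = path[:-7] if path.endswith(".nii.gz") else path.rsplit(".", 1)[0]
        with open(side + ".labels.json", "w") as fh:
            json.dump({str(k): v for k, v in L.NAME_OF_LABEL.items()}, fh, indent=1)

    @classmethod
    def load(cls, path) -> "VoxelLabelMap":
        import nibabel as nib

        img = nib.load(str(path))
        aff = img.affine
        spac = float(aff[0, 0])
        if not np.allclose(np.diag(aff)[:3], spac):
            raise ValueError("label maps must have isotropic, axis-aligned spacing")
        return cls(np.asarray(img.dataobj).astype(np.int16), spac, aff[:3, 3].copy())


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic forefoot (lengths in mm).

    The defaults describe a full-scale subject consistent with the cohort
    medians the pipeline targets (tissue depth 15.6 mm, sesamoid offset 22.1%
    of MH1 width, MH1 medial-plantar curvature ~0.15 /mm, BMI 24.8).
    """

    subject_id: str = "phantom"
    body_mass: float = 65.0          # kg
    bmi: float = 24.8                # kg/m^2
    full_foot_length: float = 240.0
    section_length: float = 70.0
    voxel_size: float = 0.5
    mh_centers: tuple = (0.0, 11.5, 21.5, 30.5, 38.5)   # medio-lateral x, mm
    mh_radii: tuple = (9.0, 7.0, 6.0, 5.5, 5.0)
    mh1_medial_plantar_radius: float = 6.7               # 1/0.149 per mm
    tissue_depth_mh1: float = 15.6
    sesamoid_offset_frac: float = 0.221
    sesamoid_radius: float = 4.0
    skin_thickness: float = 2.0
    base_pad: float = 5.0            # minimum soft-tissue cover around bones
    seed: int = 0

    def __post_init__(self):
        pos = {
            "body_mass": self.body_mass, "bmi": self.bmi,
            "full_foot_length": self.full_foot_length,
            "section_length": self.section_length, "voxel_size": self.voxel_size,
            "mh1_medial_plantar_radius": self.mh1_medial_plantar_radius,
            "tissue_depth_mh1": self.tissue_depth_mh1,
            "sesamoid_radius": self.sesamoid_radius,
            "skin_thickness": self.skin_thickness, "base_pad": self.base_pad,
        }
        for name, v in pos.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if any(r <= 0 for r in self.mh_radii):
            raise ValueError("all mh_radii must be > 0")
        if self.section_length > self.full_foot_length:
            raise ValueError("section_length must not exceed full_foot_length")
        if self.voxel_size > self.skin_thickness / 2.0:
            raise ValueError(
                f"voxel_size {self.voxel_size} must be <= skin_thickness/2 "
                f"({self.skin_thickness / 2.0}) so the skin shell is resolvable")
        if self.sesamoid_offset_frac < 0:
            raise ValueError("sesamoid_offset_frac must be >= 0")
        if len(self.mh_centers) != 5 or len(self.mh_radii) != 5:
            raise ValueError("mh_centers and mh_radii must have 5 entries")
        if any(b <= a for a, b in zip(self.mh_centers, self.mh_centers[1:])):
            raise ValueError("mh_centers must be strictly ordered medial->lateral")

    def scaled(self, factor: float, **overrides) -> "PhantomSpec":
        """Uniformly scale all geometric lengths by ``factor`` (not mass/BMI)."""
        geo = dict(
            full_foot_length=self.full_foot_length * factor,
            section_length=self.section_length * factor,
            voxel_size=self.voxel_size * factor,
            mh_centers=tuple(c * factor for c in self.mh_centers),
            mh_radii=tuple(r * factor for r in self.mh_radii),
            mh1_medial_plantar_radius=self.mh1_medial_plantar_radius * factor,
            tissue_depth_mh1=self.tissue_depth_mh1 * factor,
            sesamoid_radius=self.sesamoid_radius * factor,
            skin_thickness=self.skin_thickness * factor,
            base_pad=self.base_pad * factor,
        )
        geo.update(overrides)
        return replace(self, **geo)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _head_setbacks(spec: PhantomSpec) -> np.ndarray:
    """Distance (mm) of each metatarsal head centre from the distal cut.

    The second ray is the most distal, mimicking the metatarsal parabola.
    """
    r = np.asarray(spec.mh_radii)
    parabola = np.array([1.5, 1.0, 1.25, 1.6, 1.9])
    return 1.2 * r + 4.0 * parabola * (r[0] / 9.0)


def build_phantom(spec: PhantomSpec) -> VoxelLabelMap:
    """Voxelize the anatomy (bones, soft tissue, skin) of one phantom.

    Deterministic for a given spec.  Raises
    :class:`InfeasibleGeometryError` when the requested parameters cannot
    coexist (e.g. a sesamoid larger than the tissue depth under MH1).
    """
    h = spec.voxel_size
    R = np.asarray(spec.mh_radii)
    cx = np.asarray(spec.mh_centers)
    r_mp = spec.mh1_medial_plantar_radius
    r_s = spec.sesamoid_radius
    pad_needed_below = spec.tissue_depth_mh1 + 2 * h

    # sesamoid placement (world coords); bone axes lie in the y = 0 plane
    mh1_w = 2.0 * R[0]
    ses_gap = 0.25 * r_s
    y_ses = -(R[0] + r_s + 0.1 * r_s)
    ses_bottom = y_ses - r_s
    tissue_bottom = -(R[0] + (spec.tissue_depth_mh1 - spec.skin_thickness))
    if ses_bottom < tissue_bottom + h:
        raise InfeasibleGeometryError(
            f"sesamoid_radius={r_s} mm does not fit inside "
            f"tissue_depth_mh1={spec.tissue_depth_mh1} mm under MH1 "
            f"(sesamoid bottom {ses_bottom:.1f} < tissue bottom {tissue_bottom:.1f})")

    # grid extents with margin for soft tissue, skin and later dressing
    margin = spec.base_pad + spec.skin_thickness + 6.0
    x_lo = cx[0] - max(R[0], r_mp) - margin - 8.0
    x_hi = cx[-1] + R[-1] + margin + 8.0
    y_lo = tissue_bottom - spec.skin_thickness - margin - 14.0
    y_hi = R[0] + margin + 8.0
    z_lo, z_hi = 0.0, spec.section_length
    origin = np.array([x_lo, y_lo, z_lo])
    shape = tuple(int(np.ceil((hi - lo) / h)) + 1
                  for lo, hi in [(x_lo, x_hi), (y_lo, y_hi), (z_lo, z_hi)])
    X = origin[0] + np.arange(shape[0])[:, None, None] * h
    Y = origin[1] + np.arange(shape[1])[None, :, None] * h
    Z = origin[2] + np.arange(shape[2])[None, None, :] * h

    lab = np.zeros(shape, dtype=np.int16)
    setback = _head_setbacks(spec)

    def capsule(x0, z0, z1, radius, y0=0.0):
        """Voxel mask of a z-aligned capsule."""
        dz = np.clip(Z, z0, z1)
        d2 = (X - x0) ** 2 + (Y - y0) ** 2 + (Z - dz) ** 2
        return d2 <= radius**2

    bone_masks = {}
    for i, code in enumerate(L.METATARSALS):
        z_head = spec.section_length - setback[i]
        if z_head <= 0:
            raise InfeasibleGeometryError(
                f"section_length={spec.section_length} too short for head setback "
                f"{setback[i]:.1f} of ray {i + 1}")
        # MH1's neck thins with a sharp medial-plantar head so the carved
        # head surface is not undercut by the shaft/stub inside the head zone
        r_shaft = 0.55 * R[i] if i else min(0.55 * R[i], 0.85 * r_mp)
        r_stub = 0.5 * R[i] if i else min(0.5 * R[i], 0.8 * r_mp)
        shaft = capsule(cx[i], 0.0, z_head, r_shaft)
        head_d2 = (X - cx[i]) ** 2 + Y**2 + (Z - z_head) ** 2
        head = head_d2 <= R[i] ** 2
        if i == 0:
            # Medial-plantar sector shaped by a sphere of radius r_mp tangent
            # to the main head sphere along the medial-plantar diagonal; the
            # radial extent is blended smoothly into the main sphere so the
            # surface carries curvature 1/r_mp over the sector without a
            # crease at its boundary.
            d0 = np.array([-1.0, -1.0, 0.0]) / np.sqrt(2.0)
            dx, dy, dz = X - cx[0], Y - 0.0, Z - z_head
            rho = np.sqrt(dx**2 + dy**2 + dz**2)
            with np.errstate(invalid="ignore", divide="ignore"):
                cosa = np.clip((dx * d0[0] + dy * d0[1]) / np.maximum(rho, 1e-12),
                               -1.0, 1.0)
            dR = R[0] - r_mp
            disc = r_mp**2 - dR**2 * (1.0 - cosa**2)
            rho_mp = np.where(disc > 0.0, dR * cosa + np.sqrt(np.maximum(disc, 0.0)),
                              R[0])
            a = np.arccos(cosa)
            a0, a1 = np.deg2rad(72.0), np.deg2rad(95.0)
            t = np.clip((a - a0) / (a1 - a0), 0.0, 1.0)
            s = 1.0 - t * t * (3.0 - 2.0 * t)          # 1 inside 72 deg, 0 beyond 95
            rho_lim = R[0] + (rho_mp - R[0]) * s
            head = rho <= rho_lim
        stub = capsule(cx[i], z_head, spec.section_length, r_stub)
        bone_masks[code] = shaft | head | stub

    # place the sesamoids relative to the *voxelized* MH1 edge and width so
    # the construct-then-measure round trip closes to within a voxel
    z_head1 = spec.section_length - setback[0]
    z_ses = z_head1 - 0.2 * R[0]
    ix_mh1 = np.nonzero(bone_masks[L.MH1].any(axis=(1, 2)))[0]
    x_edge_vox = origin[0] + ix_mh1[0] * h
    w_vox = (ix_mh1[-1] - ix_mh1[0] + 1) * h
    x_med_edge = x_edge_vox + spec.sesamoid_offset_frac * w_vox
    for code, x_c in [(L.SESAMOID_MEDIAL, x_med_edge + r_s),
                      (L.SESAMOID_LATERAL, x_med_edge + 3.0 * r_s + ses_gap)]:
        d2 = (X - x_c) ** 2 + (Y - y_ses) ** 2 + (Z - z_ses) ** 2
        bone_masks[code] = d2 <= r_s**2

    bones = np.zeros(shape, dtype=bool)
    for m in bone_masks.values():
        bones |= m

    # soft-tissue envelope: variable-radius dilation of the bones, with the
    # pad under MH1 chosen so the measured depth equals tissue_depth_mh1
    D = ndimage.distance_transform_edt(~bones, sampling=h)
    mh1 = bone_masks[L.MH1]
    iy_low = np.argwhere(mh1)
    k = np.argmin(iy_low[:, 1])
    ix_star, iy_star, iz_star = iy_low[k]
    y_low = origin[1] + iy_star * h
    y_target = y_low - (spec.tissue_depth_mh1 - spec.skin_thickness)
    iy_t = int(round((y_target - origin[1]) / h))
    if iy_t < 0:
        raise InfeasibleGeometryError(
            f"tissue_depth_mh1={spec.tissue_depth_mh1} exceeds the grid margin")
    pad_mh1 = D[ix_star, iy_t, iz_star]
    sigma = 1.2 * R[0]
    gauss = np.exp(-(((X - (origin[0] + ix_star * h)) ** 2
                      + (Z - (origin[2] + iz_star * h)) ** 2) / (2.0 * sigma**2)))
    pad = spec.base_pad + (pad_mh1 - spec.base_pad) * gauss
    tissue = D <= pad

    # skin: uniform Euclidean shell around the tissue envelope
    Dt = ndimage.distance_transform_edt(~tissue, sampling=h)
    skin = (Dt > 0) & (Dt <= spec.skin_thickness)

    lab[tissue & ~bones] = L.SOFT_TISSUE
    lab[skin] = L.SKIN
    for code, m in bone_masks.items():
        lab[m] = code
    return VoxelLabelMap(lab, h, origin)


# ---------------------------------------------------------------------------
# dressing: sock, total-contact orthosis, sole, upper
# ---------------------------------------------------------------------------

def dress_phantom(anatomy: VoxelLabelMap,
                  sock_thickness: float = 2.0,
                  upper_thickness: float = 3.0,
                  sole_thickness: float = 6.0,
                  orthosis_min: float = 3.0) -> VoxelLabelMap:
    """Add sock, total-contact orthosis, sole slab and upper shell.

    The sock is an in-plane (coronal x-y) dilation shell of the foot
    surface; the orthosis fills the gap between the sock plantar surface and
    a flat sole top placed ``orthosis_min`` below the lowest sock voxel; the
    sole is a flat slab and the upper an in-plane shell around the sock.
    """
    if not np.any(anatomy.labels == L.SKIN):
        raise ValueError("anatomy has no skin label; dress_phantom needs a skinned foot")
    h = anatomy.spacing
    s_v = max(1, int(round(sock_thickness / h)))
    u_v = max(1, int(round(upper_thickness / h)))
    o_v = max(1, int(round(orthosis_min / h)))
    sl_v = max(1, int(round(sole_thickness / h)))

    # grow the array so every layer fits
    pad_xy = s_v + u_v + 2
    pad_bot = s_v + o_v + sl_v + 2
    lab = np.pad(anatomy.labels, ((pad_xy, pad_xy), (pad_bot, pad_xy), (0, 0)))
    origin = anatomy.origin - np.array([pad_xy, pad_bot, 0.0]) * h

    foot = lab != L.BACKGROUND
    nx, ny, nz = lab.shape

    sock = np.zeros_like(foot)
    shell = np.zeros_like(foot)
    for iz in range(nz):
        sl = foot[:, :, iz]
        if not sl.any():
            continue
        d2 = ndimage.distance_transform_edt(~sl, sampling=h)
        sock[:, :, iz] = (d2 > 0) & (d2 <= sock_thickness)
        shell[:, :, iz] = (d2 > sock_thickness) & (d2 <= sock_thickness + upper_thickness)

    dressed = lab.copy()
    dressed[sock] = L.SOCK

    cover = sock | shell
    cols = cover.any(axis=1)                       # (nx, nz) footprint
    sock_cols = sock.any(axis=1)
    sock_bottom = np.where(sock_cols, np.argmax(sock, axis=1), ny)
    # the orthosis must reach the sock's plantar surface (total contact);
    # only the fringe beyond the sock footprint stops at the upper shell
    bottom = np.where(sock_cols, sock_bottom,
                      np.where(cols, np.argmax(cover, axis=1), ny))
    iy_sole_top = int(sock_bottom[sock_cols].min()) - o_v
    if iy_sole_top - sl_v < 0:
        raise ValueError("insufficient plantar margin to place sole; pad the map")

    iy_grid = np.arange(ny)[None, :, None]
    below = (iy_grid >= iy_sole_top) & (iy_grid < bottom[:, None, :])
    orthosis = below & cols[:, None, :] & (dressed[:, :, :] == L.BACKGROUND)
    dressed[orthosis] = L.ORTHOSIS

    sole = (iy_grid >= iy_sole_top - sl_v) & (iy_grid < iy_sole_top) & cols[:, None, :]
    dressed[sole & (dressed == L.BACKGROUND)] = L.SOLE

    dressed[shell & (dressed == L.BACKGROUND)] = L.UPPER
    return VoxelLabelMap(dressed, h, origin)
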