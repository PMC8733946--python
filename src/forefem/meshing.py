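"""Label map to second-order tetrahedral mesh with per-region refinement.

The mesher builds a 2:1-balanced octree lattice over the labelled volume:
each lattice cell is refined until its edge is no larger than the target
edge length of every region it intersects.  Leaves are tetrahedralized with
conforming templates:

* cells whose faces all meet same-or-coarser neighbours get the 6-tet Kuhn
  split along the main diagonal (whose face diagonals coincide with the
  canonical min-corner rule used everywhere);
* cells adjacent to finer neighbours are split by triangulating each face
  (4 sub-squares against finer neighbours) with canonical diagonals and
  coning the triangles to the cell centroid.

Because face triangulations are derived canonically from the shared square
geometry, meshes are conforming across level transitions without hanging
nodes.  Element region labels are sampled from the voxel map by majority
over five interior points.  Midside nodes are added afterwards (straight
edges, so all elements are affine); the ``quadratic=False`` fallback keeps
4-node tets for fast plumbing tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from . import labels as L
from .phantom import VoxelLabelMap


class ThinRegionError(ValueError):
    """Requested element size cannot resolve a thin region."""


#: VTK local edge order of a 10-node tetrahedron
TET10_EDGES = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))
#: local corner triples of the four faces
TET_FACES = ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))


@dataclass
class FEMesh:
    """Region-labelled tetrahedral mesh (lengths in mm).

    ``tets`` has 10 columns (VTK ordering) for quadratic meshes, 4 for the
    linear fallback.  ``region`` carries one voxel-label code per element.
    """

    nodes: np.ndarray
    tets: np.ndarray
    region: np.ndarray
    spacing_hint: float = 0.0
    source_map: Optional[VoxelLabelMap] = None
    sizing: Optional[dict] = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    @property
    def quadratic(self) -> bool:
        return self.tets.shape[1] == 10

    def corner_coords(self) -> np.ndarray:
        return self.nodes[self.tets[:, :4]]

    def jacobians(self) -> np.ndarray:
        """Signed 6*volume of each element (affine corner Jacobian)."""
        X = self.corner_coords()
        d = X[:, 1:] - X[:, :1]
        return np.linalg.det(d)

    def volumes(self) -> np.ndarray:
        return self.jacobians() / 6.0

    def region_volumes(self) -> dict:
        out = {}
        v = self.volumes()
        for lab in np.unique(self.region):
            out[int(lab)] = float(v[self.region == lab].sum())
        return out

    def edge_lengths_of(self, label: int) -> np.ndarray:
        sel = self.tets[self.region == label][:, :4]
        segs = []
        for a, b in TET10_EDGES:
            segs.append(np.linalg.norm(self.nodes[sel[:, a]] - self.nodes[sel[:, b]],
                                       axis=1))
        return np.concatenate(segs)

    def faces_with_counts(self):
        """Unique corner faces, their multiplicity and owner elements.

        Returns ``(faces, counts, owners)`` with ``faces`` the sorted corner
        node triples, ``owners`` a ``(n_faces, 2)`` array of element indices
        (second column -1 for boundary faces).
        """
        M = len(self.tets)
        tri = np.sort(self.tets[:, :4][:, TET_FACES].reshape(-1, 3), axis=1)
        owner = np.repeat(np.arange(M), 4)
        order = np.lexsort(tri.T)
        tri_s, owner_s = tri[order], owner[order]
        new = np.ones(len(tri_s), dtype=bool)
        new[1:] = np.any(tri_s[1:] != tri_s[:-1], axis=1)
        idx = np.nonzero(new)[0]
        counts = np.diff(np.append(idx, len(tri_s)))
        faces = tri_s[idx]
        owners = np.full((len(faces), 2), -1, dtype=np.int64)
        owners[:, 0] = owner_s[idx]
        two = counts == 2
        owners[two, 1] = owner_s[idx[two] + 1]
        return faces, counts, owners


# ---------------------------------------------------------------------------
# octree construction
# ---------------------------------------------------------------------------

def _normalize_sizing(vmap: VoxelLabelMap, sizing) -> dict:
    present = [int(v) for v in np.unique(vmap.labels) if v != L.BACKGROUND]
    if np.isscalar(sizing):
        return {lab: float(sizing) for lab in present}
    out = {}
    for lab in present:
        if lab in sizing:
            out[lab] = float(sizing[lab])
        else:
            name = L.REGION_OF_LABEL.get(lab)
            if name in sizing:
                out[lab] = float(sizing[name])
            else:
                raise KeyError(f"no target edge length for region "
                               f"{L.NAME_OF_LABEL.get(lab, lab)}")
    return out


def _check_thin_regions(vmap: VoxelLabelMap, sizes: dict, labels=None) -> None:
    for lab, target in sizes.items():
        if labels is not None and lab not in labels:
            continue
        mask = vmap.labels == lab
        if not mask.any():
            continue
        thick = 2.0 * float(ndimage.distance_transform_edt(
            mask, sampling=vmap.spacing).max())
        if target > 1.5 * thick:
            raise ThinRegionError(
                f"target edge {target} mm cannot resolve region "
                f"{L.NAME_OF_LABEL.get(lab, lab)} of thickness ~{thick:.1f} mm")


def label_to_mesh(vmap: VoxelLabelMap, sizing, quadratic: bool = True,
                  thin_check=True) -> FEMesh:
    """Mesh a labelled volume with per-region target edge lengths.

    ``sizing`` is a scalar or a mapping from region name / label code to the
    target edge length in mm.  Raises :class:`ThinRegionError` when a target
    exceeds a region's thickness; ``thin_check`` may be an iterable of label
    codes to restrict the check (e.g. deformable regions only, when rigid
    fixed bones are represented coarsely on purpose).
    """
    sizes = _normalize_sizing(vmap, sizing)
    if thin_check:
        _check_thin_regions(vmap, sizes,
                            None if thin_check is True else set(thin_check))
    h_min = min(sizes.values())
    h_max = max(sizes.values())
    n_levels = int(np.ceil(np.log2(max(h_max / h_min, 1.0)) - 1e-9))
    h0 = h_min * 2**n_levels
    level_req = {lab: max(0, min(n_levels, int(np.ceil(np.log2(h0 / s) - 1e-9))))
                 for lab, s in sizes.items()}

    lab_arr = vmap.labels
    vox = vmap.spacing
    # physical domain of the voxel cubes (origin is the centre of voxel 0)
    lattice_origin = vmap.origin - 0.5 * vox
    extent = np.array(lab_arr.shape) * vox
    nbase = np.maximum(1, np.ceil(extent / h0 - 1e-9).astype(int))
    # base cells are mildly anisotropic so the lattice ends exactly on the
    # proximal/distal cut planes (flat cut cross-sections for the roller BC)
    h0v = np.array([h0, h0, extent[2] / nbase[2]])
    # align a horizontal cell boundary with the flat sole bottom so the
    # ground-facing surface meshes as a plane
    if np.any(lab_arr == L.SOLE):
        iy_min = int(np.nonzero((lab_arr == L.SOLE).any(axis=(0, 2)))[0][0])
        y_bottom = vmap.origin[1] + (iy_min - 0.5) * vox
        q = h0v[1] / 2 ** level_req.get(L.SOLE, 0)
        delta = float(np.mod(y_bottom - lattice_origin[1], q))
        if min(delta, q - delta) > 1e-9:
            lattice_origin = lattice_origin - np.array([0.0, q - delta, 0.0])
            nbase[1] = int(np.ceil((extent[1] + q - delta) / h0v[1] - 1e-9))

    # label-presence pyramid: presence[l][lab] is a boolean cell grid
    hL = h0v / 2**n_levels
    nfine = nbase * 2**n_levels
    off = (vmap.origin - 0.5 * vox) - lattice_origin
    idx = [np.minimum((((np.arange(lab_arr.shape[a]) + 0.5) * vox + off[a])
                       / hL[a]).astype(int), nfine[a] - 1) for a in range(3)]
    labels_present = [int(v) for v in np.unique(lab_arr) if v != L.BACKGROUND]
    pres_fine = {}
    IX, IY, IZ = np.meshgrid(idx[0], idx[1], idx[2], indexing="ij")
    flat = (IX * nfine[1] + IY) * nfine[2] + IZ
    for lab in labels_present:
        hit = np.bincount(flat[lab_arr == lab].ravel(),
                          minlength=nfine.prod()) > 0
        pres_fine[lab] = hit.reshape(tuple(nfine))
    presence = [None] * (n_levels + 1)
    presence[n_levels] = pres_fine
    for l in range(n_levels - 1, -1, -1):
        prev = presence[l + 1]
        cur = {}
        for lab, p in prev.items():
            s = p.shape
            cur[lab] = p.reshape(s[0] // 2, 2, s[1] // 2, 2, s[2] // 2, 2).any(
                axis=(1, 3, 5))
        presence[l] = cur

    def cell_labels(l, i, j, k):
        return [lab for lab in labels_present if presence[l][lab][i, j, k]]

    # refine until every cell satisfies the strictest present region
    leaves = {}
    stack = [(0, i, j, k) for i in range(nbase[0])
             for j in range(nbase[1]) for k in range(nbase[2])]
    while stack:
        l, i, j, k = stack.pop()
        labs = cell_labels(l, i, j, k)
        if not labs:
            continue
        req = max(level_req[lab] for lab in labs)
        if l >= req:
            leaves[(l, i, j, k)] = True
        else:
            for di in range(2):
                for dj in range(2):
                    for dk in range(2):
                        stack.append((l + 1, 2 * i + di, 2 * j + dj, 2 * k + dk))

    # 2:1 balance across faces
    def split(key):
        del leaves[key]
        l, i, j, k = key
        for di in range(2):
            for dj in range(2):
                for dk in range(2):
                    c = (l + 1, 2 * i + di, 2 * j + dj, 2 * k + dk)
                    if cell_labels(*c):
                        leaves[c] = True

    changed = True
    while changed:
        changed = False
        for key in list(leaves.keys()):
            if key not in leaves:
                continue
            l, i, j, k = key
            if l < 2:
                continue
            for axis in range(3):
                for d in (-1, 1):
                    n = [i, j, k]
                    n[axis] += d
                    if n[axis] < 0 or n[axis] >= nbase[axis] * 2**l:
                        continue
                    # a leaf ancestor at level <= l-2 is too coarse
                    for la in range(l - 2, -1, -1):
                        sh = l - la
                        anc = (la, n[0] >> sh, n[1] >> sh, n[2] >> sh)
                        if anc in leaves:
                            split(anc)
                            changed = True
                            break

    # ------------------------------------------------------------------
    # tetrahedralization (integer lattice units of h0 / 2^(n_levels+1))
    # ------------------------------------------------------------------
    unitv = h0v / 2 ** (n_levels + 1)
    origin = lattice_origin
    nodes = {}

    def nid(p):
        v = nodes.get(p)
        if v is None:
            v = len(nodes)
            nodes[p] = v
        return v

    def canonical_tris(sq):
        """Triangulate a square (4 cyclic corners) with the min-corner diagonal."""
        m = min(range(4), key=lambda a: sq[a])
        return ((sq[m], sq[(m + 1) % 4], sq[(m + 2) % 4]),
                (sq[m], sq[(m + 2) % 4], sq[(m + 3) % 4]))

    # square corner offsets (cyclic) for each face of a cell of size s:
    # axis a at side d (0: low, 1: high)
    def face_squares(base, s, axis, side, halves):
        o = list(base)
        o[axis] += side * s
        u, v = (axis + 1) % 3, (axis + 2) % 3
        def corner(pu, pv):
            c = list(o)
            c[u] += pu
            c[v] += pv
            return tuple(c)
        if not halves:
            yield (corner(0, 0), corner(s, 0), corner(s, s), corner(0, s))
        else:
            hs = s // 2
            for pu in (0, hs):
                for pv in (0, hs):
                    yield (corner(pu, pv), corner(pu + hs, pv),
                           corner(pu + hs, pv + hs), corner(pu, pv + hs))

    kuhn_perms = ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0))
    tets = []

    for (l, i, j, k) in leaves:
        s = 2 ** (n_levels - l + 1)            # cell size in lattice units
        base = (i * s, j * s, k * s)
        fine_faces = []
        for axis in range(3):
            for side in (0, 1):
                n = [i, j, k]
                n[axis] += -1 if side == 0 else 1
                finer = False
                if 0 <= n[axis] < nbase[axis] * 2**l:
                    if (l, n[0], n[1], n[2]) not in leaves and l < n_levels:
                        # any child leaf of the neighbour touching this face?
                        cb = [2 * n[0], 2 * n[1], 2 * n[2]]
                        face_child = 1 if side == 0 else 0
                        u, v = (axis + 1) % 3, (axis + 2) % 3
                        for pu in (0, 1):
                            for pv in (0, 1):
                                c = list(cb)
                                c[axis] += face_child
                                c[u] += pu
                                c[v] += pv
                                if (l + 1, c[0], c[1], c[2]) in leaves:
                                    finer = True
                                    break
                            if finer:
                                break
                fine_faces.append(finer)

        if not any(fine_faces):
            # Kuhn 6-tet split from the min corner to the max corner
            for perm in kuhn_perms:
                p0 = list(base)
                path = [tuple(p0)]
                for ax in perm:
                    p0[ax] += s
                    path.append(tuple(p0))
                tets.append((nid(path[0]), nid(path[1]), nid(path[2]), nid(path[3])))
        else:
            centroid = (base[0] + s // 2, base[1] + s // 2, base[2] + s // 2)
            c_id = nid(centroid)
            f = 0
            for axis in range(3):
                for side in (0, 1):
                    for sq in face_squares(base, s, axis, side, fine_faces[f]):
                        for tri in canonical_tris(sq):
                            tets.append((nid(tri[0]), nid(tri[1]), nid(tri[2]), c_id))
                    f += 1

    coords = np.empty((len(nodes), 3))
    for p, v in nodes.items():
        coords[v] = p
    coords = origin + coords * unitv
    tets = np.asarray(tets, dtype=np.int64)

    # fix orientation (positive volume)
    d = coords[tets[:, 1:]] - coords[tets[:, :1]]
    neg = np.linalg.det(d) < 0
    tmp = tets[neg].copy()
    tmp[:, [1, 2]] = tmp[:, [2, 1]]
    tets[neg] = tmp

    # region labels: majority over centroid + 4 shrunk-vertex samples
    X = coords[tets]
    cent = X.mean(axis=1)
    pts = [cent] + [cent + 0.5 * (X[:, a] - cent) for a in range(4)]
    votes = []
    shp = np.array(lab_arr.shape)
    for p in pts:
        ind = np.round((p - vmap.origin) / vox).astype(int)
        ok = np.all((ind >= 0) & (ind < shp), axis=1)
        ind = np.clip(ind, 0, shp - 1)
        lv = lab_arr[ind[:, 0], ind[:, 1], ind[:, 2]].astype(np.int32)
        lv[~ok] = L.BACKGROUND
        votes.append(lv)
    votes = np.stack(votes, axis=1)
    region = np.zeros(len(tets), dtype=np.int32)
    # mode with centroid tie-break
    for r in range(votes.shape[0]):
        vals, cnt = np.unique(votes[r], return_counts=True)
        best = cnt.max()
        cand = vals[cnt == best]
        region[r] = votes[r, 0] if votes[r, 0] in cand else cand[0]
    keep = region != L.BACKGROUND
    tets, region = tets[keep], region[keep]

    used = np.unique(tets)
    remap = -np.ones(len(coords), dtype=np.int64)
    remap[used] = np.arange(len(used))
    tets = remap[tets]
    coords = coords[used]

    mesh = FEMesh(coords, tets, region, spacing_hint=h_min,
                  source_map=vmap, sizing=dict(sizes))
    if quadratic:
        mesh = _to_quadratic(mesh)
    return mesh


def _to_quadratic(mesh: FEMesh) -> FEMesh:
    """Insert midside nodes (VTK TET10 ordering); edges stay straight."""
    corners = mesh.tets[:, :4]
    M = len(corners)
    pairs = np.stack([corners[:, [a, b]] for a, b in TET10_EDGES], axis=1)  # (M,6,2)
    lo = pairs.min(axis=2).ravel()
    hi = pairs.max(axis=2).ravel()
    key = lo.astype(np.int64) * mesh.n_nodes + hi
    uniq, inv = np.unique(key, return_inverse=True)
    mid_xyz = 0.5 * (mesh.nodes[(uniq // mesh.n_nodes)]
                     + mesh.nodes[(uniq % mesh.n_nodes)])
    mid_ids = mesh.n_nodes + inv.reshape(M, 6)
    tets10 = np.concatenate([corners, mid_ids], axis=1)
    nodes = np.vstack([mesh.nodes, mid_xyz])
    return FEMesh(nodes, tets10, mesh.region, mesh.spacing_hint,
                  mesh.source_map, mesh.sizing)


def subdivide(mesh: FEMesh):
    """Uniform red 1:8 refinement of a quadratic mesh on fixed geometry.

    Every tetrahedron is split into 8 children through its edge midpoints
    (4 corner tets + 4 from the inner octahedron along a fixed diagonal);
    region labels are inherited, so the discretized geometry is exactly
    preserved and the refined mesh is conforming by construction.

    Returns ``(fine_mesh, embed)`` where ``embed(u)`` maps a nodal field on
    the parent mesh onto the fine mesh's nodes (parent nodes exactly, new
    midside nodes by edge averaging) - the warm start of the convergence
    harness.
    """
    if not mesh.quadratic:
        raise ValueError("subdivide expects a quadratic mesh")
    t = mesh.tets
    # children in terms of the parent's 10 local nodes
    # (corners 0-3; midsides 4:(01) 5:(12) 6:(02) 7:(03) 8:(13) 9:(23));
    # the inner octahedron is split along its SHORTEST diagonal per parent,
    # which keeps the children's quality close to the parent's
    corner_children = np.array([[0, 4, 6, 7], [4, 1, 5, 8],
                                [6, 5, 2, 9], [7, 8, 9, 3]])
    octa = {
        0: np.array([[4, 9, 5, 6], [4, 9, 6, 7], [4, 9, 7, 8], [4, 9, 8, 5]]),
        1: np.array([[5, 7, 4, 6], [5, 7, 6, 9], [5, 7, 9, 8], [5, 7, 8, 4]]),
        2: np.array([[6, 8, 4, 5], [6, 8, 5, 9], [6, 8, 9, 7], [6, 8, 7, 4]]),
    }
    X = mesh.nodes[t]
    diag = np.stack([np.linalg.norm(X[:, 4] - X[:, 9], axis=1),
                     np.linalg.norm(X[:, 5] - X[:, 7], axis=1),
                     np.linalg.norm(X[:, 6] - X[:, 8], axis=1)], axis=1)
    choice = np.argmin(diag, axis=1)
    corners = np.empty((len(t), 8, 4), dtype=t.dtype)
    corners[:, :4] = t[:, corner_children]
    for k, tpl in octa.items():
        sel = choice == k
        corners[sel, 4:] = t[sel][:, tpl]
    corners = corners.reshape(-1, 4)
    region = np.repeat(mesh.region, 8)
    # local template per element (kept in sync with orientation fixes)
    loc = np.empty((len(t), 8, 4), dtype=np.int64)
    loc[:, :4] = corner_children[None]
    for k, tpl in octa.items():
        loc[choice == k, 4:] = tpl[None]
    loc = loc.reshape(-1, 4)
    lin = FEMesh(mesh.nodes.copy(), corners, region, mesh.spacing_hint / 2.0,
                 mesh.source_map, mesh.sizing)
    # fix orientation of the octahedron tets
    d = lin.nodes[lin.tets[:, 1:]] - lin.nodes[lin.tets[:, :1]]
    neg = np.linalg.det(d) < 0
    for arr in (lin.tets, loc):
        tmp = arr[neg].copy()
        tmp[:, [1, 2]] = tmp[:, [2, 1]]
        arr[neg] = tmp
    n_parent = mesh.n_nodes
    fine = _to_quadratic(lin)

    # Exact quadratic embedding: every new midside node is the midpoint of
    # a child edge connecting two parent-LOCAL nodes; evaluate the parent's
    # P2 shape functions there.  (Averaging endpoint values instead would
    # linearize the field and, through the volumetric penalty, produce
    # huge spurious internal forces in the warm start.)
    xi_loc = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    xi10 = np.vstack([xi_loc] + [0.5 * (xi_loc[a] + xi_loc[b])
                                 for a, b in TET10_EDGES])

    def _n10(xi):
        x, y, z = xi
        lam = np.array([1 - x - y - z, x, y, z])
        N = np.empty(10)
        N[:4] = lam * (2 * lam - 1)
        for e, (a, b) in enumerate(TET10_EDGES):
            N[4 + e] = 4 * lam[a] * lam[b]
        return N

    loc_edges = loc[:, TET10_EDGES]                      # (8M, 6, 2) local
    glob_edges = lin.tets[:, TET10_EDGES]                # (8M, 6, 2) global
    lo = glob_edges.min(axis=2).ravel()
    hi = glob_edges.max(axis=2).ravel()
    key = lo.astype(np.int64) * n_parent + hi
    occ_parent = np.repeat(np.arange(len(t)), 8 * 6)
    occ_la = loc_edges.reshape(-1, 2)[:, 0]
    occ_lb = loc_edges.reshape(-1, 2)[:, 1]
    n_uniq = len(np.unique(key))

    def _selection(prefer_elems=None):
        """One evaluation site per new node, preferring given parents."""
        if prefer_elems is None:
            order = np.argsort(key, kind="stable")
        else:
            pref = ~np.asarray(prefer_elems)[occ_parent]   # False sorts first
            order = np.lexsort((pref, key))
        skey = key[order]
        first = order[np.concatenate([[0], np.nonzero(np.diff(skey))[0] + 1])]
        pe = occ_parent[first]
        la, lb = occ_la[first], occ_lb[first]
        W = np.stack([_n10(0.5 * (xi10[a] + xi10[b]))
                      for a, b in zip(la, lb)])            # (K, 10)
        return W, t[pe]

    def embed(u_parent: np.ndarray, prefer_elems=None) -> np.ndarray:
        """Evaluate the parent P2 field at the fine nodes.

        ``prefer_elems`` (parent-element mask) selects which side of a
        material/body interface supplies the values of new nodes that lie
        on shared faces - needed when the parent field is discontinuous
        across a contact interface.
        """
        flat = np.asarray(u_parent).ndim == 1
        u = np.asarray(u_parent).reshape(n_parent, -1)
        W, conn = _selection(prefer_elems)
        out = np.zeros((fine.n_nodes, u.shape[1]))
        out[:n_parent] = u
        out[n_parent:] = np.einsum("kj,kjc->kc", W, u[conn])
        return out.ravel() if flat else out

    return fine, embed


def refine(mesh: FEMesh, factor: float) -> FEMesh:
    """Remesh the source map with all target edge lengths divided by ``factor``."""
    if factor <= 1.0:
        raise ValueError(f"refinement factor must be > 1, got {factor}")
    if mesh.source_map is None or mesh.sizing is None:
        raise ValueError("mesh does not carry its source map; cannot refine")
    new_sizes = {lab: s / factor for lab, s in mesh.sizing.items()}
    return label_to_mesh(mesh.source_map, new_sizes, quadratic=mesh.quadratic)
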