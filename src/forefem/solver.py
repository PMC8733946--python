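"""Quasi-static total-Lagrangian FE solution of the shod midstance load case.

The model couples two bodies through frictional contact:

* the foot body (bones, soft tissue, skin and the bonded sock),
* the shoe body (orthosis, sole, upper, bonded together),

with the scaled vertical + medial ground reaction applied as tractions on
the sole bottom, metatarsal bones fixed (sesamoids free), roller conditions
on the proximal/distal cut planes, and penalty contact with regularized
Coulomb friction (mu = 0.55) on the sock-orthosis/upper interface.

Elements are affine 10-node tetrahedra integrated with the 4-point rule;
contact is integrated at 3 points per interface facet on the conforming
faces created by duplicating interface nodes.  Newton iterations reuse the
factorized tangent while convergence is fast (modified Newton) and
refactorize otherwise; load is applied incrementally.

Internal force/stiffness units are N and mm (stresses in MPa); interface
pressures are reported in kPa as is conventional for plantar loads.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import labels as L
from . import materials as mat
from .meshing import FEMesh, TET10_EDGES, TET_FACES

GRAVITY = 9.81  # m/s^2


class ConvergenceError(RuntimeError):
    def __init__(self, message, increment=None, residual_history=None):
        super().__init__(message)
        self.increment = increment
        self.residual_history = residual_history or []


# ---------------------------------------------------------------------------
# load case (Eq.-style midstance scaling)
# ---------------------------------------------------------------------------

@dataclass
class LoadCase:
    """Scaled midstance ground reaction for one forefoot section."""

    grf_vertical: float                 # N
    zone_forces: np.ndarray             # (5,) N, medial -> lateral
    medial_force: float                 # N
    zone_boundaries: np.ndarray         # (4,) medio-lateral x, mm
    load_increments: int = 10

    def __post_init__(self):
        self.zone_forces = np.asarray(self.zone_forces, dtype=float)
        self.zone_boundaries = np.asarray(self.zone_boundaries, dtype=float)
        if abs(self.zone_forces.sum() - self.grf_vertical) > 1e-9 * max(
                self.grf_vertical, 1.0):
            raise ValueError("zone forces must sum to the vertical GRF")
        if self.medial_force < 0:
            raise ValueError("medial force must be >= 0")


#: per-zone multipliers of the mean forefoot load, medial to lateral
ZONE_MULTIPLIERS = np.array([1.05, 1.26, 1.06, 0.88, 0.75])
FOREFOOT_SHARE = 1.4
MEDIAL_BW_FRACTION = 0.05


def build_load_case(body_mass: float, section_length: float,
                    full_foot_length: float, mh_centers,
                    load_increments: int = 10) -> LoadCase:
    """Midstance vertical GRF scaled by section share, split across 5 zones.

    ``grf = m g (section/full) * 1.4``; zone i carries ``grf * m_i / 5``
    with multipliers (1.05, 1.26, 1.06, 0.88, 0.75) which average exactly
    one; the medial force is 5% of body weight.  Zone boundaries fall at
    midpoints between adjacent metatarsal head centres.
    """
    if full_foot_length <= 0 or section_length <= 0:
        raise ValueError("foot lengths must be > 0")
    if section_length > full_foot_length:
        raise ValueError("section_length cannot exceed full_foot_length")
    if body_mass <= 0:
        raise ValueError("body mass must be > 0")
    grf = body_mass * GRAVITY * (section_length / full_foot_length) * FOREFOOT_SHARE
    zones = grf * ZONE_MULTIPLIERS / 5.0
    mh = np.asarray(mh_centers, dtype=float)
    bounds = 0.5 * (mh[:-1] + mh[1:])
    return LoadCase(grf, zones, MEDIAL_BW_FRACTION * body_mass * GRAVITY,
                    bounds, load_increments)


@dataclass
class BoundarySpec:
    """Boundary-condition plan for the midstance model."""

    fixed_labels: tuple = L.METATARSALS      # bones held fixed (sesamoids free)
    cut_axis: int = 2                        # roller on both z cut planes
    friction_mu: float = 0.55
    contact: bool = True
    penalty_factor: float = 100.0            # contact stiffness scale


@dataclass
class SolverConfig:
    tol: float = 1e-6                 # relative residual
    max_iter: int = 30
    modified_newton: bool = True
    max_halvings: int = 3
    du_cap: float = 2.0               # trust region: max nodal step, mm
    verbose: bool = False


# ---------------------------------------------------------------------------
# TET10 reference element
# ---------------------------------------------------------------------------

# degree-2 positive rule: used for strain output and volume weighting
_QP4 = np.array([
    [0.58541019662496845, 0.13819660112501052, 0.13819660112501052],
    [0.13819660112501052, 0.58541019662496845, 0.13819660112501052],
    [0.13819660112501052, 0.13819660112501052, 0.58541019662496845],
    [0.13819660112501052, 0.13819660112501052, 0.13819660112501052],
])
_QW4 = np.full(4, 0.25)

# degree-3 5-point rule for assembly: rank-sufficient for TET10 (the 4-point
# rule leaves the element stiffness rank-marginal, which assembles into
# spurious soft modes under near-incompressible materials)
_QP5 = np.array([[0.25, 0.25, 0.25],
                 [0.5, 1 / 6, 1 / 6], [1 / 6, 0.5, 1 / 6],
                 [1 / 6, 1 / 6, 0.5], [1 / 6, 1 / 6, 1 / 6]])
_QW5 = np.array([-0.8, 0.45, 0.45, 0.45, 0.45])


def _tet10_dN(xi):
    """Shape-function gradients wrt reference coords at one point, (10, 3)."""
    x, y, z = xi
    l0 = 1.0 - x - y - z
    dl = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    lam = np.array([l0, x, y, z])
    dN = np.zeros((10, 3))
    for i in range(4):
        dN[i] = (4.0 * lam[i] - 1.0) * dl[i]
    for e, (a, b) in enumerate(TET10_EDGES):
        dN[4 + e] = 4.0 * (lam[a] * dl[b] + lam[b] * dl[a])
    return dN


_DN4 = np.stack([_tet10_dN(q) for q in _QP4])          # (4, 10, 3)
_DN5 = np.stack([_tet10_dN(q) for q in _QP5])          # (5, 10, 3)

# quadratic triangle (6 nodes: 3 corners + 3 midsides on edges 01,12,20)
_TRI_QP = np.array([[2 / 3, 1 / 6, 1 / 6], [1 / 6, 2 / 3, 1 / 6],
                    [1 / 6, 1 / 6, 2 / 3]])             # barycentric
_TRI_QW = np.full(3, 1.0 / 3.0)


def _tri6_N(lam):
    l1, l2, l3 = lam
    return np.array([l1 * (2 * l1 - 1), l2 * (2 * l2 - 1), l3 * (2 * l3 - 1),
                     4 * l1 * l2, 4 * l2 * l3, 4 * l3 * l1])


_TRI_N = np.stack([_tri6_N(q) for q in _TRI_QP])        # (3, 6)


# ---------------------------------------------------------------------------
# model: mesh + BCs + loads, ready to solve
# ---------------------------------------------------------------------------

@dataclass
class Model:
    """Assembled FE model (generic: tests build these directly)."""

    nodes: np.ndarray
    tets: np.ndarray
    region: np.ndarray
    material_of_element: list                 # material object per element
    fixed_dofs: np.ndarray                    # global dof indices, value 0
    prescribed: tuple = (np.zeros(0, dtype=int), np.zeros(0))  # (dofs, values)
    traction_faces: list = field(default_factory=list)
    # each entry: (face_nodes (F,6) int, traction (F,3) N/mm^2)
    contact: Optional[dict] = None            # see _build_contact
    f_ext_extra: Optional[np.ndarray] = None
    #: model-node -> source-mesh-node map (identity + duplicated copies)
    node_source: Optional[np.ndarray] = None

    @property
    def n_dofs(self):
        return 3 * len(self.nodes)


def _face_nodes_of(tets, elem, corner_triple):
    """Face node ids of a corner triple in an element.

    Six nodes (corners + midsides) for quadratic meshes, three for the
    linear fallback.
    """
    conn = tets[elem]
    loc = [int(np.nonzero(conn[:4] == c)[0][0]) for c in corner_triple]
    if tets.shape[1] == 4:
        return [conn[loc[0]], conn[loc[1]], conn[loc[2]]]
    edge_mid = {}
    for e, (a, b) in enumerate(TET10_EDGES):
        edge_mid[(a, b)] = 4 + e
        edge_mid[(b, a)] = 4 + e
    mids = [conn[edge_mid[(loc[0], loc[1])]], conn[edge_mid[(loc[1], loc[2])]],
            conn[edge_mid[(loc[2], loc[0])]]]
    return [conn[loc[0]], conn[loc[1]], conn[loc[2]]] + mids


def build_forefoot_model(mesh: FEMesh, library: mat.MaterialLibrary,
                         bcs: BoundarySpec, load: LoadCase) -> Model:
    """Split foot/shoe bodies, set up contact, BCs and sole-bottom tractions."""
    if not mesh.quadratic:
        pass  # linear fallback uses the same code paths with 4-node faces
    nodes = mesh.nodes.copy()
    tets = mesh.tets.copy()
    region = mesh.region

    faces, counts, owners = mesh.faces_with_counts()
    shoe_set = set(L.SHOE_BODY)
    foot_elems = np.isin(region, L.FOOT_BODY)
    shoe_elems = np.isin(region, L.SHOE_BODY)

    # contact interface faces: shared by one sock and one orthosis/upper element
    inter = counts == 2
    r0 = region[owners[inter, 0]]
    r1 = region[owners[inter, 1]]
    is_contact = (((r0 == L.SOCK) & np.isin(r1, (L.ORTHOSIS, L.UPPER)))
                  | ((r1 == L.SOCK) & np.isin(r0, (L.ORTHOSIS, L.UPPER))))
    cfaces = faces[inter][is_contact]
    cowners = owners[inter][is_contact]

    # duplicate every node shared between the two bodies; shoe keeps copies
    shoe_nodes = np.unique(tets[shoe_elems])
    foot_nodes = np.unique(tets[foot_elems])
    shared = np.intersect1d(shoe_nodes, foot_nodes)
    node_source = np.arange(len(nodes))
    dup_of = {}
    if len(shared):
        node_source = np.concatenate([node_source, shared])
        new_ids = np.arange(len(nodes), len(nodes) + len(shared))
        dup_of = dict(zip(shared.tolist(), new_ids.tolist()))
        nodes = np.vstack([nodes, nodes[shared]])
        remap = np.arange(len(nodes))
        remap[shared] = new_ids
        tets[shoe_elems] = remap[tets[shoe_elems]]

    contact = None
    if bcs.contact and len(cfaces):
        contact = _build_contact(nodes, tets, region, cfaces, cowners, dup_of,
                                 library, bcs)

    # Dirichlet: fixed bones + roller cut planes
    fixed_nodes = np.unique(tets[np.isin(region, bcs.fixed_labels)])
    fixed = np.concatenate([3 * fixed_nodes + c for c in range(3)])
    ax = bcs.cut_axis
    zlo, zhi = nodes[:, ax].min(), nodes[:, ax].max()
    tol = 1e-6 * max(1.0, zhi - zlo)
    cut_nodes = np.nonzero((np.abs(nodes[:, ax] - zlo) < tol)
                           | (np.abs(nodes[:, ax] - zhi) < tol))[0]
    fixed = np.unique(np.concatenate([fixed, 3 * cut_nodes + ax]))

    # sole-bottom traction faces: exterior, sole-owned, facing the ground
    ext = counts == 1
    sole_face_sel = ext & (region[owners[:, 0]] == L.SOLE)
    bfaces = faces[sole_face_sel]
    belems = owners[sole_face_sel, 0]
    cc = nodes[bfaces].mean(axis=1)
    nrm = np.cross(nodes[bfaces[:, 1]] - nodes[bfaces[:, 0]],
                   nodes[bfaces[:, 2]] - nodes[bfaces[:, 0]])
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    tc = nodes[tets[belems, :4]].mean(axis=1)
    inward = np.einsum("fi,fi->f", nrm, cc - tc) < 0
    nrm[inward] *= -1.0
    down = nrm[:, 1] < -0.9
    bfaces, belems, cc = bfaces[down], belems[down], cc[down]
    if len(bfaces) == 0:
        raise ValueError("no sole-bottom faces found to carry the ground reaction")

    areas = 0.5 * np.linalg.norm(
        np.cross(nodes[bfaces[:, 1]] - nodes[bfaces[:, 0]],
                 nodes[bfaces[:, 2]] - nodes[bfaces[:, 0]]), axis=1)
    # split each face's area across the zones by medio-lateral overlap so
    # zone totals are exact even when faces straddle zone boundaries
    x0 = nodes[bfaces][:, :, 0].min(axis=1)
    x1 = nodes[bfaces][:, :, 0].max(axis=1)
    edges = np.concatenate([[-np.inf], load.zone_boundaries, [np.inf]])
    frac = np.zeros((len(bfaces), 5))
    width = np.maximum(x1 - x0, 1e-12)
    for z in range(5):
        lo = np.maximum(x0, edges[z])
        hi = np.minimum(x1, edges[z + 1])
        frac[:, z] = np.clip(hi - lo, 0.0, None) / width
    frac /= np.maximum(frac.sum(axis=1, keepdims=True), 1e-12)
    zone_area = (areas[:, None] * frac).sum(axis=0)
    if np.any(zone_area <= 0):
        bad = int(np.argmin(zone_area)) + 1
        raise ValueError(f"load zone {bad} has no sole-bottom area")
    p_zone = load.zone_forces / zone_area                    # N/mm^2 upward
    traction = np.zeros((len(bfaces), 3))
    traction[:, 1] = frac @ p_zone
    traction[:, 0] = -load.medial_force / areas.sum()        # medial = -x

    face6 = np.array([_face_nodes_of(tets, e, f) for e, f in zip(belems, bfaces)])

    mats = [library[L.REGION_OF_LABEL[int(r)]] for r in region]
    return Model(nodes, tets, region, mats, fixed,
                 traction_faces=[(face6, traction)], contact=contact,
                 node_source=node_source)


def _build_contact(nodes, tets, region, cfaces, cowners, dup_of, library, bcs):
    """Conforming face-pair penalty contact data."""
    F = len(cfaces)
    nfn = 6 if tets.shape[1] == 10 else 3
    foot6 = np.zeros((F, nfn), dtype=np.int64)
    shoe6 = np.zeros((F, nfn), dtype=np.int64)
    normals = np.zeros((F, 3))
    areas = np.zeros(F)
    for i in range(F):
        e0, e1 = cowners[i]
        sock_e, shoe_e = (e0, e1) if region[e0] == L.SOCK else (e1, e0)
        fn = _face_nodes_of(tets, sock_e, cfaces[i])
        foot6[i] = fn
        shoe6[i] = [dup_of.get(int(n), int(n)) for n in fn]
        x = nodes[fn[:3]]
        nv = np.cross(x[1] - x[0], x[2] - x[0])
        a2 = np.linalg.norm(nv)
        areas[i] = 0.5 * a2
        n = nv / a2
        # orient from the shoe body toward the sock
        shoe_c = nodes[tets[shoe_e, :4]].mean(axis=0)
        if np.dot(n, x.mean(axis=0) - shoe_c) < 0:
            n = -n
        normals[i] = n

    orth = library["orthosis"]
    mu0 = getattr(orth, "mu", 144.0) * 1e-3        # MPa
    h = np.sqrt(max(np.mean(areas), 1e-12))
    kn = bcs.penalty_factor * 2.0 * mu0 / h        # MPa/mm
    return {
        "foot": foot6, "shoe": shoe6, "normal": normals, "area": areas,
        "kn": kn, "kt": kn / 10.0, "mu": bcs.friction_mu,
        "delta0": 0.05 * h, "k_reg": 1e-4 * kn,
        "shoe_region": region[[cowners[i, 1] if region[cowners[i, 0]] == L.SOCK
                               else cowners[i, 0] for i in range(F)]],
        "slip": np.zeros((F, 3, 3)),               # plastic slip per face qp
    }


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

class _Kinematics:
    """Precomputed affine element data and material grouping."""

    def __init__(self, model: Model, rule: str = "assembly"):
        nodes, tets = model.nodes, model.tets
        X = nodes[tets[:, :4]]
        J = np.transpose(X[:, 1:] - X[:, :1], (0, 2, 1))       # (E,3,3) columns
        self.detJ = np.linalg.det(J)
        if np.any(self.detJ <= 0):
            raise mat.ElementInversionError("inverted reference element",
                                            int(np.argmin(self.detJ)))
        Jinv = np.linalg.inv(J)
        if tets.shape[1] == 10:
            dN_ref, qw = (_DN5, _QW5) if rule == "assembly" else (_DN4, _QW4)
            self.dN = np.einsum("qak,ekj->qeaj", dN_ref, Jinv)  # (nqp,E,10,3)
            self.qw = qw
        else:
            dn1 = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
            self.dN = np.einsum("ak,ekj->eaj", dn1, Jinv)[None]
            self.qw = np.array([1.0])
        # groups by identical material object; elements whose every dof is
        # constrained (fixed bones) never strain and are skipped entirely
        fixed_mask = np.zeros(model.n_dofs, dtype=bool)
        fixed_mask[model.fixed_dofs] = True
        node_fully_fixed = fixed_mask.reshape(-1, 3).all(axis=1)
        skip = node_fully_fixed[tets].all(axis=1)
        groups = {}
        for e, m in enumerate(model.material_of_element):
            if skip[e]:
                continue
            groups.setdefault(id(m), (m, []))[1].append(e)
        self.groups = [(m, np.asarray(ix)) for m, ix in groups.values()]
        self.sparsity = None


def _internal_forces(model, kin, u, want_tangent):
    """Internal force vector, optional element stiffness blocks, qp strains."""
    tets = model.tets
    nn = tets.shape[1]
    E_el = len(tets)
    nqp = kin.dN.shape[0]
    ue = u.reshape(-1, 3)[tets]                               # (E, nn, 3)
    f_el = np.zeros((E_el, nn, 3))
    K_el = np.zeros((E_el, 3 * nn, 3 * nn)) if want_tangent else None
    strains = np.zeros((nqp, E_el, 3, 3))
    eye = np.eye(3)
    for q in range(nqp):
        G = kin.dN[q]                                          # (E, nn, 3)
        F = eye + np.einsum("eai,eaJ->eiJ", ue, G)
        for m, ix in kin.groups:
            Fg = F[ix]
            S_kpa, C_kpa = mat.stress_and_tangent(m, Fg)
            S = S_kpa * 1e-3
            P = np.einsum("eiM,eMJ->eiJ", Fg, S)
            w = (kin.qw[q] * kin.detJ[ix] / 6.0)
            f_el[ix] += w[:, None, None] * np.einsum("eaJ,eiJ->eai", G[ix], P)
            if want_tangent:
                CC = C_kpa * 1e-3
                A = (np.einsum("ik,eJL->eiJkL", eye, S)
                     + np.einsum("eiM,eMJNL,ekN->eiJkL", Fg, CC, Fg,
                                 optimize=True))
                Ke = np.einsum("eaJ,eiJkL,ebL->eaibk", G[ix], A, G[ix],
                               optimize=True)
                K_el[ix] += w[:, None, None] * Ke.reshape(len(ix), 3 * nn, 3 * nn)
            Eg = 0.5 * (np.einsum("ekI,ekJ->eIJ", Fg, Fg) - eye)
            strains[q, ix] = Eg
    return f_el, K_el, strains


def _contact_forces(model, u, want_tangent, update_state=False):
    """Penalty-contact internal forces, stiffness blocks and qp tractions.

    The normal law is a C1 quadratic-ramp penalty (stiffness grows linearly
    over a transition depth ``delta0``); friction is a smooth-saturation
    regularized Coulomb law ``t = mu p v / sqrt(|v|^2 + (mu p)^2)`` with
    ``v = kt (s - s_p)``, so ``|t| < mu p`` holds at every point by
    construction.  A weak tether spring (``k_reg``) ties the surfaces and
    suppresses the shoe body's rigid modes before load develops.  All
    branches are smooth, which keeps Newton iterations stable.
    """
    c = model.contact
    F = len(c["foot"])
    nfn = c["foot"].shape[1]                   # 6 (quadratic) or 3 (linear)
    nqp = len(_TRI_QW)
    uf = u.reshape(-1, 3)
    fe = np.zeros((F, 2 * nfn, 3))
    Ke = np.zeros((F, 6 * nfn, 6 * nfn)) if want_tangent else None
    pressures = np.zeros((F, nqp))
    tangents = np.zeros((F, nqp))
    kn, kt, mu = c["kn"], c["kt"], c["mu"]
    d0 = c["delta0"]
    k_reg = c["k_reg"]
    n = c["normal"]                                            # (F,3)
    new_slip = c["slip"].copy()
    eye = np.eye(3)
    for q in range(nqp):
        N = _TRI_N[q] if nfn == 6 else _TRI_QP[q]              # (nfn,)
        d = (np.einsum("a,fai->fi", N, uf[c["shoe"]])
             - np.einsum("a,fai->fi", N, uf[c["foot"]]))       # shoe - foot
        dn = np.einsum("fi,fi->f", d, n)
        # C1 ramp with a 5% stiffness floor: p rises quadratically over the
        # transition depth d0; the floor keeps the closed interface from
        # being numerically free at first load application
        dnp = np.maximum(dn, 0.0)
        inside = dnp < d0
        eps_f = 0.05
        p = np.where(inside,
                     kn * (dnp**2 / (2.0 * d0) + eps_f * dnp),
                     kn * ((1.0 + eps_f) * dnp - d0 / 2.0))
        dp = np.where(dn >= 0.0,
                      np.where(inside, kn * (dnp / d0 + eps_f),
                               kn * (1.0 + eps_f)),
                      0.0)
        s_t = d - dn[:, None] * n
        v = kt * (s_t - c["slip"][:, q])
        vn = np.linalg.norm(v, axis=1)
        mp = mu * p
        r = np.sqrt(vn**2 + mp**2) + 1e-30
        t = (mp / r)[:, None] * v
        if update_state:
            # keep the elastic part of the slip displacement
            new_slip[:, q] = s_t - t / kt
        sigma = p[:, None] * n + t + k_reg * d                 # traction on foot
        wA = _TRI_QW[q] * c["area"]
        # e-vector: -N on foot nodes, +N on shoe nodes
        ev = np.concatenate([-N, N])                           # (2 nfn,)
        fe += (wA[:, None] * sigma)[:, None, :] * ev[None, :, None]
        pressures[:, q] = p * 1e3                              # kPa
        tangents[:, q] = np.linalg.norm(t, axis=1) * 1e3
        if want_tangent:
            P_t = eye[None] - np.einsum("fi,fj->fij", n, n)
            D = dp[:, None, None] * np.einsum("fi,fj->fij", n, n)
            D = D + k_reg * eye[None]
            # dt/dv and dt/dp terms of the smooth friction law
            Dv = (mp / r)[:, None, None] * (
                P_t - np.einsum("fi,fj->fij", v, v) / (r**2)[:, None, None])
            D = D + kt * np.einsum("fik,fkj->fij", Dv, P_t)
            dt_dp = (mu * vn**2 / r**3)[:, None] * v
            D = D + np.einsum("fi,f,fj->fij", dt_dp, dp, n)
            block = np.einsum("a,b,fij->faibj", ev, ev, D).reshape(
                F, 6 * nfn, 6 * nfn)
            Ke += wA[:, None, None] * block
    if update_state:
        c["slip"] = new_slip
    return fe, Ke, pressures, tangents


def _assemble(model, kin, u, want_tangent=True):
    nn = model.tets.shape[1]
    f_el, K_el, strains = _internal_forces(model, kin, u, want_tangent)
    fint = np.zeros(model.n_dofs)
    dofs = (3 * model.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(
        len(model.tets), 3 * nn)
    np.add.at(fint, dofs.ravel(), f_el.reshape(len(model.tets), -1).ravel())
    vals = K_el.ravel() if want_tangent else None
    cp = ct = None
    if model.contact is not None:
        fe, Ke, cp, ct = _contact_forces(model, u, want_tangent)
        cd = np.concatenate([model.contact["foot"], model.contact["shoe"]],
                            axis=1)                            # (F, 2 nfn)
        cdofs = (3 * cd[:, :, None] + np.arange(3)[None, None, :]).reshape(
            len(cd), 3 * cd.shape[1])
        np.add.at(fint, cdofs.ravel(), fe.reshape(len(cd), -1).ravel())
        if want_tangent:
            vals = np.concatenate([vals, Ke.ravel()])
    K = None
    if want_tangent:
        # the sparsity pattern is fixed; sort/merge it once and afterwards
        # rebuild the CSR data array with a single bincount
        if kin.sparsity is None:
            rows = np.repeat(dofs, 3 * nn, axis=1).ravel()
            cols = np.tile(dofs, (1, 3 * nn)).ravel()
            if model.contact is not None:
                w = cdofs.shape[1]
                rows = np.concatenate([rows,
                                       np.repeat(cdofs, w, axis=1).ravel()])
                cols = np.concatenate([cols,
                                       np.tile(cdofs, (1, w)).ravel()])
            key = rows.astype(np.int64) * model.n_dofs + cols
            order = np.argsort(key, kind="stable")
            skey = key[order]
            new = np.ones(len(skey), dtype=bool)
            new[1:] = skey[1:] != skey[:-1]
            uk = skey[new]
            pos = np.searchsorted(uk, key)
            indptr = np.searchsorted(uk // model.n_dofs,
                                     np.arange(model.n_dofs + 1), side="left")
            indices = (uk % model.n_dofs).astype(np.int32)
            kin.sparsity = (pos, indices, indptr, len(uk))
        pos, indices, indptr, nnz = kin.sparsity
        data = np.bincount(pos, weights=vals, minlength=nnz)
        K = sp.csr_matrix((data, indices, indptr),
                          shape=(model.n_dofs, model.n_dofs))
    return fint, K, strains, (cp, ct)


def external_forces(model: Model) -> np.ndarray:
    """Consistent nodal loads of the configured face tractions (dead loads)."""
    f = np.zeros(model.n_dofs)
    for face6, trac in model.traction_faces:
        x = model.nodes[face6[:, :3]]
        areas = 0.5 * np.linalg.norm(
            np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]), axis=1)
        if face6.shape[1] == 6:
            # exact for straight quadratic triangles: corners get zero weight
            wgt = np.array([0.0, 0, 0, 1 / 3, 1 / 3, 1 / 3])
        else:
            wgt = np.full(face6.shape[1], 1.0 / face6.shape[1])
        for a in range(face6.shape[1]):
            np.add.at(f.reshape(-1, 3), face6[:, a],
                      (areas * wgt[a])[:, None] * trac)
    if model.f_ext_extra is not None:
        f += model.f_ext_extra
    return f


# ---------------------------------------------------------------------------
# result container and Newton driver
# ---------------------------------------------------------------------------

@dataclass
class SolveResult:
    model: Model
    u: np.ndarray                          # (n_nodes*3,)
    strains: np.ndarray                    # (nqp, E, 3, 3) Green-Lagrange
    qp_volumes: np.ndarray                 # (nqp, E) reference volume weights
    qp_z: np.ndarray                       # (nqp, E) qp axial position (mm)
    contact_pressure: Optional[np.ndarray]  # (F, 3) kPa
    contact_tangent: Optional[np.ndarray]   # (F, 3) kPa
    contact_area: Optional[np.ndarray]      # (F,) mm^2 (per face)
    contact_xz: Optional[np.ndarray]        # (F, 3, 2) qp plan positions
    contact_region: Optional[np.ndarray]    # (F,) shoe-side label
    contact_normal: Optional[np.ndarray]    # (F, 3)
    reactions: np.ndarray                  # residual at constrained dofs (N)
    f_ext: np.ndarray
    log: list = field(default_factory=list)

    @property
    def region(self):
        return self.model.region

    def displacement_field(self):
        return self.u.reshape(-1, 3)


def interpolate_displacement(src_model: Model, src_u: np.ndarray,
                             dst_nodes: np.ndarray) -> np.ndarray:
    """Inverse-distance interpolation of a nodal field onto new nodes.

    Used to warm-start refined meshes from a coarser solution in the mesh
    convergence harness; accuracy only needs to be good enough to land the
    Newton iteration inside its basin of attraction.
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(src_model.nodes)
    dist, idx = tree.query(dst_nodes, k=6)
    w = 1.0 / np.maximum(dist, 1e-9) ** 2
    w /= w.sum(axis=1, keepdims=True)
    uf = src_u.reshape(-1, 3)
    return (uf[idx] * w[..., None]).sum(axis=1).ravel()


def solve(model: Model, config: SolverConfig = None,
          load_increments: int = 10, u0: Optional[np.ndarray] = None
          ) -> SolveResult:
    """Incremental-load Newton solution of the assembled model.

    ``u0`` warm-starts the iteration (e.g. a solution interpolated from a
    coarser mesh); combine with ``load_increments=1``.
    """
    cfg = config or SolverConfig()
    kin = _Kinematics(model)
    f_ext = external_forces(model)
    n = model.n_dofs
    fixed = np.unique(np.concatenate([model.fixed_dofs, model.prescribed[0]]))
    free = np.setdiff1d(np.arange(n), fixed)
    u = np.zeros(n)
    if u0 is not None:
        u = u0.copy()
        u[fixed] = 0.0
    if len(model.prescribed[0]):
        presc_d, presc_v = model.prescribed
    else:
        presc_d, presc_v = np.zeros(0, dtype=int), np.zeros(0)

    log = []
    fref = max(np.linalg.norm(f_ext[free]), 1e-8)
    lam_done = 0.0
    dlam = 1.0 / max(load_increments, 1)
    halvings = 0
    lu = None
    t_start = time.time()
    while lam_done < 1.0 - 1e-12:
        lam = min(1.0, lam_done + dlam)
        u_save = u.copy()
        hist = []
        converged = False
        refactor = True
        res_prev = np.inf
        r0_inc = None
        try:
            for it in range(cfg.max_iter):
                fint, K, strains, (cp, ct) = _assemble(model, kin, u,
                                                       want_tangent=refactor)
                r = fint - lam * f_ext
                rnorm = np.linalg.norm(r[free])
                du_p = (lam * presc_v - u[presc_d]) if len(presc_d) else None
                at_target = du_p is None or np.abs(du_p).max() < 1e-14
                # force-driven: scale by applied load; displacement-driven:
                # scale by the first out-of-balance force after applying the
                # prescribed step
                if fref > 1e-8:
                    denom = fref * lam
                else:
                    if at_target and r0_inc is None:
                        r0_inc = max(rnorm, 1e-12)
                    denom = max(r0_inc if r0_inc is not None else rnorm,
                                1e-12)
                res = rnorm / denom
                hist.append(rnorm)
                if cfg.verbose:
                    print(f"  lam={lam:.3f} it={it} rel={res:.3e} "
                          f"t={time.time() - t_start:.0f}s", flush=True)
                if res < cfg.tol and at_target:
                    converged = True
                    break
                if refactor or not at_target:
                    if K is None:
                        _, K, _, _ = _assemble(model, kin, u, want_tangent=True)
                    Kff = K[free][:, free].tocsc()
                    # symmetric Jacobi scaling tames the stiffness contrast
                    # (penalty bulk vs soft shear) before factorization
                    dscale = np.sqrt(np.maximum(Kff.diagonal(), 1e-30))
                    Dinv = sp.diags(1.0 / dscale)
                    Ks = (Dinv @ Kff @ Dinv).tocsc()
                    Kfp = K[free][:, presc_d] if not at_target else None
                    K = Kff = None      # release before the memory-peak LU
                    lu = spla.splu(Ks, permc_spec="MMD_AT_PLUS_A",
                                   options=dict(SymmetricMode=True,
                                                DiagPivotThresh=0.1))
                    Ks = None
                rhs = -r[free]
                if not at_target:
                    rhs = rhs - Kfp @ du_p
                du = lu.solve(rhs / dscale) / dscale
                if not at_target:
                    # prescribed-displacement application: full step
                    u[free] += du
                    u[presc_d] += du_p
                    alpha = 1.0
                else:
                    # trust region + backtracking on the free-dof residual
                    du_max = np.abs(du).max()
                    alpha = min(1.0, cfg.du_cap / max(du_max, 1e-30))
                    best = (None, np.inf)
                    for _ in range(8):
                        u_try = u.copy()
                        u_try[free] += alpha * du
                        try:
                            f_try, _, _, _ = _assemble(model, kin, u_try,
                                                       want_tangent=False)
                        except mat.ElementInversionError:
                            alpha *= 0.5
                            continue
                        r_try = np.linalg.norm((f_try - lam * f_ext)[free])
                        if r_try < best[1]:
                            best = (u_try, r_try)
                        # mildly nonmonotone acceptance: small transient
                        # growth is tolerated, larger growth is damped
                        if r_try < 1.2 * rnorm or alpha < 0.02:
                            break
                        alpha *= 0.5
                    if best[0] is None:
                        raise mat.ElementInversionError(
                            "line search failed to find an evaluable state")
                    u = best[0]
                if cfg.modified_newton:
                    refactor = not (res < 0.6 * res_prev)
                res_prev = res
        except mat.ElementInversionError:
            converged = False
        if not converged:
            u = u_save
            halvings += 1
            if halvings > cfg.max_halvings:
                raise ConvergenceError(
                    f"Newton failed at load factor {lam:.3f}", lam, hist)
            dlam *= 0.5
            continue
        # accept increment: update the frictional state for the next one
        # (kept untouched after the final increment so the reported contact
        # tractions are exactly the converged ones)
        if model.contact is not None and lam < 1.0 - 1e-12:
            _contact_forces(model, u, want_tangent=False, update_state=True)
        log.append({"lambda": lam, "iterations": len(hist), "residuals": hist,
                    "time_s": time.time() - t_start})
        lam_done = lam

    fint, _, _, (cp, ct) = _assemble(model, kin, u, want_tangent=False)
    reactions = fint - f_ext
    # output pass on the positive-weight rule (volume-consistent weights)
    kin_out = _Kinematics(model, rule="output")
    _, _, strains = _internal_forces(model, kin_out, u, want_tangent=False)
    qw = kin_out.qw[:, None] * kin_out.detJ[None, :] / 6.0
    # qp axial positions
    if model.tets.shape[1] == 10:
        lam_q = np.hstack([(1 - _QP4.sum(axis=1))[:, None], _QP4])
    else:
        lam_q = np.full((1, 4), 0.25)
    Xc = model.nodes[model.tets[:, :4]]
    qp_xyz = np.einsum("qa,eai->qei", lam_q, Xc)
    c = model.contact
    if c is not None:
        Nm = _TRI_N if c["foot"].shape[1] == 6 else _TRI_QP
        xz = np.einsum("qa,fai->fqi", Nm, model.nodes[c["foot"]])[:, :, [0, 2]]
        res = SolveResult(model, u, strains, qw, qp_xyz[..., 2], cp, ct,
                          c["area"], xz, c["shoe_region"], c["normal"],
                          reactions, f_ext, log)
    else:
        res = SolveResult(model, u, strains, qw, qp_xyz[..., 2], None, None,
                          None, None, None, None, reactions, f_ext, log)
    return res


# ---------------------------------------------------------------------------
# checks used by the validation suite
# ---------------------------------------------------------------------------

def equilibrium_check(result: SolveResult) -> dict:
    """Reaction/applied force balance and contact load-path integrals."""
    model = result.model
    fixed = np.unique(np.concatenate([model.fixed_dofs, model.prescribed[0]])) \
        if len(model.prescribed[0]) else model.fixed_dofs
    R = result.reactions.reshape(-1, 3)
    mask = np.zeros(model.n_dofs, bool)
    mask[fixed] = True
    mask = mask.reshape(-1, 3)
    reac = np.where(mask, R, 0.0).sum(axis=0)
    applied = result.f_ext.reshape(-1, 3).sum(axis=0)
    out = {"applied": applied, "reaction": reac,
           "imbalance": applied + reac}
    if result.contact_pressure is not None:
        c = result.model.contact
        w = result.contact_area[:, None] * _TRI_QW[None, :]
        # normal-pressure part of the interface load
        nrm = result.contact_normal
        f_n = (result.contact_pressure * 1e-3 * w)[:, :, None] * nrm[:, None, :]
        out["contact_normal_force"] = f_n.sum(axis=(0, 1))
        out["contact_normal_total"] = float(
            (result.contact_pressure * 1e-3 * w).sum())
        # full traction integral transmitted to the foot (normal + friction
        # + tether): the load-path check against the applied GRF
        fe, _, _, _ = _contact_forces(model, result.u, want_tangent=False)
        nfn = c["foot"].shape[1]
        out["contact_force_total"] = -fe[:, :nfn, :].sum(axis=(0, 1))
    return out


def coulomb_check(result: SolveResult) -> float:
    """Max of ||t_tangential|| - mu p over contact points (<= 0 is admissible)."""
    c = result.model.contact
    if c is None or result.contact_pressure is None:
        return 0.0
    return float((result.contact_tangent - c["mu"] * result.contact_pressure)
                 .max())
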