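# Methods

`forefem` computes internal tissue loading in a shod forefoot fitted with a
total-contact orthosis, under a static midstance ground reaction, and turns
the solutions into four damage-risk metrics plus a cohort-level correlation
screen. This note describes the models, the numerical choices, and what the
synthetic phantoms do and do not emulate.

## Geometry: parametric voxel phantoms

A `PhantomSpec` replaces MR segmentation with a parametric construction on
an isotropic voxel grid (x medial→lateral, y plantar→dorsal, z
proximal→distal). Five metatarsals are capsule shafts fused to spherical
heads and short phalanx stubs (the second ray most distal, mimicking the
metatarsal parabola). Two sesamoids sit plantar to the first metatarsal
head (MH1); the medial sesamoid's medial edge is placed at
`sesamoid_offset_frac` of the voxelized MH1 width from MH1's medial edge,
so the construct-then-measure round trip closes to within a voxel. The MH1
head carries a medial-plantar sector shaped by a sphere of radius
`mh1_medial_plantar_radius`, tangent to the head sphere along the
medial-plantar diagonal and blended smoothly (no crease) between 72° and
95° from that diagonal; the sector's surface curvature is therefore the
reciprocal of the requested radius. The MH1 neck thins with a sharp head so
the sector surface is not undercut by the shaft inside the measured zone.

The soft-tissue envelope is a variable-radius dilation of the bones
(Euclidean distance transform): the pad under MH1 is chosen numerically so
the plantar distance from the lowest MH1 voxel to the outer skin surface
equals `tissue_depth_mh1` exactly; away from MH1 the pad relaxes to
`base_pad` over a Gaussian with width 1.2 R(MH1). The skin is a
uniform-thickness Euclidean shell around the tissue.

Dressing follows the modelling protocol of the source imaging pipeline: a
sock as an in-plane (coronal-slice) dilation shell of the foot surface
(default 2 mm), a flat-topped sole whose top plane sits `orthosis_min`
(default 3 mm) below the lowest sock voxel, a total-contact orthosis
filling the gap between that plane and the sock plantar surface (so the
minimum orthosis thickness is exactly the configured value and concavities
are filled), a 6 mm sole slab, and a 3 mm upper shell around the sock. The
shoe edge geometry beyond the sock footprint is a simple extrusion — how a
real upper wraps the last is not modelled.

**Morphometrics.** Tissue depth and sesamoid offset are read directly from
the label map (voxel-level accuracy, ±1–2 voxels in tests). MH1 curvature
follows the mesh-based estimate: marching cubes on the lightly smoothed MH1
mask (σ = 1 voxel), outward orientation, selection of the head zone
(|z − z_head| ≤ 0.45 of the head's equivalent radius, with z_head at the
maximum cross-section) and of the medial-plantar quarter by centroid
splits in x and y, then per-vertex height-field quadrics over neighbours
within three median edge lengths; the area-weighted mean of (κ₁+κ₂)/2 is
reported. Spheres and cylinders are recovered within 5%, phantom round
trips within 10% for medial-plantar radii between ~0.75 and ~1.5 head
radii (the anatomically relevant range).

## Meshing: balanced octree lattices

`label_to_mesh` builds a 2:1-balanced octree over the voxel map with
per-region target edge lengths; cells refine until they satisfy the
strictest region they intersect. Leaves are tetrahedralized with conforming
templates: interior cells by the Kuhn 6-tet split (whose face diagonals
coincide with the canonical min-corner diagonal rule used globally), cells
adjacent to finer neighbours by face triangulation + coning to the cell
centroid. Meshes are conforming across level transitions without hanging
nodes; midside nodes make every element an affine 10-node tetrahedron. Base
cells are mildly anisotropic in z so the lattice ends exactly on the
proximal/distal cut planes, and the lattice is shifted vertically so a cell
boundary coincides with the flat sole bottom (flat traction surface and cut
cross-sections by construction). Element region labels come from a
five-point majority vote against the voxel map; regions thinner than the
requested edge length raise an error unless explicitly exempted (fixed
bones may be represented coarsely — they carry no strain field).

`subdivide` performs nested red 1:8 refinement on fixed geometry (every
tet split through its edge midpoints) and returns an embedding operator
for warm-starting the refined solve; `refine(factor)` rebuilds the lattice
with all targets divided by the factor.

## Constitutive models

All stresses in kPa, lengths in mm. Skin and bulk soft tissue use a
one-term Ogden law written with the μ/α prefactor,

  W = (μ/α)(λ₁^α + λ₂^α + λ₃^α − 3) − μ ln J + (K/2)(J − 1)²,

where the −μ ln J term makes the reference state stress-free for the
printed power term and K = 1000 μ (configurable) enforces
near-incompressibility (effective Poisson ratio ≈ 0.499); in the
incompressible limit the uniaxial response is exactly
σ = μ(λ^α − λ^(−α/2)). The orthosis and sole foams use the Storakers law

  W = (2μ/α²)(λ₁^α + λ₂^α + λ₃^α − 3 + (J^(−αβ) − 1)/β),

whose volumetric term is written in the standard form that vanishes at the
reference state. Shoe upper, sock and bone are linear elastic, evaluated
as St. Venant–Kirchhoff so they remain objective under finite rotations.
Default constants (shear-modulus/exponent pairs for the hyperelastic
materials, E/ν for the linear ones) are shipped as the standard material
table and serializable as YAML.

Stress and tangent are evaluated in the principal basis of C = FᵀF:
S = Σ (1/λₐ)(∂W/∂λₐ) Nₐ⊗Nₐ, with the standard isotropic elasticity tensor
assembled from ∂²W/∂λ∂λ and the (Sᵦ−Sₐ)/(λᵦ²−λₐ²) shear coefficients,
including the analytic coincident-stretch limit. The tangent is exact
(finite-difference checks to ~1e-10 relative in the tests).

## Midstance load case and boundary conditions

The vertical ground reaction is the body-weight share carried by the
modelled section at midstance: grf = m g (section/full foot length) × 1.4,
distributed across five medio-lateral zones (boundaries at midpoints
between metatarsal head centres) with multipliers 1.05/1.26/1.06/0.88/0.75
of the mean (they sum to exactly 5, conserving the total); a medial force
of 5% body weight acts over the same sole-bottom faces (medial = −x).
Tractions are applied to downward-facing exterior sole faces, with each
face's area split across the zones by medio-lateral overlap so zone totals
are exact even when faces straddle zone boundaries. Metatarsals are fixed
(they are effectively grounded through the midfoot), sesamoids deform
freely within the tissue, the cut planes carry rollers (zero normal
displacement), and bones–tissue–skin–sock respectively orthosis–sole–upper
are bonded (shared nodes).

## Contact

The sock exterior and the orthosis top / upper interior form a frictional
interface (static coefficient 0.55). The voxel lattice makes the two sides
conforming, so contact is integrated at three points per facet pair after
duplicating the interface nodes (the model splits into a foot body and a
shoe body coupled only through contact). The normal law is a C¹
quadratic-ramp penalty: stiffness grows linearly from a 5% floor to
kn = 50·2μ₀(orthosis)/h over a transition depth of 0.05 h (h = mean facet
size); penetrations stay below ~2% of the facet size at working loads.
Friction uses the smooth-saturation regularization
t = μp·v/√(|v|²+(μp)²) with elastic driver v = kt(s − s_p), kt = kn/10 and
the plastic slip s_p updated at increment ends; ‖t‖ < μp holds pointwise by
construction, and stick is approximated with a small elastic creep. A weak
tether spring (10⁻⁴ kn) ties the surfaces so the shoe body has no rigid
modes before load develops. All branches are smooth with exact tangents,
which keeps Newton stable; the earlier discrete return-map formulation
produced bit-exact active-set limit cycles.

## Solver

Total-Lagrangian Newton with incremental loading (adaptive halving),
backtracking line search, and modified-Newton reuse of the factorized
tangent while convergence is fast. Assembly integrates TET10 elements with
a degree-3 five-point rule — the common four-point rule leaves the element
rank-marginal and assembles into spurious soft modes once the
incompressibility penalty dominates — while strain output and volume
weights use the positive-weight four-point rule. Linear systems are solved
with SuperLU after symmetric Jacobi scaling (the stiffness diagonal spans
six decades between penalty and soft-shear terms; unscaled factorizations
pivot-thrash) under minimum-degree ordering. Prescribed displacements are
applied through consistent elimination (the increment enters via the
tangent system, not by state injection). Convergence is declared at 1e-6
relative residual (force-driven: relative to the applied load;
displacement-driven: relative to the increment's initial out-of-balance
force). Solutions are deterministic; reruns reproduce metrics bitwise.

## Damage metrics

From a converged solution: (1) the volume-weighted 99th percentile of the
maximum shear strain γ = (E_I − E_III)/2 over soft tissue and skin
quadrature points (tensorial shear from principal Green–Lagrange strains,
in %); (2) the tissue volume strictly above 10% shear; (3) the 99th
percentile of plantar pressure; (4) the maximum pressure gradient.
Pressures are taken from the orthosis-side contact facets, weighted by
plan-projected areas, resampled to a regular 5×5 mm grid (the resolution of
in-shoe pressure sensors), with cells within one cell of the section's cut
edges excluded; the pressure percentile is evaluated over the grid cells
weighted by covered area. This sensor-resolution estimator is deliberate:
pointwise penalty pressures on a faceted voxel interface carry
mesh-resolution corner artefacts and do not converge under refinement,
whereas cell averages do and match what the experimental instrument
reports. The gradient is the maximum |Δp|/distance over the
8-neighbourhood of valid cells. Percentiles use weighted empirical-CDF
inversion (the smallest value whose cumulative weight fraction reaches the
level); an interpolating variant was considered and rejected to keep the
estimator exactly reproducible against its sorting oracle.

## Cohort generation and statistics

Covariates (BMI, height, disease duration, LFIS-IF, instance counts,
tissue depth, sesamoid offset, MH1 curvature) are sampled through a
Gaussian copula whose normal-score correlations are set from target rank
correlations (2 sin(πρ/6)); defaults emulate the observed structure of
small RA forefoot cohorts — duration correlates +0.7 with sesamoid offset
and −0.72 offset-with-depth — with everything else independent. Geometry
parameters scale multiplicatively around the template phantom, so cohorts
can be generated at any template scale. The statistical screen applies
Shapiro–Wilk gates (α = 0.05) per variable, Pearson where both variables
pass and Spearman otherwise, pairwise-complete handling of missing data,
median/IQR summaries, and rank-in-cohort placement of an optional
reference subject (ties share rank, flagged '='). No multiple-testing
correction by default (a Benjamini–Hochberg option exists), matching the
exploratory character of such screens.

## The fixture phantom and problem sizes

FE validation (convergence, equilibrium, ordering sweeps, cut-edge
sensitivity) runs on a packaged reduced-scale fixture: 0.3-scale skeleton
(MH1 radius 2.7 mm, section 12 mm), worn layers proportionally thickened
(skin, sock, upper and minimum orthosis 4 mm; sole 6 mm) so one element
spans each layer at the working density, voxel 1.5 mm, body mass 14 kg,
and the plantar-pressure sensor grid scaled to 2 mm cells.
The mass keeps peak tissue shear in the 10–20% band the metrics are
designed for while staying safely below the sole-edge foam buckling load
(~20 kg for this miniature, identified by tangent eigenanalysis). The
density ladder is 5.0 and 4.0 mm lattices plus one nested 1:8 subdivision
of the 4.0 mm working mesh (effective 2.0 mm, identical discretized
geometry, warm-started from the embedded coarse solution) — on faceted
voxel geometry, comparing across *lattice* densities confounds FE error
with geometry-representation changes, so the convergence bound is judged
on the nested pair. Working meshes are ~2×10³ elements (~10⁴ nodes), the
subdivided level ~1.8×10⁴ elements (~9×10⁴ unknowns); a full ladder
solves in roughly a quarter of an hour on one CPU.

The study's outcome should be read plainly: at these affordable
resolutions the percentile metrics are *not* mesh-converged — the nested
halving still moves the 99th-percentile shear strain and plantar pressure
by tens of percent, because the strain concentration under MH1 spans only
one or two elements at the working density and the voxel-faceted bone
surfaces keep refining into their own corners. Converging such fields to a
few percent would need roughly millimetre elements across the plantar pad
(order 10⁶ unknowns), beyond what a pure-Python direct solver can
factorize in this footprint. The harness therefore does two jobs: it runs
the selection protocol end to end, and it quantifies honestly how far from
convergence a desk-scale model of this kind operates. Same-mesh
comparisons (parameter sweeps, cut-edge sensitivity, equilibrium,
admissibility) are unaffected by this caveat, which is why the ordering
studies pin their conclusions to a fixed working mesh.

What passing these tests shows — and does not. The fixture exercises every
model ingredient (all materials, contact with friction, the full load
model) at realistic strain levels, so equilibrium,
admissibility and monotonicity results transfer qualitatively. It does not
establish absolute metric values for human-scale anatomy: the miniature's
pressures are higher and its layer proportions differ from clinical
geometry, and the phantom omits bursae, joint detail, and loaded-posture
tissue redistribution, as any simplified bulk-tissue model does.

Two further desk-scale limits surfaced by the validation harness deserve
naming. First, the cut-edge sensitivity protocol (extend the section with
the subject's foot length fixed, compare metrics in a distal region of
interest on a bit-identically discretized lattice) *detects* boundary
influence on the 12 mm fixture section: ROI pressure percentiles move by
tens of percent when the proximal cut recedes. That is the protocol doing
its job — a 12 mm section places the cut ~7 mm from MH1 — but the section
length is pinned by the memory budget of the nested convergence level, so
the fixture knowingly operates inside its cut's influence zone. Second,
MH1-curvature sweeps are not resolvable on the miniature: ±30–50% radius
changes displace the bone surface by ~0.2 mm against 1.5 mm voxels, so the
voxelized geometry barely changes while inter-phantom discretization noise
moves the metrics by ±10–20%; curvature ordering studies require
clinical-scale resolution. Mass (BMI) ordering, by contrast, compares
identical geometry under scaled load and is robust at fixture scale.

## Known limitations

* Static midstance only; no toe-off, no dynamic gait, no pressure–time
  integrals.
* Bones other than the sesamoids are rigid and fixed; no joint articulation.
* The voxel-lattice surface is faceted; surface-sensitive quantities are
  therefore reported at sensor resolution (pressures) or as volume-weighted
  percentiles (strains), not as pointwise extrema.
* The contact regularization admits small creep under stick and ~0.1 mm
  scale penetrations; both are far below the layer thicknesses.
* Direct sparse factorization bounds the affordable mesh size (~10⁵ dofs);
  iterative solvers were evaluated and do not converge reliably on this
  conditioning.
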