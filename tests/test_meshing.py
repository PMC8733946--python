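"""Octree tetrahedralization: volumes, refinement, conformity, quality."""

import numpy as np
import pytest

from forefem import labels as L
from forefem import meshing as ME


class TestCubeMeshing:
    def test_volume_preserved(self, cube_map):
        vm = cube_map(n=20, h=1.0)
        mesh = ME.label_to_mesh(vm, 5.0)
        assert mesh.volumes().sum() == pytest.approx(8000.0, rel=0.05)

    def test_positive_jacobians(self, cube_map):
        mesh = ME.label_to_mesh(cube_map(n=20, h=1.0), 4.0)
        assert mesh.jacobians().min() > 0

    def test_quadratic_nodes_on_edge_midpoints(self, cube_map):
        mesh = ME.label_to_mesh(cube_map(n=10, h=1.0), 5.0)
        X = mesh.nodes[mesh.tets]
        for e, (a, b) in enumerate(ME.TET10_EDGES):
            assert np.allclose(X[:, 4 + e], 0.5 * (X[:, a] + X[:, b]))

    def test_linear_fallback(self, cube_map):
        mesh = ME.label_to_mesh(cube_map(n=10, h=1.0), 5.0, quadratic=False)
        assert mesh.tets.shape[1] == 4
        assert mesh.volumes().sum() == pytest.approx(1000.0, rel=0.05)


class TestRegionHandling:
    def test_two_label_volumes_and_preservation(self, cube_map):
        vm = cube_map(n=20, h=1.0, slab=(L.SKIN, 4))
        mesh = ME.label_to_mesh(vm, {"skin": 2.0, "soft_tissue": 4.0})
        assert set(np.unique(mesh.region)) == {L.SKIN, L.SOFT_TISSUE}
        vox = vm.region_volumes()
        got = mesh.region_volumes()
        for lab in vox:
            assert got[lab] == pytest.approx(vox[lab], rel=0.05)

    def test_local_refinement_shrinks_thin_region_edges(self, cube_map):
        vm = cube_map(n=40, h=0.5, slab=(L.SKIN, 4))
        mesh = ME.label_to_mesh(vm, {"skin": 1.0, "soft_tissue": 4.0})
        assert (np.median(mesh.edge_lengths_of(L.SKIN))
                < np.median(mesh.edge_lengths_of(L.SOFT_TISSUE)))

    def test_thin_region_error(self, cube_map):
        vm = cube_map(n=40, h=0.5, slab=(L.SKIN, 2))  # 1 mm slab
        with pytest.raises(ME.ThinRegionError):
            ME.label_to_mesh(vm, {"skin": 8.0, "soft_tissue": 8.0})

    def test_thin_check_scoping(self, cube_map):
        vm = cube_map(n=40, h=0.5, slab=(L.SKIN, 2))
        mesh = ME.label_to_mesh(vm, {"skin": 8.0, "soft_tissue": 8.0},
                                thin_check=(L.SOFT_TISSUE,))
        assert mesh.n_elements > 0

    def test_missing_sizing_entry_rejected(self, cube_map):
        vm = cube_map(n=10, h=1.0, slab=(L.SKIN, 3))
        with pytest.raises(KeyError):
            ME.label_to_mesh(vm, {"soft_tissue": 4.0})


class TestSubdivide:
    def test_eight_children_preserve_geometry(self, cube_map):
        mesh = ME.label_to_mesh(cube_map(n=10, h=1.0), 5.0)
        fine, embed = ME.subdivide(mesh)
        assert fine.n_elements == 8 * mesh.n_elements
        assert fine.volumes().sum() == pytest.approx(mesh.volumes().sum(),
                                                     rel=1e-12)
        assert fine.jacobians().min() > 0
        _, counts, _ = fine.faces_with_counts()
        assert counts.max() == 2          # conforming

    def test_embedding_exact_for_quadratic_fields(self, cube_map):
        mesh = ME.label_to_mesh(cube_map(n=10, h=1.0), 5.0)
        fine, embed = ME.subdivide(mesh)

        def f(X):          # full quadratic polynomial
            return (1.0 + 0.3 * X[:, 0] - 1.2 * X[:, 1] + 0.7 * X[:, 2]
                    + 0.05 * X[:, 0] ** 2 - 0.04 * X[:, 1] * X[:, 2]
                    + 0.02 * X[:, 0] * X[:, 1] + 0.01 * X[:, 2] ** 2)

        u = np.column_stack([f(mesh.nodes), 2 * f(mesh.nodes),
                             np.zeros(mesh.n_nodes)])
        uf = embed(u.ravel()).reshape(-1, 3)
        assert np.abs(uf[:, 0] - f(fine.nodes)).max() < 1e-12

    def test_region_labels_inherited(self, cube_map):
        vm = cube_map(n=20, h=1.0, slab=(L.SKIN, 4))
        mesh = ME.label_to_mesh(vm, {"skin": 2.0, "soft_tissue": 4.0})
        fine, _ = ME.subdivide(mesh)
        for lab in (L.SKIN, L.SOFT_TISSUE):
            assert fine.region_volumes()[lab] == pytest.approx(
                mesh.region_volumes()[lab], rel=1e-12)


class TestRefine:
    def test_factor_two_octuples_elements(self, cube_map):
        mesh = ME.label_to_mesh(cube_map(n=20, h=1.0), 5.0)
        fine = ME.refine(mesh, 2.0)
        ratio = fine.n_elements / mesh.n_elements
        assert 8.0 * 0.7 <= ratio <= 8.0 * 1.3
        assert fine.volumes().sum() == pytest.approx(mesh.volumes().sum(),
                                                     rel=0.02)

    def test_non_dyadic_factor_scales_lattice(self, cube_map):
        mesh = ME.label_to_mesh(cube_map(n=20, h=1.0), 5.0)
        fine = ME.refine(mesh, 1.26)
        ratio = fine.n_elements / mesh.n_elements
        assert 1.3 <= ratio <= 3.2          # ~1.26^3 = 2 with lattice snap
        assert fine.jacobians().min() > 0

    def test_factor_one_rejected(self, cube_map):
        mesh = ME.label_to_mesh(cube_map(n=10, h=1.0), 5.0)
        with pytest.raises(ValueError):
            ME.refine(mesh, 1.0)


@pytest.fixture(scope="module")
def fixture_mesh(dressed_fixture_map):
    from forefem.pipeline import DEFORMABLE_LABELS
    return ME.label_to_mesh(dressed_fixture_map, 4.0,
                            thin_check=DEFORMABLE_LABELS)


class TestDressedPhantomMesh:
    def test_all_regions_represented(self, dressed_fixture_map, fixture_mesh):
        want = {int(v) for v in np.unique(dressed_fixture_map.labels)
                if v != L.BACKGROUND}
        got = {int(v) for v in np.unique(fixture_mesh.region)}
        # bones below mesh resolution may drop; the deformable regions and
        # MH1 must all survive
        assert {L.SOFT_TISSUE, L.SKIN, L.SOCK, L.ORTHOSIS, L.SOLE, L.UPPER,
                L.MH1} <= got
        assert got <= want

    def test_no_inverted_elements(self, fixture_mesh):
        assert fixture_mesh.jacobians().min() > 0

    def test_deformable_region_volumes_close_to_voxels(
            self, dressed_fixture_map, fixture_mesh):
        vox = dressed_fixture_map.region_volumes()
        got = fixture_mesh.region_volumes()
        total_v = sum(vox[k] for k in (L.SOFT_TISSUE, L.SKIN, L.SOCK,
                                       L.ORTHOSIS, L.SOLE, L.UPPER))
        total_m = sum(got.get(k, 0.0) for k in (L.SOFT_TISSUE, L.SKIN, L.SOCK,
                                                L.ORTHOSIS, L.SOLE, L.UPPER))
        assert total_m == pytest.approx(total_v, rel=0.05)

    def test_contact_interface_conformity(self, fixture_mesh):
        """Sock-shoe interface faces pair exactly one sock element with one
        orthosis/upper element."""
        faces, counts, owners = fixture_mesh.faces_with_counts()
        reg = fixture_mesh.region
        inter = counts == 2
        r0, r1 = reg[owners[inter, 0]], reg[owners[inter, 1]]
        contact = (((r0 == L.SOCK) & np.isin(r1, (L.ORTHOSIS, L.UPPER)))
                   | ((r1 == L.SOCK) & np.isin(r0, (L.ORTHOSIS, L.UPPER))))
        assert contact.sum() > 50
        # no face is owned by more than two elements anywhere
        assert counts.max() == 2

    def test_cut_planes_are_flat(self, fixture_mesh, dressed_fixture_map):
        """The lattice ends exactly on the distal/proximal cut planes."""
        z = fixture_mesh.nodes[:, 2]
        vm = dressed_fixture_map
        z_lo = vm.origin[2] - vm.spacing / 2
        z_hi = vm.origin[2] + (vm.labels.shape[2] - 0.5) * vm.spacing
        assert z.min() == pytest.approx(z_lo, abs=1e-9)
        assert z.max() == pytest.approx(z_hi, abs=1e-9)
        # a whole cross-section of nodes sits on each plane
        assert (np.abs(z - z_lo) < 1e-9).sum() > 30
        assert (np.abs(z - z_hi) < 1e-9).sum() > 30
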