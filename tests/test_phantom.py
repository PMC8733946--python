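"""Phantom construction, dressing geometry and cohort sampling."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage, stats

from forefem import cohort as CO
from forefem import labels as L
from forefem import phantom as P


@pytest.fixture(scope="module")
def default_anatomy():
    return P.build_phantom(P.PhantomSpec())


class TestSpecValidation:
    def test_voxel_must_resolve_skin(self):
        with pytest.raises(ValueError):
            P.PhantomSpec(voxel_size=1.5, skin_thickness=2.0)

    def test_section_within_foot(self):
        with pytest.raises(ValueError):
            P.PhantomSpec(section_length=300.0, full_foot_length=240.0)

    def test_centers_ordered(self):
        with pytest.raises(ValueError):
            P.PhantomSpec(mh_centers=(0.0, 11.0, 10.0, 30.0, 38.0))

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            P.PhantomSpec(sesamoid_offset_frac=-0.1)


class TestBuildPhantom:
    def test_deterministic(self):
        spec = P.PhantomSpec()
        a = P.build_phantom(spec)
        b = P.build_phantom(spec)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.origin, b.origin)

    def test_contains_all_bones(self, default_anatomy):
        present = set(np.unique(default_anatomy.labels).tolist())
        for code in L.BONES + (L.SOFT_TISSUE, L.SKIN):
            assert code in present

    def test_label_partition(self, default_anatomy):
        allowed = {L.BACKGROUND, L.SOFT_TISSUE, L.SKIN, *L.BONES}
        assert set(np.unique(default_anatomy.labels).tolist()) <= allowed

    def test_bone_enclosed_in_plane(self, default_anatomy):
        assert default_anatomy.bone_enclosed_in_plane()

    def test_skin_is_shell_around_tissue(self, default_anatomy):
        lab = default_anatomy.labels
        foot_wo_skin = np.isin(lab, L.BONES + (L.SOFT_TISSUE,))
        st = ndimage.generate_binary_structure(3, 1)
        grown = ndimage.binary_dilation(foot_wo_skin, st) & ~foot_wo_skin
        # every interior-region surface voxel that is not on the cut planes
        # must be skin
        touching = lab[grown]
        frac_skin = (touching == L.SKIN).mean()
        assert frac_skin > 0.9

    def test_infeasible_sesamoid_raises_named_error(self):
        with pytest.raises(P.InfeasibleGeometryError, match="sesamoid_radius"):
            P.build_phantom(P.PhantomSpec(sesamoid_radius=16.0))

    def test_scaled_spec_scales_geometry_only(self):
        spec = P.PhantomSpec().scaled(0.5)
        base = P.PhantomSpec()
        assert spec.full_foot_length == base.full_foot_length * 0.5
        assert spec.mh_radii[0] == base.mh_radii[0] * 0.5
        assert spec.body_mass == base.body_mass


class TestDressPhantom:
    def _cylinder_foot(self, radius=12.0, h=0.5, length=30.0, notch=None):
        """Flat-bottomed half-cylinder 'foot' with a 2 mm skin shell.

        ``notch=(half_width, depth)`` carves a plantar concavity whose skin
        follows the carved surface.
        """
        n_xy = int(2 * (radius + 12) / h)
        n_z = int(length / h)
        x = (np.arange(n_xy) - n_xy / 2) * h
        y = (np.arange(n_xy) - n_xy / 2) * h
        X, Y = np.meshgrid(x, y, indexing="ij")
        y_bot = -radius * 0.6
        solid = (X**2 + Y**2 <= radius**2) & (Y >= y_bot)
        inner = (X**2 + Y**2 <= (radius - 2.0) ** 2) & (Y >= y_bot + 2.0)
        if notch is not None:
            w, depth = notch
            solid &= ~((np.abs(X) < w) & (Y < y_bot + depth))
            inner &= ~((np.abs(X) < w + 2.0) & (Y < y_bot + depth + 2.0))
        sl = np.where(solid & ~inner, L.SKIN,
                      np.where(inner, L.SOFT_TISSUE, 0)).astype(np.int16)
        lab = np.repeat(sl[:, :, None], n_z, axis=2)
        return P.VoxelLabelMap(lab, h, np.array([x[0], y[0], 0.0]))

    def test_flat_bottom_gives_uniform_minimum_orthosis(self):
        vm = self._cylinder_foot()
        d = P.dress_phantom(vm, sock_thickness=2.0, orthosis_min=3.0)
        h = d.spacing
        sock = d.labels == L.SOCK
        orth = d.labels == L.ORTHOSIS
        cols = np.argwhere(sock.any(axis=1))
        sb_all = np.array([np.argmax(sock[ix, :, iz]) for ix, iz in cols])
        flat = sb_all == sb_all.min()     # columns on the flat plantar face
        thick = []
        for (ix, iz), sb in zip(cols[flat], sb_all[flat]):
            oc = orth[ix, :sb, iz].sum()
            if oc:
                thick.append(oc * h)
        thick = np.asarray(thick)
        assert flat.sum() > 100
        assert np.allclose(thick, 3.0, atol=h / 2)

    def test_concavity_filled_to_total_contact(self):
        vm = self._cylinder_foot(notch=(4.0, 4.0))
        h = vm.spacing
        d = P.dress_phantom(vm, sock_thickness=2.0, orthosis_min=3.0)
        orth = d.labels == L.ORTHOSIS
        sock = d.labels == L.SOCK
        iz = d.labels.shape[2] // 2
        xs = d.origin[0] + np.arange(d.labels.shape[0]) * h
        thick = {}
        for ix in range(d.labels.shape[0]):
            if sock[ix, :, iz].any():
                sb = np.argmax(sock[ix, :, iz])
                oc = orth[ix, :sb, iz].sum()
                if oc:
                    thick[xs[ix]] = oc * h
        flat = [t for x, t in thick.items() if 6.0 < abs(x) < 9.0]
        deep = [t for x, t in thick.items() if abs(x) < 3.0]
        assert np.allclose(flat, 3.0, atol=h)
        assert abs(max(deep) - 7.0) <= 2 * h
        assert min(deep) >= 3.0 - h

    def test_sock_thickness_via_distance_transform(self):
        vm = self._cylinder_foot()
        d = P.dress_phantom(vm, sock_thickness=2.0)
        h = d.spacing
        foot = np.isin(d.labels, (L.SKIN, L.SOFT_TISSUE))
        sock = d.labels == L.SOCK
        mid = d.labels.shape[2] // 2
        dist = ndimage.distance_transform_edt(~foot[:, :, mid], sampling=h)
        inside = dist[sock[:, :, mid]]
        assert inside.max() <= 2.0 + h
        # the shell reaches its nominal thickness somewhere
        assert inside.max() >= 2.0 - h

    def test_missing_skin_rejected(self):
        lab = np.zeros((10, 10, 10), dtype=np.int16)
        lab[4:6, 4:6, :] = L.SOFT_TISSUE
        with pytest.raises(ValueError, match="skin"):
            P.dress_phantom(P.VoxelLabelMap(lab, 1.0, np.zeros(3)))

    def test_dressed_layers_present_and_exclusive(self, default_anatomy):
        d = P.dress_phantom(default_anatomy)
        present = set(np.unique(d.labels).tolist())
        for code in (L.SOCK, L.ORTHOSIS, L.SOLE, L.UPPER):
            assert code in present
        # anatomy voxels unchanged by dressing
        assert (np.isin(d.labels, L.BONES).sum()
                == np.isin(default_anatomy.labels, L.BONES).sum())


class TestVoxelLabelMapIO:
    def test_nifti_round_trip(self, tmp_path, default_anatomy):
        path = tmp_path / "map.nii.gz"
        default_anatomy.save(path)
        back = P.VoxelLabelMap.load(path)
        assert np.array_equal(back.labels, default_anatomy.labels)
        assert back.spacing == pytest.approx(default_anatomy.spacing)
        assert np.allclose(back.origin, default_anatomy.origin)
        assert (tmp_path / "map.labels.json").exists()


class TestCohortSampling:
    def test_independent_null_within_sampling_bounds(self):
        spec = CO.CohortSpec(n_subjects=13, rank_targets={}, seed=5)
        cov = CO.sample_covariates(spec)
        # 95% critical |r| for n=13 is ~0.55; allow all pairs to stay below
        # a generous null bound
        keys = list(cov)
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                r = stats.spearmanr(cov[a], cov[b]).statistic
                assert abs(r) < 0.75

    def test_copula_recovers_target_at_n500(self):
        spec = CO.CohortSpec(n_subjects=500, seed=3)
        cov = CO.sample_covariates(spec)
        r = stats.spearmanr(cov["disease_duration"],
                            cov["sesamoid_offset_frac"]).statistic
        assert r == pytest.approx(0.698, abs=0.1)
        r2 = stats.spearmanr(cov["sesamoid_offset_frac"],
                             cov["tissue_depth_mh1"]).statistic
        assert r2 == pytest.approx(-0.721, abs=0.1)

    def test_degenerate_two_subject_cohort_runs(self):
        out = CO.sample_cohort(CO.CohortSpec(n_subjects=2, seed=0))
        assert len(out) == 2

    def test_non_psd_targets_rejected(self):
        bad = CO.CohortSpec(rank_targets={
            ("bmi", "disease_duration"): 0.99,
            ("bmi", "tissue_depth_mh1"): 0.99,
            ("disease_duration", "tissue_depth_mh1"): -0.99})
        with pytest.raises(CO.CorrelationError):
            CO.sample_covariates(bad)

    def test_deterministic_given_seed(self):
        a = CO.sample_cohort(CO.CohortSpec(n_subjects=5, seed=11))
        b = CO.sample_cohort(CO.CohortSpec(n_subjects=5, seed=11))
        assert all(pa == pb for (pa, _), (pb, _) in zip(a, b))

    def test_subjects_are_feasible_phantoms(self):
        for ph, rec in CO.sample_cohort(CO.CohortSpec(n_subjects=6, seed=2)):
            assert ph.tissue_depth_mh1 > 0
            assert rec.bmi_group in ("normal", "high")
            # specs validate on construction; building must not raise
            P.build_phantom(replace(ph, voxel_size=1.0))

    def test_bmi_group_boundary(self):
        assert CO.ClinicalRecord(24.99, 5, 5, 5).bmi_group == "normal"
        assert CO.ClinicalRecord(25.0, 5, 5, 5).bmi_group == "high"
        assert CO.ClinicalRecord(18.4, 5, 5, 5).bmi_group == "high"
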