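"""Damage-metric reductions against brute-force oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from forefem import metrics as MX


def brute_percentile(values, weights, q):
    """Sorting-based oracle for the weighted CDF-inversion percentile."""
    order = np.argsort(values, kind="stable")
    cw = np.cumsum(np.asarray(weights, float)[order])
    target = q / 100.0 * cw[-1]
    for v, c in zip(np.asarray(values, float)[order], cw):
        if c >= target:
            return v
    return float(values[order][-1])


def brute_gradient(P, V, h):
    """Exhaustive pair enumeration over the 8-neighbourhood."""
    best = 0.0
    nx, nz = P.shape
    for i in range(nx):
        for j in range(nz):
            if not V[i, j]:
                continue
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < nx and 0 <= b < nz and V[a, b]:
                        d = h * np.hypot(di, dj)
                        best = max(best, abs(P[i, j] - P[a, b]) / d)
    return best


class TestWeightedPercentile:
    def test_integers_equal_weights(self):
        v = np.arange(1.0, 101.0)
        assert MX.weighted_percentile(v, np.ones(100), 99) == 99.0

    def test_constant_field(self):
        for q in (1, 50, 99):
            assert MX.weighted_percentile([3.3] * 7, [1] * 7, q) == 3.3

    def test_two_point_cdf_inversion(self):
        # weight 99 on value 1: the 99th percentile is still 1
        assert MX.weighted_percentile([1.0, 100.0], [99.0, 1.0], 99) == 1.0
        assert MX.weighted_percentile([1.0, 100.0], [99.0, 1.0], 99.5) == 100.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 200)
        v = rng.random(n) * 50
        w = rng.random(n) + 0.01
        q = float(rng.uniform(1, 99))
        assert MX.weighted_percentile(v, w, q) == brute_percentile(v, w, q)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_property_bounded_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        v = rng.standard_normal(n) * 10
        w = rng.random(n) + 1e-3
        qs = np.sort(rng.uniform(1, 99, size=3))
        ps = [MX.weighted_percentile(v, w, q) for q in qs]
        assert all(a <= b for a, b in zip(ps, ps[1:]))
        assert v.min() <= ps[0] and ps[-1] <= v.max()

    def test_errors(self):
        with pytest.raises(ValueError):
            MX.weighted_percentile([], [], 50)
        with pytest.raises(ValueError):
            MX.weighted_percentile([1, 2], [1, -1], 50)
        with pytest.raises(ValueError):
            MX.weighted_percentile([1, 2], [1, 1], 0)


class TestVolumeAbove:
    def test_stated_examples(self):
        assert MX.volume_above([5, 15, 20], [1, 2, 3], 10.0) == 5.0
        assert MX.volume_above([1, 2, 3], [1, 1, 1], 10.0) == 0.0
        assert MX.volume_above([1, 2, 3], [2, 2, 2], 0.0) == 6.0

    def test_strict_threshold(self):
        assert MX.volume_above([10.0, 10.0001], [1, 1], 10.0) == 1.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_non_increasing_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.random(30) * 20
        vol = rng.random(30) + 0.1
        ts = np.sort(rng.uniform(0, 20, 3))
        vals = [MX.volume_above(v, vol, t) for t in ts]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestResampleAndGradient:
    def _flat_patch(self, nxp=40, nzp=40, h=1.0, pfun=lambda x, z: 60.0):
        x, z = np.meshgrid(np.arange(nxp) * h, np.arange(nzp) * h,
                           indexing="ij")
        xz = np.column_stack([x.ravel(), z.ravel()])
        p = np.array([pfun(a, b) for a, b in xz])
        a = np.full(len(xz), h * h)
        return p, a, xz

    def test_uniform_surface(self):
        p, a, xz = self._flat_patch()
        grid = MX.resample_pressure(p, a, xz, spacing=5.0)
        assert np.allclose(grid.pressures[grid.valid], 60.0)
        assert grid.valid.any()

    def test_edge_cells_masked(self):
        p, a, xz = self._flat_patch()
        grid = MX.resample_pressure(p, a, xz, spacing=5.0, cut_edge_margin=5.0)
        zc = grid.origin[1] + np.arange(grid.pressures.shape[1]) * grid.spacing
        assert not grid.valid[:, 0].any() and not grid.valid[:, -1].any()

    def test_narrow_strip_single_column(self):
        p, a, xz = self._flat_patch(nxp=4, nzp=40)
        grid = MX.resample_pressure(p, a, xz, spacing=5.0)
        assert grid.pressures.shape[0] == 1

    def test_linear_ramp_cell_means(self):
        p, a, xz = self._flat_patch(pfun=lambda x, z: 2.0 * x + 10.0)
        grid = MX.resample_pressure(p, a, xz, spacing=5.0,
                                    cut_edge_margin=0.0)
        nx = grid.pressures.shape[0]
        # cell mean of 2x+10 over 5 unit-spaced samples starting at 5k
        for i in range(nx):
            xs = np.arange(i * 5, min((i + 1) * 5, 40))
            want = (2.0 * xs + 10.0).mean()
            got = grid.pressures[i][grid.valid[i]]
            assert np.allclose(got, want)

    def test_gradient_examples(self):
        grid = MX.PressureGrid(np.array([[50.0, 65.0]]),
                               np.ones((1, 2), bool), 5.0, (0, 0))
        assert MX.max_pressure_gradient(grid) == pytest.approx(3.0)
        grid_u = MX.PressureGrid(np.full((4, 4), 7.0), np.ones((4, 4), bool),
                                 5.0, (0, 0))
        assert MX.max_pressure_gradient(grid_u) == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_gradient_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.random((6, 6)) * 80
        V = rng.random((6, 6)) > 0.2
        V[0, 0] = V[1, 1] = True
        grid = MX.PressureGrid(P, V, 5.0, (0, 0))
        assert MX.max_pressure_gradient(grid) == pytest.approx(
            brute_gradient(P, V, 5.0))

    def test_gradient_shift_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        P = rng.random((5, 5)) * 40
        V = np.ones((5, 5), bool)
        g0 = MX.max_pressure_gradient(MX.PressureGrid(P, V, 5.0, (0, 0)))
        g_shift = MX.max_pressure_gradient(
            MX.PressureGrid(P + 13.0, V, 5.0, (0, 0)))
        g_scale = MX.max_pressure_gradient(
            MX.PressureGrid(P * 2.5, V, 5.0, (0, 0)))
        assert g_shift == pytest.approx(g0)
        assert g_scale == pytest.approx(2.5 * g0)

    def test_too_few_valid_cells(self):
        grid = MX.PressureGrid(np.zeros((3, 3)), np.zeros((3, 3), bool),
                               5.0, (0, 0))
        grid.valid[1, 1] = True
        with pytest.raises(ValueError):
            MX.max_pressure_gradient(grid)


class _FakeResult:
    """Minimal strain-carrying stand-in for a solved model."""

    def __init__(self, E_list, vols, regions, z=None):
        self.strains = np.asarray(E_list)[None]          # one qp per element
        self.qp_volumes = np.asarray(vols)[None]
        self.qp_z = (np.asarray(z)[None] if z is not None
                     else np.zeros_like(self.qp_volumes))
        self.region = np.asarray(regions)


class TestMaxShearField:
    def test_diagonal_strain_example(self):
        from forefem import labels as L
        E = np.diag([0.20, -0.05, -0.05])
        res = _FakeResult([E], [1.0], [L.SOFT_TISSUE])
        gamma, w = MX.max_shear_field(res)
        assert gamma[0] == pytest.approx(12.5)

    def test_rigid_rotation_strain_free(self):
        from forefem import labels as L
        th = 0.4
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        E = 0.5 * (R.T @ R - np.eye(3))
        res = _FakeResult([E], [1.0], [L.SOFT_TISSUE])
        gamma, _ = MX.max_shear_field(res)
        assert gamma[0] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_eigen_oracle(self, seed):
        from forefem import labels as L
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((3, 3)) * 0.1
        E = 0.5 * (A + A.T)
        res = _FakeResult([E], [1.0], [L.SOFT_TISSUE])
        gamma, _ = MX.max_shear_field(res)
        ev = np.sort(np.linalg.eigvals(E).real)
        assert gamma[0] == pytest.approx(100 * (ev[2] - ev[0]) / 2, rel=1e-9)

    def test_region_filter_excludes_bone(self):
        from forefem import labels as L
        E = np.diag([0.2, 0.0, -0.2])
        res = _FakeResult([E, E], [1.0, 2.0], [L.MH1, L.SOFT_TISSUE])
        gamma, w = MX.max_shear_field(res)
        assert len(gamma) == 1 and w[0] == 2.0
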