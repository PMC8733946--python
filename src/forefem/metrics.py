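"""Tissue damage-risk metrics from a converged midstance solution.

Four indicators summarize injury risk:

1. 99th-percentile maximum shear strain in the soft tissues (%), weighted
   by tissue volume;
2. volume of tissue above 10% shear strain (mm^3);
3. 99th-percentile plantar pressure on the orthosis/limb interface (kPa),
   weighted by interface area;
4. maximum plantar pressure gradient (kPa/mm) on a pressure map resampled
   to a regular 5 x 5 mm grid, with cells along the section's cut edges
   excluded.

Maximum shear strain is the tensorial definition
``gamma = (E_I - E_III)/2`` from the principal Green-Lagrange strains;
percentiles use weighted empirical-CDF inversion (the smallest value whose
cumulative weight fraction reaches the requested level).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import labels as L
from .solver import SolveResult


@dataclass
class MetricsRecord:
    shear_p99: float                 # % strain
    vol_over_10pct: float            # mm^3
    pressure_p99: float              # kPa
    max_pressure_gradient: float     # kPa/mm
    subject_id: str = ""
    mesh_id: str = ""


@dataclass
class PressureGrid:
    """Regular plan-view (x, z) pressure map in kPa."""

    pressures: np.ndarray            # (nx, nz)
    valid: np.ndarray                # (nx, nz) bool
    spacing: float                   # mm
    origin: tuple                    # (x0, z0) of cell (0, 0) centre
    coverage: Optional[np.ndarray] = None   # contact plan-area per cell, mm^2


# ---------------------------------------------------------------------------
# field extraction
# ---------------------------------------------------------------------------

def max_shear_field(result: SolveResult, regions=(L.SOFT_TISSUE, L.SKIN),
                    z_window: Optional[tuple] = None):
    """Per-quadrature maximum shear strain (%) and volume weights (mm^3).

    ``z_window`` restricts the evaluation to an axial region of interest
    (used by the cut-edge sensitivity protocol).
    """
    sel = np.isin(result.region, regions)
    E = result.strains[:, sel]
    w = result.qp_volumes[:, sel]
    z = result.qp_z[:, sel]
    ev = np.linalg.eigvalsh(E.reshape(-1, 3, 3))
    gamma = 0.5 * (ev[:, 2] - ev[:, 0]) * 100.0
    wf = w.reshape(-1)
    if z_window is not None:
        keep = (z.reshape(-1) >= z_window[0]) & (z.reshape(-1) <= z_window[1])
        gamma, wf = gamma[keep], wf[keep]
    return gamma, wf


def plantar_pressures(result: SolveResult, z_window: Optional[tuple] = None):
    """Orthosis-interface contact pressures (kPa), weights (mm^2), positions.

    Weights are plan-projected facet areas (area times the upward component
    of the interface normal), the measure an in-shoe pressure sensor grid
    samples.  On the faceted voxel interface the projected measure converges
    with mesh refinement, whereas the raw staircase area does not.
    """
    if result.contact_pressure is None:
        raise ValueError("solution carries no contact data")
    plantar = result.contact_region == L.ORTHOSIS
    p = result.contact_pressure[plantar]
    ny = np.maximum(result.contact_normal[plantar, 1], 0.0)
    a = ((result.contact_area[plantar] * ny)[:, None]
         * np.full(p.shape[1], 1.0 / p.shape[1]))
    xz = result.contact_xz[plantar]
    p, a = p.reshape(-1), a.reshape(-1)
    xz = xz.reshape(-1, 2)
    keep = a > 1e-12
    p, a, xz = p[keep], a[keep], xz[keep]
    if z_window is not None:
        keep = (xz[:, 1] >= z_window[0]) & (xz[:, 1] <= z_window[1])
        p, a, xz = p[keep], a[keep], xz[keep]
    return p, a, xz


# ---------------------------------------------------------------------------
# scalar reductions
# ---------------------------------------------------------------------------

def weighted_percentile(values, weights, q) -> float:
    """Smallest value whose cumulative weight fraction reaches q/100."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("empty input to weighted_percentile")
    if v.shape != w.shape:
        raise ValueError("values and weights must have the same length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if not 0 < q < 100:
        raise ValueError("q must lie strictly between 0 and 100")
    order = np.argsort(v, kind="stable")
    cw = np.cumsum(w[order])
    k = int(np.searchsorted(cw, q / 100.0 * cw[-1], side="left"))
    return float(v[order][min(k, len(v) - 1)])


def volume_above(values, element_volumes, threshold=10.0) -> float:
    """Total volume whose field value strictly exceeds the threshold."""
    v = np.asarray(values, dtype=float)
    vol = np.asarray(element_volumes, dtype=float)
    if v.shape != vol.shape:
        raise ValueError("values and volumes must have the same length")
    return float(vol[v > threshold].sum())


def resample_pressure(pressures, areas, xz, spacing: float = 5.0,
                      cut_edge_margin: Optional[float] = None,
                      z_limits: Optional[tuple] = None) -> PressureGrid:
    """Area-weighted average pressure on a regular plan grid.

    Cells whose centres lie within ``cut_edge_margin`` (default: one cell)
    of the axial limits of the contact patch are masked invalid, mirroring
    the exclusion of boundary-affected sensors.
    """
    p = np.asarray(pressures, dtype=float)
    a = np.asarray(areas, dtype=float)
    xz = np.asarray(xz, dtype=float)
    if p.size == 0:
        raise ValueError("no contact data to resample")
    if cut_edge_margin is None:
        cut_edge_margin = spacing
    # anchor the grid to absolute multiples of the spacing so translated
    # geometry (e.g. an extended section) samples identical cells
    x0 = np.floor(xz[:, 0].min() / spacing) * spacing
    z0 = np.floor(xz[:, 1].min() / spacing) * spacing
    ix = np.floor((xz[:, 0] - x0) / spacing).astype(int)
    iz = np.floor((xz[:, 1] - z0) / spacing).astype(int)
    nx, nz = ix.max() + 1, iz.max() + 1
    wsum = np.zeros((nx, nz))
    psum = np.zeros((nx, nz))
    np.add.at(wsum, (ix, iz), a)
    np.add.at(psum, (ix, iz), a * p)
    valid = wsum > 0
    out = np.zeros((nx, nz))
    out[valid] = psum[valid] / wsum[valid]
    zlo, zhi = (z_limits if z_limits is not None
                else (xz[:, 1].min(), xz[:, 1].max()))
    zc = z0 + (np.arange(nz) + 0.5) * spacing
    edge = (zc < zlo + cut_edge_margin) | (zc > zhi - cut_edge_margin)
    valid[:, edge] = False
    return PressureGrid(out, valid, spacing,
                        (x0 + spacing / 2, z0 + spacing / 2), coverage=wsum)


def max_pressure_gradient(grid: PressureGrid) -> float:
    """Max |dp| / distance over the 8-neighbourhood of every valid cell."""
    P = grid.pressures
    V = grid.valid
    if V.sum() < 2:
        raise ValueError("need at least two valid cells for a gradient")
    best = 0.0
    h = grid.spacing
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            dist = h * np.hypot(di, dj)
            a = P[max(di, 0):P.shape[0] + min(di, 0),
                  max(dj, 0):P.shape[1] + min(dj, 0)]
            b = P[max(-di, 0):P.shape[0] + min(-di, 0),
                  max(-dj, 0):P.shape[1] + min(-dj, 0)]
            va = V[max(di, 0):V.shape[0] + min(di, 0),
                   max(dj, 0):V.shape[1] + min(dj, 0)]
            vb = V[max(-di, 0):V.shape[0] + min(-di, 0),
                   max(-dj, 0):V.shape[1] + min(-dj, 0)]
            ok = va & vb
            if ok.any():
                best = max(best, float(np.abs(a - b)[ok].max() / dist))
    return best


# ---------------------------------------------------------------------------
# one-call summary
# ---------------------------------------------------------------------------

def compute_metrics(result: SolveResult, grid_spacing: float = 5.0,
                    cut_edge_margin: Optional[float] = None,
                    shear_threshold: float = 10.0,
                    z_window: Optional[tuple] = None,
                    subject_id: str = "", mesh_id: str = "") -> MetricsRecord:
    """All four damage-risk metrics from one solved midstance case."""
    gamma, w = max_shear_field(result, z_window=z_window)
    shear_p99 = weighted_percentile(gamma, w, 99.0)
    vol10 = volume_above(gamma, w, shear_threshold)
    p, a, xz = plantar_pressures(result, z_window=z_window)
    grid = resample_pressure(p, a, xz, spacing=grid_spacing,
                             cut_edge_margin=cut_edge_margin)
    # the pressure percentile is evaluated at the sensor-grid resolution:
    # cell-averaged plantar pressures weighted by covered interface area
    # (pointwise penalty pressures on the faceted voxel interface carry
    # mesh-resolution corner artefacts and do not converge)
    sel = grid.coverage > 0
    pressure_p99 = weighted_percentile(grid.pressures[sel],
                                       grid.coverage[sel], 99.0)
    grad = max_pressure_gradient(grid)
    return MetricsRecord(shear_p99, vol10, pressure_p99, grad,
                         subject_id, mesh_id)
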