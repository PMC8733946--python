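"""Shared fixtures: small voxel maps, meshes, and (session-scoped) solved
midstance cases on the reduced-scale fixture phantom.

The FE solutions are expensive, so everything downstream (equilibrium and
Coulomb checks, metric monotonicity sweeps, cut-edge sensitivity) shares
the same session-scoped solves.
"""

from __future__ import annotations

import numpy as np
import pytest

from forefem import labels as L
from forefem import pipeline as PL
from forefem.phantom import VoxelLabelMap, build_phantom


@pytest.fixture(scope="session")
def cube_map():
    """Factory for single- or two-label cube maps (origin at voxel centres)."""

    def make(n=20, h=1.0, label=L.SOFT_TISSUE, slab=None):
        lab = np.full((n, n, n), label, dtype=np.int16)
        if slab is not None:
            slab_label, thickness_vox = slab
            lab[:, :thickness_vox, :] = slab_label
        return VoxelLabelMap(lab, h, np.zeros(3))

    return make


@pytest.fixture(scope="session")
def fixture_phantom():
    """The packaged reduced-scale phantom and dressing."""
    spec, dress = PL.fixture_spec()
    return spec, dress


@pytest.fixture(scope="session")
def dressed_fixture_map(fixture_phantom):
    spec, dress = fixture_phantom
    from forefem.phantom import dress_phantom

    anatomy = build_phantom(spec)
    return dress_phantom(anatomy, sock_thickness=dress.sock,
                         upper_thickness=dress.upper,
                         sole_thickness=dress.sole,
                         orthosis_min=dress.orthosis_min)


@pytest.fixture(scope="session")
def convergence_frame():
    """The full mesh-density ladder on the fixture (three solves; shared)."""
    return PL.convergence_study()
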