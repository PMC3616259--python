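"""Shared fixtures: phantom suite and cached reconstructions.

Reconstruction (segment → cleanup → thinning → graph) is deterministic, so
each phantom is reconstructed once per session and shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import arbormap as am


@pytest.fixture(scope="session")
def phantoms() -> dict[str, am.Fixture]:
    return am.standard_fixtures()


@pytest.fixture(scope="session")
def reconstructions(phantoms):
    """name -> (fixture, mask, graph) for the noise-free tree phantoms."""
    out = {}
    for name in ("straight_tube", "curved_tube", "tapering_cone", "y_tree",
                 "tree_with_spur", "stellate"):
        fx = phantoms[name]
        mask = am.remove_small_components(am.segment(fx.morphology))
        midline = am.extract_midline(mask)
        graph = am.build_graph(midline, fx.seed_point, fx.morphology.geometry,
                               mask=mask)
        graph = am.estimate_radius(graph, mask)
        out[name] = (fx, mask, graph)
    return out


def midline_voxels(fx: am.Fixture, names=None) -> np.ndarray:
    """Unique (z, y, x) voxel indices of a phantom's analytic midline."""
    geom = fx.morphology.geometry
    pts = fx.truth.midline_points(names)
    vox = np.round(pts / np.array(geom.spacing_xyz)).astype(int)
    return np.unique(vox[:, ::-1], axis=0)
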