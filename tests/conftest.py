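"""Shared fixtures: small tilings, label images and reference scenes.

Scenes are module-scoped because simulation is the expensive part; tests
must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from texkin.synthetic import FlowSpec, SceneConfig, make_hexagonal_tiling, \
    make_voronoi_tiling, simulate
from texkin.tiling_io import frame_from_tiling


@pytest.fixture(scope="session")
def hex_tiling():
    return make_hexagonal_tiling(7, 7, spacing=20.0)


@pytest.fixture(scope="session")
def hex_frame(hex_tiling):
    return frame_from_tiling(hex_tiling)


@pytest.fixture(scope="session")
def square_grid_labels():
    """3x3 grid of 9x9-px square cells separated by 1-px contours."""
    img = np.zeros((31, 31), dtype=np.int32)
    for r in range(3):
        for c in range(3):
            img[r * 10 + 1:(r + 1) * 10, c * 10 + 1:(c + 1) * 10] = r * 3 + c + 1
    return img


@pytest.fixture(scope="session")
def voronoi_tiling():
    return make_voronoi_tiling(100, seed=2, lloyd_steps=5)


@pytest.fixture(scope="session")
def affine_scene():
    """Event-free scene under a fixed affine flow (shear + dilation)."""
    cfg = SceneConfig(
        tiling_kind="voronoi", n_cells=120, n_intervals=3, dt=1.0,
        flow=FlowSpec(kind="affine",
                      gradient=np.array([[0.01, 0.004], [-0.002, -0.006]])))
    return simulate(cfg, seed=3)


@pytest.fixture(scope="session")
def t1_scene():
    """Area-preserving rearrangement-only scene (pure shear flow)."""
    cfg = SceneConfig(
        tiling_kind="voronoi", n_cells=150, n_intervals=5, dt=1.0,
        t1_per_interval=3, t1_relax=True,
        flow=FlowSpec(kind="affine",
                      gradient=np.array([[0.005, 0.0], [0.0, -0.005]])))
    return simulate(cfg, seed=4)


@pytest.fixture(scope="session")
def division_scene():
    """Division-only scene, no imposed flow."""
    cfg = SceneConfig(tiling_kind="voronoi", n_cells=150, n_intervals=4,
                      dt=1.0, divisions_per_interval=2)
    return simulate(cfg, seed=5)


@pytest.fixture(scope="session")
def apoptosis_scene():
    """T2-removal-only scene, no imposed flow."""
    cfg = SceneConfig(tiling_kind="voronoi", n_cells=150, n_intervals=3,
                      dt=1.0, t2_per_interval=1)
    return simulate(cfg, seed=6)


@pytest.fixture(scope="session")
def mixed_event_scene():
    """Divisions + T2 removals under a weak affine flow."""
    cfg = SceneConfig(
        tiling_kind="voronoi", n_cells=150, n_intervals=4, dt=1.0,
        divisions_per_interval=2, t2_per_interval=1,
        flow=FlowSpec(kind="affine",
                      gradient=np.array([[0.005, 0.0], [0.0, -0.003]])))
    return simulate(cfg, seed=9)


@pytest.fixture(scope="session")
def division_rich_scene():
    """Larger dividing tissue for the density-balance regression."""
    cfg = SceneConfig(
        tiling_kind="voronoi", n_cells=250, n_intervals=8, dt=1.0,
        divisions_per_interval=3,
        flow=FlowSpec(kind="affine",
                      gradient=np.array([[0.004, 0.0], [0.0, 0.003]])))
    return simulate(cfg, seed=21)
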