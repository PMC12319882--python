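"""Shared fixtures: phantom scenes and small constructed meshes."""

from __future__ import annotations

import numpy as np
import pytest

from safsheet.io_formats import SurfaceMesh
from safsheet.synthetic_data import SceneConfig, SyntheticScene, make_scene


def grid_mesh(
    nx: int = 11,
    ny: int = 11,
    step: float = 1.0,
    z: float = 0.0,
    role: str = "white",
) -> SurfaceMesh:
    """A flat rectangular grid mesh in the z = const plane, normals up."""
    xs = np.arange(nx) * step
    ys = np.arange(ny) * step
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    vertices = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, float(z))])
    tris = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            v00 = j * nx + i
            v10 = v00 + 1
            v01 = v00 + nx
            v11 = v01 + 1
            tris.append([v00, v10, v11])
            tris.append([v00, v11, v01])
    return SurfaceMesh(vertices, np.array(tris), role=role)


@pytest.fixture(scope="session")
def scene() -> SyntheticScene:
    """Default phantom scene, seed 1, with fMRI."""
    return make_scene(SceneConfig(seed=1))


@pytest.fixture(scope="session")
def quiet_scene() -> SyntheticScene:
    """Phantom with all degradation knobs at zero (pure geometry)."""
    cfg = SceneConfig(seed=2)
    cfg.fibres.jitter_sd = 0.0
    cfg.fibres.crowding_sd = 0.0
    return make_scene(cfg, with_fmri=False)


@pytest.fixture()
def flat_ribbon() -> tuple[SurfaceMesh, SurfaceMesh]:
    """Planar cortical ribbon: white at z=0, pial at z=2, 20x20 mm."""
    white = grid_mesh(21, 21, 1.0, z=0.0, role="white")
    pial = grid_mesh(21, 21, 1.0, z=2.0, role="pial")
    return white, pial
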