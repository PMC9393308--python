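import numpy as np
import pytest
import trimesh

from hipmorph import TriangleMesh, make_healthy_hip


@pytest.fixture(scope="session")
def unit_cube():
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriangleMesh(np.asarray(box.vertices), np.asarray(box.faces))


@pytest.fixture(scope="session")
def icosphere_r20():
    ico = trimesh.creation.icosphere(subdivisions=4, radius=20.0)
    return TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def icosphere_r10():
    ico = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def healthy_hip_res3():
    return make_healthy_hip(head_radius=20.0, mesh_resolution=3)


@pytest.fixture(scope="session")
def healthy_hip_res4():
    return make_healthy_hip(head_radius=20.0, mesh_resolution=4)


@pytest.fixture(scope="session")
def chiral_mesh():
    """A generic (hence chiral) random surface for mirror-detection tests."""
    rng = np.random.default_rng(42)
    pts = rng.normal(size=(200, 3)) * np.array([12.0, 7.0, 4.0])
    hull = trimesh.convex.convex_hull(pts)
    return TriangleMesh(np.asarray(hull.vertices), np.asarray(hull.faces))
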