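import numpy as np
import pytest

from retinatopo import RetinaParams, VascularGraph, generate_retina


@pytest.fixture(scope="session")
def hemi_retina():
    """Default-geometry hemisphere retina, seed 1."""
    return generate_retina(RetinaParams(seed=1))


@pytest.fixture(scope="session")
def flat_retina():
    """Small flat two-plexus patch for fast voxel-level tests."""
    return generate_retina(
        RetinaParams(geometry_mode="flat", shell_radius_um=250.0, seed=3)
    )


@pytest.fixture(scope="session")
def clean_flat_retina():
    """Chord- and jitter-free flat patch: voxelization is topology-exact."""
    return generate_retina(
        RetinaParams(
            geometry_mode="flat",
            shell_radius_um=250.0,
            seed=3,
            jitter_um=0.0,
            chord_rate=0.0,
        )
    )


def toy_graph(points, edges, radius=3.0, compartment="primary"):
    g = VascularGraph()
    for i, p in enumerate(points):
        g.add_node(i, np.asarray(p, dtype=float), radius)
    for a, b in edges:
        g.add_edge(a, b, radius, compartment)
    return g


@pytest.fixture()
def triangle_graph():
    return toy_graph([(0, 0, 0), (60, 0, 0), (30, 52, 0)], [(0, 1), (1, 2), (0, 2)])


@pytest.fixture()
def star_graph():
    return toy_graph(
        [(0, 0, 0), (60, 0, 0), (-60, 0, 0), (0, 60, 0)], [(0, 1), (0, 2), (0, 3)]
    )
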