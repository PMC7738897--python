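"""Generator contracts: geometry, compartments, OIR deletion, voxelisation."""

import dataclasses

import numpy as np
import pytest

from retinatopo import (
    OirParams,
    RetinaParams,
    apply_oir,
    generate_retina,
    make_phantom,
    voxelize,
)
from retinatopo.synthetic import DegenerateGeometryError
from retinatopo.topology import clustering_coefficients, euler_graph
from retinatopo.volume import PLEXUS, SPROUT

from conftest import toy_graph

FLAT_SMALL = dict(geometry_mode="flat", shell_radius_um=250.0)


# ---------------------------------------------------------------------------
# parameter validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [
        {"mesh_edge_um": -1.0},
        {"sprout_density": 1.5},
        {"chord_rate": -0.1},
        {"layer_separation_um": 2000.0},
        {"geometry_mode": "sphere"},
    ],
)
def test_invalid_retina_params_rejected(kwargs):
    with pytest.raises(ValueError):
        RetinaParams(**kwargs)


def test_invalid_oir_params_rejected():
    with pytest.raises(ValueError):
        OirParams(p_secondary=1.2)


def test_mesh_coarser_than_extent_is_degenerate():
    with pytest.raises(DegenerateGeometryError):
        generate_retina(
            RetinaParams(geometry_mode="flat", shell_radius_um=100.0,
                         layer_separation_um=50.0, mesh_edge_um=120.0)
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def test_every_edge_tagged_and_connected(hemi_retina):
    import networkx as nx

    tags = {e.compartment for e in hemi_retina.graph.edges}
    assert tags == {"primary", "secondary", "sprout"}
    assert nx.is_connected(hemi_retina.graph.to_networkx())


def test_zero_sprout_density_splits_layers():
    import networkx as nx

    retina = generate_retina(RetinaParams(seed=4, sprout_density=0.0, **FLAT_SMALL))
    assert not any(e.compartment == "sprout" for e in retina.graph.edges)
    assert nx.number_connected_components(retina.graph.to_networkx()) >= 2


def test_determinism_identical_seed():
    a = generate_retina(RetinaParams(seed=9, **FLAT_SMALL))
    b = generate_retina(RetinaParams(seed=9, **FLAT_SMALL))
    assert a.graph.node_ids() == b.graph.node_ids()
    for i in a.graph.nodes:
        assert np.array_equal(a.graph.nodes[i].position, b.graph.nodes[i].position)
    assert [
        (e.node_a, e.node_b, e.compartment) for e in a.graph.edges
    ] == [(e.node_a, e.node_b, e.compartment) for e in b.graph.edges]
    va, _ = voxelize(a.graph, 4.0)
    vb, _ = voxelize(b.graph, 4.0)
    assert np.array_equal(va.data, vb.data)


def test_modal_degree_is_three_by_brute_force():
    """Honeycomb layers give interior degree 3; mode is 3 for every seed."""
    from collections import Counter

    for seed in range(1, 11):
        retina = generate_retina(RetinaParams(seed=seed, **FLAT_SMALL))
        counts = Counter()
        for e in retina.graph.edges:
            counts[e.node_a] += 1
            counts[e.node_b] += 1
        degree_freq = Counter(counts.values())
        assert max(degree_freq, key=degree_freq.get) == 3


def test_layers_sit_on_their_shells(hemi_retina):
    params = hemi_retina.params
    tol = 4.0 * params.jitter_um + 1.0
    for comp, nominal in (("primary", params.shell_radius_um - params.layer_separation_um),
                          ("secondary", params.shell_radius_um)):
        ids = {e.node_a for e in hemi_retina.graph.edges if e.compartment == comp}
        ids |= {e.node_b for e in hemi_retina.graph.edges if e.compartment == comp}
        radii = np.array(
            [np.linalg.norm(hemi_retina.graph.nodes[i].position) for i in ids]
        )
        assert np.all(np.abs(radii - nominal) < tol)


def test_orientation_fidelity(hemi_retina):
    """Sprouts within 15° of radial; plexus edges within 15° of tangential."""
    for e in hemi_retina.graph.edges:
        d = e.polyline[-1] - e.polyline[0]
        d = d / np.linalg.norm(d)
        mid = 0.5 * (e.polyline[0] + e.polyline[-1])
        u = hemi_retina.radial_direction(mid)[0]
        off_radial = np.degrees(np.arccos(np.clip(abs(d @ u), 0, 1)))
        if e.compartment == "sprout":
            assert off_radial <= 15.0
        else:
            assert off_radial >= 75.0


def test_positive_clustering_calibration():
    """Across seeds, ≈10 % of nodes have a positive clustering coefficient."""
    fractions = []
    for seed in range(1, 11):
        retina = generate_retina(RetinaParams(seed=seed))
        cc = clustering_coefficients(retina.graph)
        values = np.array(list(cc.values()))
        fractions.append(float((values > 0).mean()))
    assert abs(np.mean(fractions) - 0.10) < 0.03


# ---------------------------------------------------------------------------
# OIR
# ---------------------------------------------------------------------------

def test_oir_total_deletion_removes_secondary_and_sprouts(flat_retina):
    out = apply_oir(flat_retina, OirParams(p_secondary=1.0, p_sprout=1.0, seed=0))
    tags = {e.compartment for e in out.graph.edges}
    assert "secondary" not in tags and "sprout" not in tags


def test_oir_zero_probabilities_is_identity(flat_retina):
    out = apply_oir(
        flat_retina,
        OirParams(p_secondary=0.0, p_sprout=0.0, p_primary_central=0.0, seed=0),
    )
    assert out.graph.n_edges == flat_retina.graph.n_edges
    assert out.graph.n_nodes == flat_retina.graph.n_nodes


def test_oir_never_adds_edges_and_reduces_connectivity(hemi_retina):
    out = apply_oir(hemi_retina, OirParams(seed=5))
    assert out.graph.n_edges < hemi_retina.graph.n_edges
    before = 1 - euler_graph(hemi_retina.graph)
    after = 1 - euler_graph(out.graph)
    assert after < before


def test_oir_deleted_fraction_matches_probability(hemi_retina):
    """Per-compartment deleted fraction is binomial around its probability."""
    p = 0.5
    out = apply_oir(hemi_retina, OirParams(p_secondary=p, p_sprout=p,
                                           p_primary_central=p, seed=11))
    for comp in ("secondary", "sprout"):
        n_before = sum(1 for e in hemi_retina.graph.edges if e.compartment == comp)
        n_after = sum(1 for e in out.graph.edges if e.compartment == comp)
        frac = 1.0 - n_after / n_before
        sigma = np.sqrt(p * (1 - p) / n_before)
        assert abs(frac - p) < 5 * sigma


def test_oir_determinism(flat_retina):
    a = apply_oir(flat_retina, OirParams(seed=7))
    b = apply_oir(flat_retina, OirParams(seed=7))
    assert [(e.node_a, e.node_b) for e in a.graph.edges] == [
        (e.node_a, e.node_b) for e in b.graph.edges
    ]


# ---------------------------------------------------------------------------
# voxelisation and phantoms
# ---------------------------------------------------------------------------

def test_voxelize_cylinder_volume_matches_analytic():
    length, radius, voxel = 40.0, 4.0, 2.0
    g = toy_graph([(0, 0, 0), (length, 0, 0)], [(0, 1)], radius=radius)
    vol, _ = voxelize(g, voxel)
    expected = np.pi * radius**2 * length / voxel**3
    assert abs(int(vol.data.sum()) - expected) / expected < 0.10


def test_voxelize_empty_graph_is_background():
    from retinatopo import VascularGraph

    vol, lab = voxelize(VascularGraph(), 2.0)
    assert vol.data.sum() == 0 and lab.data.sum() == 0
    assert vol.voxel_size_um == 2.0


def test_voxelize_label_classes(flat_retina):
    _, lab = voxelize(flat_retina.graph, 3.0)
    fg = lab.data[lab.data != 0]
    assert set(np.unique(fg)) <= {PLEXUS, SPROUT}


def test_radial_tube_phantom_is_all_sprout():
    vol, lab = make_phantom("radial_tube")
    fg = vol.data.astype(bool)
    assert fg.any() and np.all(lab.data[fg] == SPROUT)


def test_tangential_tube_phantom_is_all_plexus():
    vol, lab = make_phantom("tangential_tube")
    fg = vol.data.astype(bool)
    assert fg.any() and np.all(lab.data[fg] == PLEXUS)


def test_two_layer_slab_fraction_matches_capsule_volumes():
    extent, sep, spacing, n_sprouts, radius = 200.0, 120.0, 40.0, 4, 4.0
    vol, lab = make_phantom(
        "two_layer_slab", extent_um=extent, separation_um=sep,
        tube_spacing_um=spacing, n_sprouts=n_sprouts, radius_um=radius,
        voxel_size_um=2.0,
    )
    n_rails = int(extent // spacing) + 1
    rail_volume = 2 * n_rails * np.pi * radius**2 * extent
    sprout_volume = n_sprouts * np.pi * radius**2 * sep
    expected = sprout_volume / (sprout_volume + rail_volume)
    counts = lab.class_counts()
    got = counts[SPROUT] / (counts[SPROUT] + counts[PLEXUS])
    assert abs(got - expected) < 0.25 * expected  # voxelisation/overlap tolerance


def test_unknown_phantom_kind():
    with pytest.raises(ValueError):
        make_phantom("moebius_tube")
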