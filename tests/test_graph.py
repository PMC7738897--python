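"""Graph model, CSV round-trips, morphometrics and skeleton tracing."""

import numpy as np
import pandas as pd
import pytest

from retinatopo import (
    VascularGraph,
    compute_morphometrics,
    extract_graph_from_skeleton,
    read_graph,
    voxelize,
    write_graph,
)
from retinatopo.graph import GraphSchemaError, write_swc
from retinatopo.volume import VolumeImage

from conftest import toy_graph


# ---------------------------------------------------------------------------
# model invariants
# ---------------------------------------------------------------------------

def test_self_loop_rejected():
    g = VascularGraph()
    g.add_node(0, (0, 0, 0), 3.0)
    with pytest.raises(GraphSchemaError):
        g.add_edge(0, 0)


def test_dangling_endpoint_rejected():
    g = VascularGraph()
    g.add_node(0, (0, 0, 0), 3.0)
    with pytest.raises(GraphSchemaError):
        g.add_edge(0, 5)


def test_polyline_endpoint_mismatch_rejected():
    from retinatopo.graph import Edge, Node

    nodes = {0: Node((0, 0, 0), 3.0), 1: Node((10, 0, 0), 3.0)}
    bad = Edge(0, 1, [(0, 0, 0), (9, 1, 0)], 3.0)
    with pytest.raises(GraphSchemaError):
        VascularGraph(nodes, [bad])


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def test_roundtrip_preserves_graph(tmp_path, flat_retina):
    nodes, edges = tmp_path / "nodes.csv", tmp_path / "edges.csv"
    write_graph(flat_retina.graph, nodes, edges)
    back = read_graph(nodes, edges)
    assert back.node_ids() == flat_retina.graph.node_ids()
    for i in back.nodes:
        assert np.allclose(
            back.nodes[i].position, flat_retina.graph.nodes[i].position, atol=1e-5
        )
    assert [(e.node_a, e.node_b, e.compartment) for e in back.edges] == [
        (e.node_a, e.node_b, e.compartment) for e in flat_retina.graph.edges
    ]


def test_read_rejects_dangling_edge(tmp_path):
    pd.DataFrame(
        {"id": [0], "x_um": [0.0], "y_um": [0.0], "z_um": [0.0], "radius_um": [3.0]}
    ).to_csv(tmp_path / "nodes.csv", index=False)
    pd.DataFrame(
        {
            "id": [0],
            "node_a": [0],
            "node_b": [99],
            "compartment": ["primary"],
            "radius_um": [3.0],
            "polyline": ["[[0,0,0],[1,1,1]]"],
        }
    ).to_csv(tmp_path / "edges.csv", index=False)
    with pytest.raises(GraphSchemaError, match="row 2"):
        read_graph(tmp_path / "nodes.csv", tmp_path / "edges.csv")


def test_read_rejects_missing_columns(tmp_path):
    pd.DataFrame({"id": [0], "x_um": [0.0]}).to_csv(tmp_path / "nodes.csv", index=False)
    with pytest.raises(GraphSchemaError, match="missing columns"):
        read_graph(tmp_path / "nodes.csv")


def test_nodes_only_file_gives_edgeless_graph(tmp_path):
    pd.DataFrame(
        {"id": [0, 1], "x_um": [0.0, 1.0], "y_um": [0.0, 0.0], "z_um": [0.0, 0.0],
         "radius_um": [3.0, 3.0]}
    ).to_csv(tmp_path / "nodes.csv", index=False)
    g = read_graph(tmp_path / "nodes.csv")
    assert g.n_nodes == 2 and g.n_edges == 0


def test_swc_export_refuses_cycles(tmp_path, triangle_graph):
    with pytest.raises(ValueError, match="cyclic"):
        write_swc(triangle_graph, tmp_path / "tree.swc")


def test_swc_export_tree(tmp_path, star_graph):
    write_swc(star_graph, tmp_path / "tree.swc")
    lines = [l for l in (tmp_path / "tree.swc").read_text().splitlines()
             if not l.startswith("#")]
    assert len(lines) == 4
    assert sum(1 for l in lines if l.split()[-1] == "-1") == 1  # one root


# ---------------------------------------------------------------------------
# morphometrics
# ---------------------------------------------------------------------------

def test_single_segment_analytic():
    g = toy_graph([(0, 0, 0), (100, 0, 0)], [(0, 1)], radius=3.0)
    rec = compute_morphometrics(g)
    assert rec.total_length == pytest.approx(100.0)
    assert rec.total_volume == pytest.approx(np.pi * 9 * 100, rel=1e-9)
    assert rec.branch_points == 0 and rec.terminal_points == 2


def test_y_shape_has_one_branch_point(star_graph):
    rec = compute_morphometrics(star_graph)
    assert rec.branch_points == 1
    assert rec.terminal_points == 3


def test_totals_match_bruteforce_resummation(flat_retina):
    """Independent re-summation over all polyline points."""
    length = 0.0
    volume = 0.0
    for e in flat_retina.graph.edges:
        seg = 0.0
        for p, q in zip(e.polyline[:-1], e.polyline[1:]):
            seg += float(np.sqrt(((np.asarray(q) - np.asarray(p)) ** 2).sum()))
        length += seg
        volume += np.pi * e.radius**2 * seg
    rec = compute_morphometrics(flat_retina.graph)
    assert rec.total_length == pytest.approx(length, rel=1e-9)
    assert rec.total_volume == pytest.approx(volume, rel=1e-9)


def test_morphometrics_additive_over_disjoint_union():
    a = toy_graph([(0, 0, 0), (50, 0, 0), (50, 50, 0)], [(0, 1), (1, 2)])
    b = toy_graph([(200, 0, 0), (260, 0, 0)], [(0, 1)], radius=5.0)
    union = VascularGraph()
    for g, offset in ((a, 0), (b, 100)):
        for i, n in g.nodes.items():
            union.add_node(i + offset, n.position, n.radius)
        for e in g.edges:
            union.add_edge(e.node_a + offset, e.node_b + offset, e.radius)
    ra, rb, ru = (compute_morphometrics(g) for g in (a, b, union))
    assert ru.total_length == pytest.approx(ra.total_length + rb.total_length)
    assert ru.total_volume == pytest.approx(ra.total_volume + rb.total_volume)
    assert ru.branch_points == ra.branch_points + rb.branch_points


def test_scale_equivariance(flat_retina):
    s = 2.5
    scaled = VascularGraph()
    for i, n in flat_retina.graph.nodes.items():
        scaled.add_node(i, n.position * s, n.radius)
    for e in flat_retina.graph.edges:
        scaled.add_edge(e.node_a, e.node_b, e.radius, e.compartment,
                        polyline=e.polyline * s)
    r0 = compute_morphometrics(flat_retina.graph)
    r1 = compute_morphometrics(scaled)
    assert r1.total_length == pytest.approx(s * r0.total_length, rel=1e-9)
    assert r1.total_volume == pytest.approx(s * r0.total_volume, rel=1e-9)


# ---------------------------------------------------------------------------
# skeleton tracing
# ---------------------------------------------------------------------------

def test_extract_single_segment():
    g = toy_graph([(0, 0, 0), (100, 0, 0)], [(0, 1)])
    vol, _ = voxelize(g, 2.0)
    out = extract_graph_from_skeleton(vol)
    assert out.n_nodes == 2 and out.n_edges == 1
    assert sorted(out.degrees().values()) == [1, 1]


def test_extract_y_has_one_branch():
    g = toy_graph(
        [(0, 0, 0), (60, 0, 0), (100, 40, 0), (100, -40, 0)],
        [(0, 1), (1, 2), (1, 3)],
    )
    vol, _ = voxelize(g, 2.0)
    out = extract_graph_from_skeleton(vol)
    degs = sorted(out.degrees().values())
    assert degs.count(3) == 1
    assert out.n_nodes - out.n_edges == 1  # tree


def test_extract_empty_volume():
    out = extract_graph_from_skeleton(VolumeImage(np.zeros((4, 4, 4), np.uint8), 2.0))
    assert out.n_nodes == 0 and out.n_edges == 0


def test_extract_rejects_nonbinary():
    with pytest.raises(ValueError):
        extract_graph_from_skeleton(VolumeImage(np.full((3, 3, 3), 7), 2.0))


def test_extractor_preserves_euler_on_retina(clean_flat_retina):
    """V−E of the traced graph equals the ground-truth graph's on a clean patch."""
    vol, _ = voxelize(clean_flat_retina.graph, 3.0)
    out = extract_graph_from_skeleton(vol)
    truth = clean_flat_retina.graph
    assert out.n_nodes - out.n_edges == truth.n_nodes - truth.n_edges
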