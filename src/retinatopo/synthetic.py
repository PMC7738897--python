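"""Synthetic two-plexus retinal vascular networks.

The generator emulates the architecture of the neonatal mouse retinal
vasculature: a superficial (primary) and a deep (secondary) reticulated
capillary plexus — honeycomb-like meshes with interior node degree 3 —
bridged by radially oriented vertical sprouts, laid out either on a
hemispherical shell (the in-situ geometry) or on two parallel planes (flat
mode, convenient for closed-form unit tests).  An oxygen-induced-retinopathy
(OIR) perturbation stochastically deletes edges per compartment, emulating
hyperoxic vaso-obliteration that preferentially erases the secondary plexus
and the sprouts, with partial loss of the central primary plexus.

Hemisphere layout: a planar honeycomb lattice is mapped onto each shell with
a Lambert azimuthal equal-area projection (pole = optic-disk axis), so mesh
density is uniform per unit shell area and regional morphometrics are
homogeneous by construction.  Both layers share one angular lattice; with
``sprout_density`` of the primary nodes emitting a sprout to the nearest
secondary node, nominal sprouts are exactly radial.  Positional jitter is
applied in the projection plane (tangentially), keeping each layer on its
shell.  Triangle-forming chords between two neighbours of a node are inserted
at ``chord_rate`` per node; each chord gives three nodes a positive
clustering coefficient, so the default 0.033 calibrates ≈10 % of nodes to
positive clustering.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.spatial import cKDTree

from .graph import Edge, Node, VascularGraph
from .volume import BACKGROUND, PLEXUS, SPROUT, LabelVolume, VolumeImage

PRIMARY = "primary"
SECONDARY = "secondary"
SPROUT_TAG = "sprout"


class DegenerateGeometryError(ValueError):
    """Mesh spacing is too coarse for the requested shell/plane extent."""


@dataclasses.dataclass(frozen=True)
class RetinaParams:
    """Geometry and stochasticity of the synthetic retina.

    Defaults describe a plausible P12 mouse retina: shell radius 1 mm,
    inter-plexus depth 120 µm (the vasculature spans ~0-240 µm of retinal
    depth), capillary mesh spacing 60 µm, capillary radius 3 µm.
    """

    geometry_mode: str = "hemisphere"  # or "flat"
    shell_radius_um: float = 1000.0
    layer_separation_um: float = 120.0
    mesh_edge_um: float = 60.0
    vessel_radius_um: float = 3.0
    sprout_density: float = 0.3
    chord_rate: float = 0.033
    jitter_um: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry_mode not in ("hemisphere", "flat"):
            raise ValueError(f"unknown geometry_mode {self.geometry_mode!r}")
        for name in ("shell_radius_um", "layer_separation_um", "mesh_edge_um",
                     "vessel_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sprout_density", "chord_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.jitter_um < 0:
            raise ValueError("jitter_um must be non-negative")
        if self.layer_separation_um >= self.shell_radius_um:
            raise ValueError("layer_separation_um must be below shell_radius_um")


@dataclasses.dataclass(frozen=True)
class OirParams:
    """Per-compartment edge-deletion probabilities of the OIR perturbation."""

    p_secondary: float = 0.95
    p_sprout: float = 0.95
    p_primary_central: float = 0.8
    central_fraction: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_secondary", "p_sprout", "p_primary_central",
                     "central_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclasses.dataclass
class SyntheticRetina:
    """A generated vascular network plus the parameters that produced it."""

    graph: VascularGraph
    params: RetinaParams
    oir: OirParams | None = None
    origin_um: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(3, dtype=float)
    )

    def radial_direction(self, points: np.ndarray) -> np.ndarray:
        """Unit radial (depth) direction at world points (n, 3)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.params.geometry_mode == "flat":
            out = np.zeros_like(points)
            out[:, 2] = 1.0
            return out
        vec = points - self.origin_um
        norm = np.linalg.norm(vec, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return vec / norm


# ---------------------------------------------------------------------------
# honeycomb lattice
# ---------------------------------------------------------------------------


def _honeycomb_disk(radius: float, edge: float):
    """Honeycomb node positions within a disk and the lattice edge index pairs.

    Nodes are the two interleaved triangular sublattices of the honeycomb
    (interior degree 3); returned in a deterministic order.
    """
    v1 = np.array([math.sqrt(3.0) * edge, 0.0])
    v2 = np.array([math.sqrt(3.0) * edge / 2.0, 1.5 * edge])
    offset_b = np.array([0.0, edge])
    n_max = int(math.ceil(radius / edge)) + 2

    key_to_id: dict[tuple[int, int, int], int] = {}
    positions: list[np.ndarray] = []
    for n2 in range(-n_max, n_max + 1):
        for n1 in range(-n_max, n_max + 1):
            base = n1 * v1 + n2 * v2
            for sub, pos in ((0, base), (1, base + offset_b)):
                if pos @ pos <= radius * radius:
                    key_to_id[(n1, n2, sub)] = len(positions)
                    positions.append(pos)
    # honeycomb bonds: B(n1,n2) connects to A(n1,n2), A(n1,n2+1), A(n1-1,n2+1)
    edges: list[tuple[int, int]] = []
    for (n1, n2, sub), idx in key_to_id.items():
        if sub != 1:
            continue
        for a_key in ((n1, n2, 0), (n1, n2 + 1, 0), (n1 - 1, n2 + 1, 0)):
            j = key_to_id.get(a_key)
            if j is not None:
                edges.append((min(idx, j), max(idx, j)))
    if not positions:
        return np.zeros((0, 2)), []
    return np.asarray(positions), sorted(set(edges))


def _largest_component(positions: np.ndarray, edges: list[tuple[int, int]]):
    """Restrict a lattice to its largest connected component, reindexed."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(positions)))
    g.add_edges_from(edges)
    if g.number_of_nodes() == 0:
        return positions, edges
    keep = sorted(max(nx.connected_components(g), key=lambda c: (len(c), -min(c))))
    remap = {old: new for new, old in enumerate(keep)}
    new_edges = sorted(
        (remap[a], remap[b]) for a, b in edges if a in remap and b in remap
    )
    return positions[keep], new_edges


def _project(plane_xy: np.ndarray, shell_radius: float, mode: str,
             z_flat: float) -> np.ndarray:
    """Map planar lattice coordinates onto the layer surface."""
    out = np.zeros((len(plane_xy), 3))
    if mode == "flat":
        out[:, :2] = plane_xy
        out[:, 2] = z_flat
        return out
    # inverse Lambert azimuthal equal-area, pole at +z
    rho = np.linalg.norm(plane_xy, axis=1)
    # clip at the equator so jittered rim nodes stay on the hemisphere
    ratio = np.clip(rho / (2.0 * shell_radius), 0.0, math.sqrt(0.5))
    c = 2.0 * np.arcsin(ratio)  # polar angle from the pole
    phi = np.arctan2(plane_xy[:, 1], plane_xy[:, 0])
    out[:, 0] = shell_radius * np.sin(c) * np.cos(phi)
    out[:, 1] = shell_radius * np.sin(c) * np.sin(phi)
    out[:, 2] = shell_radius * np.cos(c)
    return out


def generate_retina(params: RetinaParams) -> SyntheticRetina:
    """Generate a two-plexus reticulated network with vertical sprouts.

    Deterministic for a fixed ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    mode = params.geometry_mode
    r_outer = params.shell_radius_um  # secondary (deep) plexus shell
    r_inner = r_outer - params.layer_separation_um  # primary (superficial)

    if mode == "hemisphere":
        plane_radius = math.sqrt(2.0) * r_outer  # full hemisphere footprint
    else:
        plane_radius = r_outer
    if params.mesh_edge_um >= plane_radius:
        raise DegenerateGeometryError(
            f"mesh_edge_um={params.mesh_edge_um} does not fit the "
            f"{plane_radius:.0f} µm footprint"
        )

    plane_xy, lattice_edges = _honeycomb_disk(plane_radius, params.mesh_edge_um)
    # disk clipping can strand small fragments at the rim; keep each layer's
    # largest connected patch so the generated plexus is a single mesh
    plane_xy, lattice_edges = _largest_component(plane_xy, lattice_edges)
    n_lattice = len(plane_xy)
    if n_lattice < 4 or not lattice_edges:
        raise DegenerateGeometryError("lattice degenerate: too few nodes")

    graph = VascularGraph()
    layer_specs = [
        (PRIMARY, r_inner, params.layer_separation_um),
        (SECONDARY, r_outer, 0.0),
    ]
    layer_node_ids: dict[str, np.ndarray] = {}
    next_id = 0
    for comp, shell_r, z_flat in layer_specs:
        jitter = rng.normal(0.0, params.jitter_um, size=plane_xy.shape)
        scale = shell_r / r_outer if mode == "hemisphere" else 1.0
        pts3 = _project(plane_xy * scale + jitter, shell_r, mode, z_flat)
        ids = np.arange(next_id, next_id + n_lattice)
        for nid, p in zip(ids, pts3):
            graph.add_node(int(nid), p, params.vessel_radius_um)
        for a, b in lattice_edges:
            graph.add_edge(int(ids[a]), int(ids[b]), params.vessel_radius_um, comp)
        layer_node_ids[comp] = ids
        next_id += n_lattice

    # triangle-forming chords within each layer
    adj = graph.adjacency()
    for comp, _, _ in layer_specs:
        for nid in layer_node_ids[comp]:
            nid = int(nid)
            neighbours = sorted(n for n in adj[nid])
            if len(neighbours) < 2:
                continue
            if rng.random() >= params.chord_rate:
                continue
            u, w = rng.choice(len(neighbours), size=2, replace=False)
            u, w = neighbours[int(u)], neighbours[int(w)]
            if u in adj[w]:
                continue  # chord already present
            graph.add_edge(u, w, params.vessel_radius_um, comp)
            adj[u].add(w)
            adj[w].add(u)

    # vertical sprouts: primary node → nearest secondary node
    primary_ids = layer_node_ids[PRIMARY]
    secondary_ids = layer_node_ids[SECONDARY]
    sec_pos = np.array([graph.nodes[int(i)].position for i in secondary_ids])
    tree = cKDTree(sec_pos)
    emit = rng.random(len(primary_ids)) < params.sprout_density
    for nid, do_emit in zip(primary_ids, emit):
        if not do_emit:
            continue
        nid = int(nid)
        d, j = tree.query(graph.nodes[nid].position, k=2)
        # tie-break equidistant candidates by lowest node id
        if len(np.atleast_1d(d)) > 1 and abs(d[0] - d[1]) < 1e-9:
            j = min(j[0], j[1])
        else:
            j = np.atleast_1d(j)[0]
        graph.add_edge(nid, int(secondary_ids[int(j)]),
                       params.vessel_radius_um, SPROUT_TAG)

    return SyntheticRetina(graph=graph, params=params)


def apply_oir(retina: SyntheticRetina, oir: OirParams) -> SyntheticRetina:
    """Delete edges per compartment with the OIR probabilities.

    Secondary-plexus and sprout edges are deleted everywhere; primary edges
    only inside the central region (normalised distance from the optic-disk
    axis below ``central_fraction``).  Nodes left isolated are removed.
    Deterministic for a fixed ``oir.seed``.
    """
    rng = np.random.default_rng(oir.seed)
    r_max = retina.params.shell_radius_um
    origin = retina.origin_um
    survivors: list[Edge] = []
    for edge in retina.graph.edges:
        if edge.compartment is None:
            raise ValueError("apply_oir requires compartment tags on every edge")
        mid = 0.5 * (edge.polyline[0] + edge.polyline[-1]) - origin
        frac = math.hypot(mid[0], mid[1]) / r_max
        if edge.compartment == SECONDARY:
            p = oir.p_secondary
        elif edge.compartment == SPROUT_TAG:
            p = oir.p_sprout
        elif frac < oir.central_fraction:
            p = oir.p_primary_central
        else:
            p = 0.0
        if rng.random() >= p:
            survivors.append(edge)

    used = {e.node_a for e in survivors} | {e.node_b for e in survivors}
    nodes = {i: retina.graph.nodes[i] for i in sorted(used)}
    graph = VascularGraph(nodes, survivors, validate=False)
    return SyntheticRetina(
        graph=graph, params=retina.params, oir=oir, origin_um=retina.origin_um.copy()
    )


# ---------------------------------------------------------------------------
# voxelisation
# ---------------------------------------------------------------------------


def voxelize(
    graph: VascularGraph,
    voxel_size_um: float,
    pad_um: float | None = None,
) -> tuple[VolumeImage, LabelVolume]:
    """Rasterise a graph as a union of capsules around its polylines.

    The label of a foreground voxel is the compartment of the nearest
    contributing edge (sprout winning distance ties, since sprouts are thin
    and otherwise under-counted).  An empty graph yields all-background
    volumes with valid metadata.
    """
    if voxel_size_um <= 0:
        raise ValueError("voxel_size_um must be positive")
    if graph.n_edges == 0:
        shape = (1, 1, 1)
        vol = VolumeImage(np.zeros(shape, dtype=np.uint8), voxel_size_um)
        lab = LabelVolume(np.zeros(shape, dtype=np.uint8), voxel_size_um)
        return vol, lab

    pts = np.concatenate([e.polyline for e in graph.edges])
    max_r = max(e.radius for e in graph.edges)
    pad = max_r + voxel_size_um if pad_um is None else pad_um
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    shape_xyz = np.maximum(np.ceil((hi - lo) / voxel_size_um).astype(int), 1)
    nz, ny, nx = int(shape_xyz[2]), int(shape_xyz[1]), int(shape_xyz[0])

    best = np.full((nz, ny, nx), np.inf, dtype=np.float32)
    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    tol = 1e-5

    def axis_coords(n, o):  # voxel centre coordinate along one axis
        return o + (np.arange(n) + 0.5) * voxel_size_um

    for edge in graph.edges:
        code = SPROUT if edge.compartment == SPROUT_TAG else PLEXUS
        for p0, p1 in zip(edge.polyline[:-1], edge.polyline[1:]):
            seg_lo = np.minimum(p0, p1) - edge.radius - voxel_size_um
            seg_hi = np.maximum(p0, p1) + edge.radius + voxel_size_um
            i0 = np.maximum(((seg_lo - lo) / voxel_size_um).astype(int), 0)
            i1 = np.minimum(
                np.ceil((seg_hi - lo) / voxel_size_um).astype(int), shape_xyz
            )
            if np.any(i0 >= i1):
                continue
            xs = axis_coords(nx, lo[0])[i0[0]:i1[0]]
            ys = axis_coords(ny, lo[1])[i0[1]:i1[1]]
            zs = axis_coords(nz, lo[2])[i0[2]:i1[2]]
            gx = xs[None, None, :]
            gy = ys[None, :, None]
            gz = zs[:, None, None]
            d = p1 - p0
            dd = float(d @ d)
            rx = gx - p0[0]
            ry = gy - p0[1]
            rz = gz - p0[2]
            if dd == 0.0:
                dist2 = rx**2 + ry**2 + rz**2
            else:
                t = np.clip((rx * d[0] + ry * d[1] + rz * d[2]) / dd, 0.0, 1.0)
                dist2 = (rx - t * d[0]) ** 2 + (ry - t * d[1]) ** 2 + (rz - t * d[2]) ** 2
            dist = np.sqrt(dist2, dtype=np.float32)
            inside = dist <= edge.radius
            if not inside.any():
                continue
            sub = (slice(i0[2], i1[2]), slice(i0[1], i1[1]), slice(i0[0], i1[0]))
            bsub = best[sub]
            lsub = labels[sub]
            closer = inside & (dist < bsub - tol)
            tie = inside & ~closer & (dist <= bsub + tol)
            lsub[closer] = code
            if code == SPROUT:
                lsub[tie] = SPROUT
            np.minimum(bsub, np.where(inside, dist, np.inf), out=bsub)
            best[sub] = bsub
            labels[sub] = lsub

    mask = np.isfinite(best)
    vol = VolumeImage(mask.astype(np.uint8), voxel_size_um, origin_um=lo)
    lab = LabelVolume(labels, voxel_size_um, origin_um=lo)
    return vol, lab


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------


def make_phantom(kind: str, **geometry) -> tuple[VolumeImage, LabelVolume]:
    """Minimal fixtures with exact ground-truth labels.

    kinds
    -----
    ``radial_tube``
        one vertical (z-axis) tube; every foreground voxel is sprout.
    ``tangential_tube``
        one horizontal tube; every foreground voxel is plexus.
    ``two_layer_slab``
        two stacked layers of parallel horizontal tubes bridged by
        ``n_sprouts`` vertical tubes.

    geometry keywords (all µm): ``length_um`` (default 100), ``radius_um``
    (4), ``voxel_size_um`` (2); for the slab additionally ``extent_um``
    (200), ``separation_um`` (120), ``tube_spacing_um`` (40), ``n_sprouts``
    (4).
    """
    radius = float(geometry.get("radius_um", 4.0))
    voxel = float(geometry.get("voxel_size_um", 2.0))
    if radius <= 0 or voxel <= 0:
        raise ValueError("phantom geometry must be positive")
    graph = VascularGraph()
    if kind == "radial_tube":
        length = float(geometry.get("length_um", 100.0))
        graph.add_node(0, (0.0, 0.0, 0.0), radius)
        graph.add_node(1, (0.0, 0.0, length), radius)
        graph.add_edge(0, 1, radius, SPROUT_TAG)
    elif kind == "tangential_tube":
        length = float(geometry.get("length_um", 100.0))
        graph.add_node(0, (0.0, 0.0, 0.0), radius)
        graph.add_node(1, (length, 0.0, 0.0), radius)
        graph.add_edge(0, 1, radius, PRIMARY)
    elif kind == "two_layer_slab":
        extent = float(geometry.get("extent_um", 200.0))
        sep = float(geometry.get("separation_um", 120.0))
        spacing = float(geometry.get("tube_spacing_um", 40.0))
        n_sprouts = int(geometry.get("n_sprouts", 4))
        if extent <= 0 or sep <= 0 or spacing <= 0 or n_sprouts < 0:
            raise ValueError("phantom geometry must be positive")
        nid = 0
        rails: dict[tuple[int, float], tuple[int, int]] = {}
        n_rails = int(extent // spacing) + 1
        for li, z in enumerate((0.0, sep)):
            for k in range(n_rails):
                y = k * spacing
                graph.add_node(nid, (0.0, y, z), radius)
                graph.add_node(nid + 1, (extent, y, z), radius)
                comp = SECONDARY if li == 0 else PRIMARY
                graph.add_edge(nid, nid + 1, radius, comp)
                rails[(li, y)] = (nid, nid + 1)
                nid += 2
        for s in range(n_sprouts):
            x = (s + 0.5) * extent / max(n_sprouts, 1)
            y = (s % n_rails) * spacing
            graph.add_node(nid, (x, y, 0.0), radius)
            graph.add_node(nid + 1, (x, y, sep), radius)
            graph.add_edge(nid, nid + 1, radius, SPROUT_TAG)
            nid += 2
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    return voxelize(graph, voxel)
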