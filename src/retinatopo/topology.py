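"""Euler characteristic, connectivity and clustering-coefficient analytics.

Two routes to the Euler characteristic χ are provided.  For a binary volume,
χ = n₀ − n₁ + n₂ − n₃ where n₀…n₃ count the distinct vertices, edges, faces
and cubes of the closed cubical complex of the foreground (cells shared
between voxels counted once).  For a traced skeleton graph — a 1-complex —
the faces and cubes vanish and χ = |V| − |E|.  The network's global
loop-richness is summarised as connectivity = 1 − χ: for a connected network
it equals the number of independent loops.

Local organisation is measured by the Watts–Strogatz clustering coefficient
C_i = 2·|links among neighbours of i| / (k_i (k_i − 1)), with C_i = 0 for
nodes of degree < 2 (terminal nodes carry a value rather than being
excluded).  Multi-edges are collapsed for the neighbour logic.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np

from .graph import VascularGraph
from .volume import VolumeImage

#: clustering histogram bin width over (0, 1]; exact zeros get their own bin
CLUSTERING_BIN_WIDTH = 0.05


@dataclasses.dataclass
class CubicalCounts:
    """Cell counts of the cubical complex of a binary volume."""

    n0: int  # vertices
    n1: int  # edges
    n2: int  # faces
    n3: int  # cubes (voxels)

    @property
    def chi(self) -> int:
        return self.n0 - self.n1 + self.n2 - self.n3


@dataclasses.dataclass
class TopologyMetrics:
    chi: int
    connectivity: int
    clustering: dict[int, float]
    mean_clustering: float
    degree_hist: dict[int, int]
    clustering_hist: dict[str, int]
    zero_fraction: float
    modal_degree: int | None
    modal_clustering: float | None


def _as_bool_volume(volume) -> np.ndarray:
    data = volume.data if isinstance(volume, VolumeImage) else np.asarray(volume)
    if not np.isin(data, (0, 1)).all():
        raise ValueError("Euler computation requires a binary volume")
    return data.astype(bool)


def euler_voxel(volume) -> tuple[int, CubicalCounts]:
    """χ and cell counts of the cubical complex of a binary volume.

    Each foreground voxel contributes a closed unit cube; vertices, edges and
    faces shared between neighbouring voxels are counted once, implemented by
    OR-ing the occupancy over each cell's incident voxels on staggered grids.
    """
    b = _as_bool_volume(volume)
    nz, ny, nx = b.shape

    def union(shifts, shape):
        acc = np.zeros(shape, dtype=bool)
        for dz, dy, dx in shifts:
            acc[dz : dz + nz, dy : dy + ny, dx : dx + nx] |= b
        return int(acc.sum())

    corners = [(dz, dy, dx) for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)]
    n0 = union(corners, (nz + 1, ny + 1, nx + 1))

    n1 = (
        union([(dz, dy, 0) for dz in (0, 1) for dy in (0, 1)], (nz + 1, ny + 1, nx))
        + union([(dz, 0, dx) for dz in (0, 1) for dx in (0, 1)], (nz + 1, ny, nx + 1))
        + union([(0, dy, dx) for dy in (0, 1) for dx in (0, 1)], (nz, ny + 1, nx + 1))
    )
    n2 = (
        union([(dz, 0, 0) for dz in (0, 1)], (nz + 1, ny, nx))  # xy faces
        + union([(0, dy, 0) for dy in (0, 1)], (nz, ny + 1, nx))  # xz faces
        + union([(0, 0, dx) for dx in (0, 1)], (nz, ny, nx + 1))  # yz faces
    )
    n3 = int(b.sum())
    counts = CubicalCounts(n0, n1, n2, n3)
    return counts.chi, counts


def euler_graph(graph: VascularGraph) -> int:
    """χ = |V| − |E| of a skeleton graph (parallel edges counted individually)."""
    return graph.n_nodes - graph.n_edges


def connectivity(chi: int) -> int:
    """The loop-richness measure 1 − χ."""
    return 1 - chi


def clustering_coefficients(graph: VascularGraph) -> dict[int, float]:
    """Local clustering coefficient per node on the simple undirected view."""
    adj = graph.adjacency()
    out: dict[int, float] = {}
    for node, neighbours in adj.items():
        k = len(neighbours)
        if k < 2:
            out[node] = 0.0
            continue
        nb = sorted(neighbours)
        links = 0
        for i, u in enumerate(nb):
            adj_u = adj[u]
            for w in nb[i + 1 :]:
                if w in adj_u:
                    links += 1
        out[node] = 2.0 * links / (k * (k - 1))
    return out


def _clustering_hist(values: np.ndarray) -> dict[str, int]:
    hist: dict[str, int] = {"0": int(np.sum(values == 0.0))}
    n_bins = int(round(1.0 / CLUSTERING_BIN_WIDTH))
    positive = values[values > 0.0]
    # right-closed bins (lo, hi] so a value of exactly 0.05 lands in (0, 0.05]
    idx = np.clip(
        np.ceil(positive / CLUSTERING_BIN_WIDTH - 1e-9).astype(int) - 1, 0, n_bins - 1
    )
    counts = np.bincount(idx, minlength=n_bins) if len(positive) else np.zeros(n_bins, int)
    for k in range(n_bins):
        lo, hi = k * CLUSTERING_BIN_WIDTH, (k + 1) * CLUSTERING_BIN_WIDTH
        hist[f"({lo:.2f},{hi:.2f}]"] = int(counts[k])
    return hist


def clustering_summary(graph: VascularGraph) -> TopologyMetrics:
    """Assemble χ, connectivity, mean clustering, histograms and modes."""
    chi = euler_graph(graph)
    cc = clustering_coefficients(graph)
    values = np.array(sorted(cc.values())) if cc else np.zeros(0)
    mean_c = float(values.mean()) if len(values) else 0.0
    zero_fraction = float(np.mean(values == 0.0)) if len(values) else 0.0

    degrees = graph.degrees()
    degree_hist = dict(sorted(Counter(degrees.values()).items()))
    modal_degree = (
        max(degree_hist, key=lambda d: (degree_hist[d], -d)) if degree_hist else None
    )

    chist = _clustering_hist(values)
    modal_clustering: float | None = None
    if len(values):
        best_key = max(chist, key=lambda k: (chist[k], k == "0"))
        if best_key == "0":
            modal_clustering = 0.0
        else:
            lo, hi = best_key.strip("(]").split(",")
            modal_clustering = 0.5 * (float(lo) + float(hi))
    return TopologyMetrics(
        chi=chi,
        connectivity=connectivity(chi),
        clustering=cc,
        mean_clustering=mean_c,
        degree_hist=degree_hist,
        clustering_hist=chist,
        zero_fraction=zero_fraction,
        modal_degree=modal_degree,
        modal_clustering=modal_clustering,
    )
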