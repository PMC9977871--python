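"""Cell adjacency graph from a label volume.

The distance between two cells is the number of simultaneous morphological
dilation rounds (6-connected structuring element) until their masks meet;
face-adjacent cells are at distance 1.  The graph construction uses one
city-block distance transform per label — a single simultaneous sweep in
disguise — and is verified against pairwise round-by-round dilation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import ndimage

__all__ = [
    "AdjacencyGraph",
    "merge_distance",
    "build_adjacency_graph",
    "neighbors",
    "export_graph",
]

_CROSS = ndimage.generate_binary_structure(3, 1)


@dataclass
class AdjacencyGraph:
    """Weighted undirected cell graph.

    ``graph`` nodes are cell labels with a ``size`` attribute (voxel
    count); edge weights are integer dilation distances in [1, r_max].
    """

    graph: nx.Graph
    r_max: int

    @property
    def labels(self) -> list[int]:
        return sorted(self.graph.nodes)

    def size(self, label: int) -> int:
        return int(self.graph.nodes[label]["size"])

    def weight(self, i: int, j: int) -> int | None:
        data = self.graph.get_edge_data(i, j)
        return None if data is None else int(data["weight"])


def merge_distance(mask_i: np.ndarray, mask_j: np.ndarray, r_max: int = 10) -> int | None:
    """Smallest r >= 1 such that the r-fold 6-connected dilations of the two
    masks intersect (i.e. the dilated cells become one connected component);
    ``None`` if not reached within ``r_max`` rounds."""
    mask_i = np.asarray(mask_i, dtype=bool)
    mask_j = np.asarray(mask_j, dtype=bool)
    if not mask_i.any() or not mask_j.any():
        raise ValueError("masks must be nonempty")
    if (mask_i & mask_j).any():
        raise ValueError("masks overlap; labels must be disjoint")
    a, b = mask_i, mask_j
    for r in range(1, r_max + 1):
        a = ndimage.binary_dilation(a, _CROSS)
        b = ndimage.binary_dilation(b, _CROSS)
        if (a & b).any():
            return r
    return None


def build_adjacency_graph(x: np.ndarray, r_max: int = 3) -> AdjacencyGraph:
    """Build the adjacency graph of all nonzero labels in ``x``.

    Equivalent to calling :func:`merge_distance` on every label pair: with
    d_i the city-block distance map to cell i, the merge distance is
    min over voxels of max(d_i, d_j), because an r-fold cross dilation
    covers exactly the voxels within city-block distance r.
    """
    x = np.asarray(x)
    labels, sizes = np.unique(x[x > 0], return_counts=True)
    g = nx.Graph()
    for lab, size in zip(labels, sizes):
        g.add_node(int(lab), size=int(size))
    if len(labels) >= 2:
        dist_maps = {}
        for lab in labels:
            d = ndimage.distance_transform_cdt(x != lab, metric="taxicab")
            dist_maps[int(lab)] = np.minimum(d, r_max + 1).astype(np.int32)
        for ai, i in enumerate(labels):
            di = dist_maps[int(i)]
            for j in labels[ai + 1 :]:
                w = int(np.minimum(np.maximum(di, dist_maps[int(j)]), r_max + 1).min())
                if 1 <= w <= r_max:
                    g.add_edge(int(i), int(j), weight=w)
    return AdjacencyGraph(graph=g, r_max=r_max)


def neighbors(g: AdjacencyGraph, i: int) -> set[int]:
    """Distance-1 neighbors N_i of cell ``i``."""
    if i not in g.graph:
        raise KeyError(f"label {i} not in adjacency graph")
    return {j for j in g.graph.neighbors(i) if g.graph.edges[i, j]["weight"] == 1}


def export_graph(g: AdjacencyGraph, out_prefix: str | Path) -> None:
    """Write edge-list CSV (i, j, weight), vertex table CSV (label, size,
    deg, wdeg), and GraphML."""
    from .tracking import track_features

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}_edges.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["i", "j", "weight"])
        for i, j, data in sorted(g.graph.edges(data=True)):
            w.writerow([i, j, data["weight"]])
    feats = track_features(g)
    with open(f"{prefix}_vertices.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "size", "deg", "wdeg"])
        for lab in g.labels:
            f = feats[lab]
            w.writerow([lab, f.S, f.N, f.D])
    nx.write_graphml(g.graph, f"{prefix}.graphml")
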