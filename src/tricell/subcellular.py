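"""Sub-cellular features from a label volume and its adjacency graph.

An anticlinal wall voxel is one whose 26-neighborhood (itself included)
touches both cells of a distance-1 pair; a three-cell-wall junction voxel
touches three mutually neighboring cells.  Wall point sets are ordered into
polylines and cut at junctions so each segment spans two junctions where
available.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .cellgraph import AdjacencyGraph, neighbors

logger = logging.getLogger(__name__)

__all__ = [
    "Polyline3D",
    "wall_segment",
    "junctions",
    "order_segment",
    "extract_all_features",
    "export_features",
]

_CUBE = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity + self
_MAX_STEP = 2.0 * np.sqrt(3.0)


@dataclass
class Polyline3D:
    """Ordered (z, y, x) voxel polyline for one wall segment."""

    points: np.ndarray  # (n, 3) int
    cells: tuple[int, ...]  # defining label pair or triple

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 1:
            raise ValueError("polyline needs >= 1 (z, y, x) point")
        if len(self.points) > 1:
            steps = np.linalg.norm(np.diff(self.points.astype(float), axis=0), axis=1)
            # walls are voxel sheets, not curves, so nearest-neighbor chains can
            # occasionally exceed the nominal bound; warn rather than fail
            if steps.max() > _MAX_STEP + 1e-9:
                logger.warning(
                    "polyline chaining step %.2f exceeds nominal bound %.2f",
                    steps.max(), _MAX_STEP,
                )

    def __len__(self) -> int:
        return len(self.points)

    def length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points.astype(float), axis=0), axis=1).sum())


def _touch_mask(x: np.ndarray, label: int) -> np.ndarray:
    """Voxels whose 26-neighborhood (self included) intersects ``label``."""
    return ndimage.binary_dilation(x == label, _CUBE)


def wall_segment(
    x: np.ndarray, g: AdjacencyGraph, i: int, j: int
) -> set[tuple[int, int, int]]:
    """All voxels shared by cells i and j (26-neighborhood incidence).
    Symmetric in (i, j); requires j to be a distance-1 neighbor of i."""
    _require_neighbors(g, i, j)
    both = _touch_mask(x, i) & _touch_mask(x, j)
    return set(map(tuple, np.argwhere(both).tolist()))


def junctions(
    x: np.ndarray, g: AdjacencyGraph, i: int, j: int
) -> set[tuple[int, int, int]]:
    """Voxels shared by cells i, j and any common neighbor k in N_i ∩ N_j.
    Empty when the two cells have no common neighbor."""
    _require_neighbors(g, i, j)
    common = neighbors(g, i) & neighbors(g, j)
    if not common:
        return set()
    both = _touch_mask(x, i) & _touch_mask(x, j)
    out: set[tuple[int, int, int]] = set()
    for k in sorted(common):
        tri = both & _touch_mask(x, k)
        out.update(map(tuple, np.argwhere(tri).tolist()))
    return out


def _require_neighbors(g: AdjacencyGraph, i: int, j: int) -> None:
    if j not in neighbors(g, i):
        w = g.weight(i, j)
        dist = "unconnected" if w is None else f"distance {w}"
        raise ValueError(f"cells {i} and {j} are not neighbors ({dist}); need distance 1")


def order_segment(points) -> Polyline3D:
    """Order an unstructured wall point set into a polyline by
    nearest-neighbor chaining, starting from the point most distant from the
    set centroid.  Only the largest 26-connected component is retained (and
    logged) if the set is disconnected."""
    pts = np.asarray(sorted(points), dtype=int)
    if pts.size == 0:
        raise ValueError("cannot order an empty point set")
    pts = _largest_component(pts)
    n = len(pts)
    if n == 1:
        return Polyline3D(points=pts, cells=())
    centroid = pts.mean(axis=0)
    start = int(np.argmax(np.linalg.norm(pts - centroid, axis=1)))
    remaining = np.ones(n, dtype=bool)
    order = [start]
    remaining[start] = False
    fpts = pts.astype(float)
    for _ in range(n - 1):
        cur = fpts[order[-1]]
        d = np.linalg.norm(fpts - cur, axis=1)
        d[~remaining] = np.inf
        nxt = int(np.argmin(d))
        order.append(nxt)
        remaining[nxt] = False
    return Polyline3D(points=pts[order], cells=())


def _largest_component(pts: np.ndarray) -> np.ndarray:
    mins = pts.min(axis=0)
    local = pts - mins
    shape = tuple(local.max(axis=0) + 1)
    vol = np.zeros(shape, dtype=bool)
    vol[tuple(local.T)] = True
    lab, n = ndimage.label(vol, structure=_CUBE)
    if n > 1:
        sizes = ndimage.sum_labels(vol, lab, index=range(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        logger.info("point set has %d components; keeping largest (%d voxels)", n, int(sizes.max()))
        sel = lab[tuple(local.T)] == keep
        pts = pts[sel]
    return pts


def extract_all_features(
    x: np.ndarray, g: AdjacencyGraph, min_run: int = 3
) -> tuple[dict[tuple[int, int], list[Polyline3D]], set[tuple[int, int, int]]]:
    """Walls and junctions for every distance-1 pair.

    Wall point sets are cut at junction voxels into maximal
    junction-to-junction runs; runs shorter than ``min_run`` voxels are
    dropped as noise (logged).  The junction set is deduplicated
    volume-wide.  Output is independent of label iteration order.
    """
    walls: dict[tuple[int, int], list[Polyline3D]] = {}
    all_junctions: set[tuple[int, int, int]] = set()
    pairs = sorted(
        (min(i, j), max(i, j)) for i in g.labels for j in neighbors(g, i) if i < j
    )
    for i, j in pairs:
        wall_pts = wall_segment(x, g, i, j)
        junc_pts = junctions(x, g, i, j)
        all_junctions.update(junc_pts)
        chain = order_segment(wall_pts)
        segments: list[Polyline3D] = []
        run: list[np.ndarray] = []
        for pt in chain.points:
            run.append(pt)
            if tuple(pt) in junc_pts and len(run) > 1:
                segments.append(run)
                run = [pt]  # next segment starts at this junction
        if run:
            segments.append(run)
        kept = []
        for seg in segments:
            if len(seg) >= min_run:
                kept.append(Polyline3D(points=np.asarray(seg), cells=(i, j)))
            else:
                logger.debug("dropping %d-voxel run on wall (%d, %d)", len(seg), i, j)
        walls[(i, j)] = kept
    return walls, all_junctions


def export_features(
    walls: dict[tuple[int, int], list[Polyline3D]],
    junction_points: set[tuple[int, int, int]],
    out_dir: str | Path,
) -> None:
    """Write junctions and ordered segment CSVs (0-based voxel coordinates,
    z-slice index first; convention stated in the headers)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "junctions.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["# 0-based voxel coordinates, order z,y,x"])
        w.writerow(["z", "y", "x"])
        for z, y, x in sorted(junction_points):
            w.writerow([z, y, x])
    with open(out / "segments.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["# 0-based voxel coordinates, order z,y,x"])
        w.writerow(["segment_id", "cell_i", "cell_j", "point_index", "z", "y", "x"])
        seg_id = 0
        for (i, j), segs in sorted(walls.items()):
            for seg in segs:
                for idx, (z, y, x) in enumerate(seg.points):
                    w.writerow([seg_id, i, j, idx, z, y, x])
                seg_id += 1
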