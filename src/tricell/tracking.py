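"""Cell tracking by adjacency-graph features.

Each detection carries a three-component feature (cell size S, neighbor
count N = deg, mean edge weight D = wdeg).  Consecutive frames are linked
greedily by ascending relative-difference similarity (normalized by the
earlier frame's features, as defined), one-to-one, below a threshold.
Track ids seed from frame 0 and propagate along links; no division or
merge events are modeled, so every node has at most one link in and out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .cellgraph import AdjacencyGraph, build_adjacency_graph, neighbors

logger = logging.getLogger(__name__)

__all__ = [
    "TrackFeature",
    "TrackGraph",
    "track_features",
    "similarity",
    "link_frames",
    "track_sequence",
    "write_track_table",
    "read_track_table",
]


@dataclass(frozen=True)
class TrackFeature:
    """(S, N, D): voxel count, distance-1 neighbor count, weighted degree."""

    S: int
    N: int
    D: float


@dataclass
class TrackGraph:
    """Acyclic oriented graph of detections across frames.

    Nodes are (frame, label); edges advance the frame index by exactly 1
    and every node has at most one incoming and one outgoing link.  Node
    attribute ``track`` holds the track id; ``mask`` optionally holds the
    detection's voxel coordinates for overlap-based matching.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def add_detection(self, frame: int, label: int, track: int, mask=None) -> None:
        self.graph.add_node((frame, label), track=track, mask=mask)

    def add_link(self, frame: int, label_a: int, label_b: int) -> None:
        a, b = (frame, label_a), (frame + 1, label_b)
        if self.graph.out_degree(a) or self.graph.in_degree(b):
            raise ValueError(f"link {a}->{b} violates one-to-one matching")
        self.graph.add_edge(a, b)

    def tracks(self) -> dict[int, tuple[int, int]]:
        """track id -> (begin frame, end frame)."""
        spans: dict[int, tuple[int, int]] = {}
        for (frame, _), data in self.graph.nodes(data=True):
            t = data["track"]
            if t in spans:
                b, e = spans[t]
                spans[t] = (min(b, frame), max(e, frame))
            else:
                spans[t] = (frame, frame)
        return spans

    def n_frames(self) -> int:
        return 1 + max((f for f, _ in self.graph.nodes), default=-1)


def track_features(g: AdjacencyGraph) -> dict[int, TrackFeature]:
    """Per-cell (S, N, D).  N counts distance-1 neighbors; D is the mean
    weight over all stored edges; an isolated vertex gets the D = 0
    sentinel."""
    out = {}
    for lab in g.labels:
        deg = g.graph.degree(lab)
        if deg == 0:
            d = 0.0
        else:
            d = sum(data["weight"] for _, _, data in g.graph.edges(lab, data=True)) / deg
        out[lab] = TrackFeature(S=g.size(lab), N=len(neighbors(g, lab)), D=float(d))
    return out


def similarity(f_i: TrackFeature, f_j: TrackFeature) -> float:
    """Relative feature difference, normalized by the earlier frame's
    feature ``f_i`` (asymmetric by definition):

        sim = |S_i - S_j| / S_i + |N_i - N_j| / N_i + |D_i - D_j| / D_i

    Zero-valued N or D denominators are substituted by 1 (logged) so the
    measure stays finite for isolated cells.
    """
    if f_i.S <= 0:
        raise ValueError("cell size must be positive")
    total = abs(f_i.S - f_j.S) / f_i.S
    for a, b in ((f_i.N, f_j.N), (f_i.D, f_j.D)):
        denom = a
        if denom == 0:
            logger.debug("zero denominator in similarity; substituting 1")
            denom = 1
        total += abs(a - b) / denom
    return float(total)


def link_frames(
    features_t: dict[int, TrackFeature],
    features_t1: dict[int, TrackFeature],
    threshold: float = 0.3,
) -> dict[int, int]:
    """Greedy one-to-one matching between two frames.

    Repeatedly links the unmatched pair (i*, j*) with the smallest
    similarity while it stays below ``threshold``.  Returns a mapping
    {label in frame T -> label in frame T+1}.  O(M^2) similarity
    evaluations.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    pairs = [
        (similarity(fi, fj), i, j)
        for i, fi in features_t.items()
        for j, fj in features_t1.items()
    ]
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    used_i: set[int] = set()
    used_j: set[int] = set()
    matching: dict[int, int] = {}
    for sim, i, j in pairs:
        if sim >= threshold:
            break
        if i in used_i or j in used_j:
            continue
        matching[i] = j
        used_i.add(i)
        used_j.add(j)
    return matching


def track_sequence(
    label_volumes: list[np.ndarray],
    threshold: float = 0.3,
    r_max: int = 3,
    keep_masks: bool = True,
) -> tuple[TrackGraph, list[np.ndarray]]:
    """Track cells through a sequence of label volumes.

    Frame-0 labels seed the track ids; links propagate them, unmatched
    detections open new ids, unmatched prior detections terminate.  Returns
    the track graph and volumes recolored by track id.  Deterministic.
    """
    if not label_volumes:
        raise ValueError("need at least one frame")
    tg = TrackGraph()
    recolored = []
    graphs = [build_adjacency_graph(np.asarray(v), r_max=r_max) for v in label_volumes]
    feats = [track_features(g) for g in graphs]

    next_track = 1
    label_to_track: dict[int, int] = {}
    for t, vol in enumerate(label_volumes):
        vol = np.asarray(vol)
        if t == 0:
            # frame-0 labels seed the track ids
            label_to_track = {lab: lab for lab in graphs[0].labels}
            next_track = max(graphs[0].labels, default=0) + 1
        else:
            matching = link_frames(feats[t - 1], feats[t], threshold)
            if not graphs[t].labels:
                logger.info("frame %d is empty; all open tracks terminate", t)
            new_map: dict[int, int] = {}
            inverse = {j: i for i, j in matching.items()}
            for lab in graphs[t].labels:
                if lab in inverse and inverse[lab] in label_to_track:
                    new_map[lab] = label_to_track[inverse[lab]]
                else:
                    new_map[lab] = next_track
                    next_track += 1
            for i, j in matching.items():
                if i in label_to_track:
                    tg.add_link(t - 1, i, j)
            label_to_track = new_map
        for lab in graphs[t].labels:
            mask = np.argwhere(vol == lab) if keep_masks else None
            tg.add_detection(t, lab, track=label_to_track[lab], mask=mask)
        out = np.zeros_like(vol, dtype=np.int32)
        for lab, tid in label_to_track.items():
            out[vol == lab] = tid
        recolored.append(out)
    return tg, recolored


def write_track_table(tg: TrackGraph, path: str | Path) -> None:
    """Cell Tracking Challenge text style: one line per track
    "id begin end parent" (parent always 0: divisions are not modeled)."""
    with open(path, "w") as fh:
        for tid, (begin, end) in sorted(tg.tracks().items()):
            fh.write(f"{tid} {begin} {end} 0\n")


def read_track_table(path: str | Path) -> dict[int, tuple[int, int, int]]:
    """Read "id begin end parent" lines -> {id: (begin, end, parent)}."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"malformed track line: {line!r}")
            tid, b, e, p = map(int, parts)
            out[tid] = (b, e, p)
    return out
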