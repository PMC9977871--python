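"""Evaluation metrics: boundary precision/recall at range R, cell-count
statistics, junction detection P/R/F at a voxel tolerance, wall-segment
curve metrics (end-point displacement, discrete Fréchet distance, length
difference), and AOGM-based tracking accuracy (TRA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .subcellular import Polyline3D
from .tracking import TrackGraph

__all__ = [
    "BoundaryScore",
    "AOGMWeights",
    "label_boundary",
    "boundary_prf",
    "count_stats",
    "junction_prf",
    "ede",
    "frechet",
    "length_metrics",
    "aogm",
    "aogm_empty",
    "tra",
]


@dataclass(frozen=True)
class BoundaryScore:
    TP: int
    FN: int
    FP: int
    R: float

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else 0.0

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else 0.0

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass(frozen=True)
class AOGMWeights:
    """Graph edit-operation weights.  This convention (node split 5, missing
    node 10, spurious node 1, edge delete 1, edge add 1.5, edge semantics 1)
    follows the tracking-challenge benchmark; all configurable."""

    w_NS: float = 5.0
    w_FN: float = 10.0
    w_FP: float = 1.0
    w_ED: float = 1.0
    w_EA: float = 1.5
    w_EC: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_NS, self.w_FN, self.w_FP, self.w_ED, self.w_EA, self.w_EC) < 0:
            raise ValueError("AOGM weights must be >= 0")


def label_boundary(labels: np.ndarray) -> np.ndarray:
    """Boundary mask of a label volume: a voxel is boundary if any of its
    6-neighbors carries a different label."""
    labels = np.asarray(labels)
    mask = np.zeros(labels.shape, dtype=bool)
    for axis in range(3):
        a = np.swapaxes(labels, 0, axis)
        m = np.swapaxes(mask, 0, axis)
        diff = a[1:] != a[:-1]
        m[1:] |= diff
        m[:-1] |= diff
    return mask


def boundary_prf(gt_boundary: np.ndarray, pred_boundary: np.ndarray, R: float = 5.0) -> BoundaryScore:
    """Boundary detection score at Euclidean tolerance ``R``.

    TP/FN are counted on the ground-truth side (a ground-truth boundary
    voxel is hit iff a predicted boundary voxel lies within ``R``), FP on
    the prediction side.
    """
    gt = np.asarray(gt_boundary, dtype=bool)
    pred = np.asarray(pred_boundary, dtype=bool)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    if not gt.any():
        raise ValueError("empty ground-truth boundary: recall is undefined")
    if pred.any():
        dist_to_pred = ndimage.distance_transform_edt(~pred)
    else:
        dist_to_pred = np.full(gt.shape, np.inf)
    dist_to_gt = ndimage.distance_transform_edt(~gt)
    tp = int((dist_to_pred[gt] <= R).sum())
    fn = int(gt.sum()) - tp
    fp = int((dist_to_gt[pred] > R).sum())
    return BoundaryScore(TP=tp, FN=fn, FP=fp, R=R)


def count_stats(label_volumes: list[np.ndarray]) -> tuple[float, float]:
    """Mean and population standard deviation of per-frame cell counts."""
    if not label_volumes:
        raise ValueError("need at least one frame")
    counts = [len(np.unique(v[np.asarray(v) > 0])) for v in map(np.asarray, label_volumes)]
    return float(np.mean(counts)), float(np.std(counts))


def junction_prf(detected, truth, tol: float = 5.0) -> tuple[float, float, float]:
    """Precision, recall and F1 of junction detection.

    Greedy one-to-one assignment by ascending distance within ``tol``
    voxels; unmatched detections count as FP, unmatched truths as FN.
    """
    det = np.asarray(sorted(detected), dtype=float).reshape(-1, 3) if len(detected) else np.empty((0, 3))
    tru = np.asarray(sorted(truth), dtype=float).reshape(-1, 3) if len(truth) else np.empty((0, 3))
    tp = 0
    if len(det) and len(tru):
        d = cdist(det, tru)
        pairs = sorted(
            ((d[a, b], a, b) for a in range(len(det)) for b in range(len(tru)) if d[a, b] <= tol)
        )
        used_a: set[int] = set()
        used_b: set[int] = set()
        for _, a, b in pairs:
            if a in used_a or b in used_b:
                continue
            used_a.add(a)
            used_b.add(b)
            tp += 1
    fp = len(det) - tp
    fn = len(tru) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def _pts(p) -> np.ndarray:
    if isinstance(p, Polyline3D):
        return p.points.astype(float)
    return np.asarray(p, dtype=float).reshape(-1, 3)


def ede(P, Q, mode: str = "corrected") -> float:
    """End-point displacement error between two segments.

    ``corrected`` (default): half the sum of the two between-curve endpoint
    displacements, minimized over the orientation of ``Q``.  ``as_printed``:
    half the sum of the two within-curve endpoint chords — kept verbatim
    because that is how the formula is printed, even though it measures
    curve extent rather than displacement (it is nonzero for P == Q).
    """
    p, q = _pts(P), _pts(Q)
    if mode == "as_printed":
        return 0.5 * (
            float(np.linalg.norm(p[0] - p[-1])) + float(np.linalg.norm(q[0] - q[-1]))
        )
    if mode != "corrected":
        raise ValueError(f"unknown mode {mode!r}")
    forward = np.linalg.norm(p[0] - q[0]) + np.linalg.norm(p[-1] - q[-1])
    backward = np.linalg.norm(p[0] - q[-1]) + np.linalg.norm(p[-1] - q[0])
    return 0.5 * float(min(forward, backward))


def _frechet_dp(p: np.ndarray, q: np.ndarray) -> float:
    """Discrete Fréchet distance by dynamic programming over monotone
    couplings (endpoints pinned, indices advance by 0 or 1)."""
    d = cdist(p, q)
    m, n = d.shape
    ca = np.empty((m, n))
    ca[0, 0] = d[0, 0]
    for i in range(1, m):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
    for j in range(1, n):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, m):
        for j in range(1, n):
            ca[i, j] = max(min(ca[i - 1, j], ca[i - 1, j - 1], ca[i, j - 1]), d[i, j])
    return float(ca[-1, -1])


def frechet(P, Q, orientation: str = "min") -> float:
    """Discrete Fréchet distance between two polylines.

    ``orientation="min"`` (default) reports the minimum over the two
    orientations of ``Q`` because manually traced segments have no
    canonical direction; ``orientation="fixed"`` evaluates the coupling
    definition exactly as given.  Symmetric in either mode.
    """
    p, q = _pts(P), _pts(Q)
    if orientation == "fixed":
        return _frechet_dp(p, q)
    if orientation != "min":
        raise ValueError(f"unknown orientation {orientation!r}")
    return min(_frechet_dp(p, q), _frechet_dp(p, q[::-1]))


def length_metrics(P, Q) -> tuple[float, float]:
    """(LD, DP): absolute length difference in voxels and its percentage of
    the ground-truth length, where ``Q`` is the ground-truth segment."""
    p, q = _pts(P), _pts(Q)
    len_p = float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum()) if len(p) > 1 else 0.0
    len_q = float(np.linalg.norm(np.diff(q, axis=0), axis=1).sum()) if len(q) > 1 else 0.0
    if len_q == 0:
        raise ValueError("zero-length ground-truth segment")
    ld = abs(len_p - len_q)
    return ld, 100.0 * ld / len_q


def _match_nodes(reference: TrackGraph, result: TrackGraph) -> dict:
    """Reference node -> result node by majority mask overlap (a result
    detection matches a reference detection when it covers more than half of
    the reference voxels).  Falls back to identical (frame, label) keys when
    masks are absent."""
    mapping = {}
    ref_by_frame: dict[int, list] = {}
    for node, data in reference.graph.nodes(data=True):
        ref_by_frame.setdefault(node[0], []).append((node, data))
    res_by_frame: dict[int, list] = {}
    for node, data in result.graph.nodes(data=True):
        res_by_frame.setdefault(node[0], []).append((node, data))
    for frame, refs in ref_by_frame.items():
        ress = res_by_frame.get(frame, [])
        for rnode, rdata in refs:
            rmask = rdata.get("mask")
            if rmask is None:
                if result.graph.has_node(rnode):
                    mapping[rnode] = rnode
                continue
            rset = set(map(tuple, np.asarray(rmask).tolist()))
            for snode, sdata in ress:
                smask = sdata.get("mask")
                if smask is None:
                    continue
                sset = set(map(tuple, np.asarray(smask).tolist()))
                if len(rset & sset) * 2 > len(rset):
                    mapping[rnode] = snode
                    break
    return mapping


def aogm(
    reference: TrackGraph,
    result: TrackGraph,
    weights: AOGMWeights | None = None,
    matching: dict | None = None,
) -> float:
    """Weighted count of graph edit operations converting ``result`` into
    ``reference``: node splits, node additions/deletions, and edge
    additions/deletions/semantics changes.  Zero when the graphs agree."""
    w = weights or AOGMWeights()
    mapping = matching if matching is not None else _match_nodes(reference, result)

    cost = 0.0
    # node operations
    assigned: dict = {}
    for rnode in reference.graph.nodes:
        snode = mapping.get(rnode)
        if snode is None:
            cost += w.w_FN
        else:
            assigned.setdefault(snode, []).append(rnode)
    for snode in result.graph.nodes:
        refs = assigned.get(snode, [])
        if not refs:
            cost += w.w_FP
        elif len(refs) > 1:
            cost += w.w_NS * (len(refs) - 1)

    # edge operations are evaluated on one-to-one matched detections only:
    # edges incident to added/deleted/split nodes come for free with the
    # node operation
    one_to_one = {refs[0]: snode for snode, refs in assigned.items() if len(refs) == 1}
    inv = {v: k for k, v in one_to_one.items()}
    for a, b in reference.graph.edges:
        img_a, img_b = one_to_one.get(a), one_to_one.get(b)
        if img_a is None or img_b is None or not result.graph.has_edge(img_a, img_b):
            cost += w.w_EA
        else:
            ref_div = reference.graph.nodes[a].get("division", False)
            res_div = result.graph.nodes[img_a].get("division", False)
            if ref_div != res_div:
                cost += w.w_EC
    for u, v in result.graph.edges:
        pre_u, pre_v = inv.get(u), inv.get(v)
        if pre_u is not None and pre_v is not None and not reference.graph.has_edge(pre_u, pre_v):
            cost += w.w_ED
    return cost


def aogm_empty(reference: TrackGraph, weights: AOGMWeights | None = None) -> float:
    """Cost of building the reference graph from scratch: every node added
    at w_FN plus every link added at w_EA."""
    w = weights or AOGMWeights()
    return w.w_FN * reference.graph.number_of_nodes() + w.w_EA * reference.graph.number_of_edges()


def tra(
    reference: TrackGraph,
    result: TrackGraph,
    weights: AOGMWeights | None = None,
    matching: dict | None = None,
) -> float:
    """Tracking accuracy: TRA = 1 - min(AOGM, AOGM_0) / AOGM_0, in [0, 1]
    (1 means perfect tracking)."""
    if reference.graph.number_of_nodes() == 0:
        raise ValueError("reference track graph is empty")
    a0 = aogm_empty(reference, weights)
    a = aogm(reference, result, weights, matching)
    return 1.0 - min(a, a0) / a0
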