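"""Phase-1 conservative 1:1 linking between consecutive frames.

A link i(t) -> j(t+1) is emitted only when all three conditions hold:

* safe:       dist(i, NN(i, t+1)) < safe_link_factor * dist(i, NN(i, t))
* mutual:     NN(i, t+1) = j  and  NN(j, t) = i
* non-conflicting: no other detection at t+1 claims i as its backward NN,
  and no other detection at t claims j as its forward NN.

Nearest-neighbor queries are exhaustive vectorized scans with a
deterministic lowest-id tie break; at the per-frame cell counts this
package targets (hundreds) this is both exact and fast, and trivially
satisfies the "equal to exhaustive scan" contract.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from lineagetrace.model import Detection, Lineage, TrackingConfig


class FrameIndex:
    """Nearest-neighbor queries over the detections of one frame."""

    def __init__(self, detections: Sequence[Detection]) -> None:
        self.detections = sorted(detections, key=lambda d: d.id)
        self.ids = np.array([d.id for d in self.detections], dtype=int)
        if self.detections:
            self.points = np.array([[d.x, d.y, d.z] for d in self.detections])
        else:
            self.points = np.empty((0, 3))

    def __len__(self) -> int:
        return len(self.detections)

    def nearest(self, point: np.ndarray, exclude_id: Optional[int] = None) -> Optional[Detection]:
        """Argmin Euclidean distance; ties broken by lowest id; None if empty."""
        if len(self.detections) == 0:
            return None
        mask = np.ones(len(self.ids), dtype=bool)
        if exclude_id is not None:
            mask &= self.ids != exclude_id
        if not mask.any():
            return None
        d2 = np.sum((self.points - np.asarray(point, dtype=float)) ** 2, axis=1)
        d2[~mask] = np.inf
        best = d2.min()
        # ids are pre-sorted ascending, so the first hit is the lowest id
        idx = int(np.flatnonzero(d2 == best)[0])
        return self.detections[idx]

    def nearest_distance(self, point: np.ndarray, exclude_id: Optional[int] = None) -> float:
        nn = self.nearest(point, exclude_id)
        if nn is None:
            return float("inf")
        return float(np.linalg.norm(np.asarray(point, dtype=float) - nn.position))

    def median_nn_distance(self) -> float:
        """Median over detections of the distance to their same-frame NN."""
        if len(self.detections) < 2:
            return float("inf")
        dists = [self.nearest_distance(d.position, exclude_id=d.id) for d in self.detections]
        return float(np.median(dists))


def nearest_neighbor(detections_at_frame: Sequence[Detection],
                     query_point: np.ndarray,
                     exclude_id: Optional[int] = None) -> Optional[Detection]:
    """Closest detection to ``query_point``, excluding ``exclude_id``."""
    return FrameIndex(detections_at_frame).nearest(query_point, exclude_id)


def is_safe_link(c: Detection, frame_t: Sequence[Detection], frame_t1: Sequence[Detection],
                 config: TrackingConfig) -> bool:
    """Displacement-bound condition for detection ``c`` in frame t.

    Vacuously true when ``c`` has no same-frame neighbor (a lone cell has
    no crowding, so its NN match is reliable).  Strict inequality.
    """
    idx_t = frame_t if isinstance(frame_t, FrameIndex) else FrameIndex(frame_t)
    idx_t1 = frame_t1 if isinstance(frame_t1, FrameIndex) else FrameIndex(frame_t1)
    fwd = idx_t1.nearest_distance(c.position)
    if not np.isfinite(fwd):
        return False
    same = idx_t.nearest_distance(c.position, exclude_id=c.id)
    if not np.isfinite(same):
        return True
    return fwd < config.safe_link_factor * same


def link_frames(frame_t: Sequence[Detection], frame_t1: Sequence[Detection],
                config: TrackingConfig) -> Set[Tuple[int, int]]:
    """Emit all safe, mutual, non-conflicting 1:1 links between two frames."""
    idx_t = FrameIndex(frame_t)
    idx_t1 = FrameIndex(frame_t1)
    if len(idx_t) == 0 or len(idx_t1) == 0:
        return set()

    fwd_nn: Dict[int, int] = {}   # id at t -> NN id at t+1
    for d in idx_t.detections:
        nn = idx_t1.nearest(d.position)
        fwd_nn[d.id] = nn.id
    bwd_nn: Dict[int, int] = {}   # id at t+1 -> NN id at t
    for d in idx_t1.detections:
        nn = idx_t.nearest(d.position)
        bwd_nn[d.id] = nn.id

    # forward/backward claim counts for the conflict test
    fwd_claims: Dict[int, int] = {}
    for j in fwd_nn.values():
        fwd_claims[j] = fwd_claims.get(j, 0) + 1
    bwd_claims: Dict[int, int] = {}
    for i in bwd_nn.values():
        bwd_claims[i] = bwd_claims.get(i, 0) + 1

    links: Set[Tuple[int, int]] = set()
    for d in idx_t.detections:
        j = fwd_nn[d.id]
        if bwd_nn[j] != d.id:
            continue                       # not mutual
        if bwd_claims.get(d.id, 0) != 1 or fwd_claims.get(j, 0) != 1:
            continue                       # conflicting claims
        if not is_safe_link(d, idx_t, idx_t1, config):
            continue
        links.add((d.id, j))
    return links


def link_all(detections: Iterable[Detection], config: TrackingConfig) -> Lineage:
    """Apply :func:`link_frames` over every consecutive frame pair."""
    lineage = Lineage(detections)
    frames = lineage.frames()
    for t0, t1 in zip(frames, frames[1:]):
        if t1 != t0 + 1:
            continue
        for pred_id, succ_id in sorted(link_frames(lineage.detections_at(t0),
                                                   lineage.detections_at(t1), config)):
            lineage.add_link(pred_id, succ_id)
    return lineage
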