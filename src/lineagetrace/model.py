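"""Core domain types: detections, the lineage link structure, and tracks.

Coordinates are stored in microns; voxel anisotropy is resolved once at
read time (see :mod:`lineagetrace.io_formats`), so every distance in the
package is plain isotropic Euclidean.  Frame indices are 1-based and
intervals are closed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np

#: Allowed per-detection status flags.
STATUS_TRACKED = "tracked"
STATUS_UNEXPLAINED = "unexplained_appearance"
STATUS_DELETED = "deleted"
STATUS_INTERPOLATED = "interpolated"

STATUSES = (STATUS_TRACKED, STATUS_UNEXPLAINED, STATUS_DELETED, STATUS_INTERPOLATED)


class LineageError(ValueError):
    """Structural violation of the lineage invariants (a caller bug)."""


@dataclass(frozen=True)
class Detection:
    """One identified nuclear object at one time point.

    Positions and radius are in microns; ``intensity`` is in arbitrary
    units.  ``eccentricity`` is optional (``None`` when the detector does
    not report shape); ``elongation_axis`` is an optional unit 3-vector.
    """

    id: int
    t: int
    x: float
    y: float
    z: float
    radius: float
    intensity: float = 0.0
    eccentricity: Optional[float] = None
    elongation_axis: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"detection {self.id}: radius must be > 0, got {self.radius}")
        if self.t < 1:
            raise ValueError(f"detection {self.id}: frame index must be >= 1, got {self.t}")
        if self.intensity < 0:
            raise ValueError(f"detection {self.id}: intensity must be >= 0")
        if self.eccentricity is not None and not (0.0 <= self.eccentricity <= 1.0):
            raise ValueError(f"detection {self.id}: eccentricity must lie in [0, 1]")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def distance_to(self, other: "Detection") -> float:
        return float(np.linalg.norm(self.position - other.position))


@dataclass
class TrackingConfig:
    """Tunable parameters of the tracing pipeline.

    ``safe_link_factor`` is the fraction of the same-frame NN distance a
    displacement must stay under for a link to be considered safe.
    ``bifurcation_distance_cutoff`` is in multiples of the candidate
    parent's radius; ``termination_window_dx`` in multiples of the median
    same-frame NN distance.
    """

    safe_link_factor: float = 0.5
    bifurcation_distance_cutoff: float = 3.0
    termination_window_dt: int = 3
    termination_window_dx: float = 2.0
    fp_max_track_length: int = 3
    max_other_iterations: int = 5
    xy_resolution: float = 1.0
    z_resolution: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.safe_link_factor <= 1.0):
            raise ValueError("safe_link_factor must lie in (0, 1]")
        for name in ("bifurcation_distance_cutoff", "termination_window_dt",
                     "termination_window_dx", "fp_max_track_length",
                     "max_other_iterations", "xy_resolution", "z_resolution"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return {
            "safe_link_factor": self.safe_link_factor,
            "bifurcation_distance_cutoff": self.bifurcation_distance_cutoff,
            "termination_window_dt": self.termination_window_dt,
            "termination_window_dx": self.termination_window_dx,
            "fp_max_track_length": self.fp_max_track_length,
            "max_other_iterations": self.max_other_iterations,
            "xy_resolution": self.xy_resolution,
            "z_resolution": self.z_resolution,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrackingConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass(frozen=True)
class Track:
    """A maximal chain of 1:1 links."""

    detection_ids: Tuple[int, ...]
    start_t: int
    end_t: int

    @property
    def length(self) -> int:
        return self.end_t - self.start_t + 1

    @property
    def first_id(self) -> int:
        return self.detection_ids[0]

    @property
    def last_id(self) -> int:
        return self.detection_ids[-1]


class Lineage:
    """Directed link structure over detections.

    Each non-deleted detection has at most one predecessor and at most two
    successors; every link spans exactly one frame, so the graph is acyclic
    by construction.  Deleted detections are flagged (never removed) and
    participate in no links.
    """

    def __init__(self, detections: Iterable[Detection] = ()) -> None:
        self.detections: Dict[int, Detection] = {}
        self._pred: Dict[int, int] = {}
        self._succ: Dict[int, List[int]] = {}
        self.status: Dict[int, str] = {}
        self._by_frame: Dict[int, List[int]] = {}
        for d in detections:
            self.add_detection(d)

    # -- structural edits ------------------------------------------------

    def add_detection(self, det: Detection, status: str = STATUS_TRACKED) -> None:
        if det.id in self.detections:
            raise LineageError(f"duplicate detection id {det.id}")
        if status not in STATUSES:
            raise LineageError(f"unknown status {status!r}")
        self.detections[det.id] = det
        self.status[det.id] = status
        self._by_frame.setdefault(det.t, []).append(det.id)

    def add_link(self, pred_id: int, succ_id: int) -> None:
        """Record a link pred(t) -> succ(t+1), enforcing all invariants."""
        pred = self.detections.get(pred_id)
        succ = self.detections.get(succ_id)
        if pred is None or succ is None:
            raise LineageError(f"unknown detection in link {pred_id}->{succ_id}")
        if succ.t != pred.t + 1:
            raise LineageError(
                f"link {pred_id}->{succ_id} spans {succ.t - pred.t} frames, must span exactly 1")
        if self.status[pred_id] == STATUS_DELETED or self.status[succ_id] == STATUS_DELETED:
            raise LineageError(f"link {pred_id}->{succ_id} touches a deleted detection")
        if succ_id in self._pred:
            raise LineageError(f"detection {succ_id} already has a predecessor")
        if len(self._succ.get(pred_id, ())) >= 2:
            raise LineageError(f"detection {pred_id} already has two successors")
        self._pred[succ_id] = pred_id
        self._succ.setdefault(pred_id, []).append(succ_id)

    def remove_link(self, pred_id: int, succ_id: int) -> None:
        if self._pred.get(succ_id) != pred_id:
            raise LineageError(f"no link {pred_id}->{succ_id} to remove")
        del self._pred[succ_id]
        self._succ[pred_id].remove(succ_id)
        if not self._succ[pred_id]:
            del self._succ[pred_id]

    def delete_detection(self, det_id: int) -> None:
        """Flag a detection deleted and drop all its links."""
        if det_id not in self.detections:
            raise LineageError(f"unknown detection {det_id}")
        p = self._pred.get(det_id)
        if p is not None:
            self.remove_link(p, det_id)
        for s in list(self._succ.get(det_id, ())):
            self.remove_link(det_id, s)
        self.status[det_id] = STATUS_DELETED

    def set_status(self, det_id: int, status: str) -> None:
        if status not in STATUSES:
            raise LineageError(f"unknown status {status!r}")
        if status == STATUS_DELETED:
            self.delete_detection(det_id)
        else:
            self.status[det_id] = status

    # -- queries ---------------------------------------------------------

    def predecessor(self, det_id: int) -> Optional[int]:
        return self._pred.get(det_id)

    def successors(self, det_id: int) -> Tuple[int, ...]:
        return tuple(self._succ.get(det_id, ()))

    def links(self) -> Set[Tuple[int, int]]:
        return {(p, s) for s, p in self._pred.items()}

    def frames(self) -> List[int]:
        return sorted(t for t, ids in self._by_frame.items() if ids)

    def detections_at(self, t: int, include_deleted: bool = False) -> List[Detection]:
        ids = self._by_frame.get(t, ())
        return [self.detections[i] for i in sorted(ids)
                if include_deleted or self.status[i] != STATUS_DELETED]

    def is_deleted(self, det_id: int) -> bool:
        return self.status[det_id] == STATUS_DELETED

    def n_active(self) -> int:
        return sum(1 for s in self.status.values() if s != STATUS_DELETED)

    def copy(self) -> "Lineage":
        out = Lineage()
        out.detections = dict(self.detections)
        out._pred = dict(self._pred)
        out._succ = {k: list(v) for k, v in self._succ.items()}
        out.status = dict(self.status)
        out._by_frame = {k: list(v) for k, v in self._by_frame.items()}
        return out

    def validate(self) -> None:
        """Re-check every invariant; raises LineageError on violation."""
        for s, p in self._pred.items():
            ds, dp = self.detections[s], self.detections[p]
            if ds.t != dp.t + 1:
                raise LineageError(f"link {p}->{s} spans more than one frame")
            if self.status[s] == STATUS_DELETED or self.status[p] == STATUS_DELETED:
                raise LineageError(f"link {p}->{s} touches a deleted detection")
        for p, ss in self._succ.items():
            if len(ss) > 2:
                raise LineageError(f"detection {p} has {len(ss)} successors")
            if len(set(ss)) != len(ss):
                raise LineageError(f"detection {p} has duplicate successors")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Lineage):
            return NotImplemented
        return (self.detections == other.detections
                and self._pred == other._pred
                and self.status == other.status)


def add_link(lineage: Lineage, pred_id: int, succ_id: int) -> Lineage:
    """Functional wrapper around :meth:`Lineage.add_link` (mutates in place)."""
    lineage.add_link(pred_id, succ_id)
    return lineage


def tracks_of(lineage: Lineage) -> List[Track]:
    """Partition the non-deleted detections into maximal 1:1 chains.

    Track boundaries fall exactly at divisions (two successors), at
    appearances (no predecessor) and at terminations (no successor).
    """
    tracks: List[Track] = []
    for det_id in sorted(lineage.detections):
        if lineage.is_deleted(det_id):
            continue
        pred = lineage.predecessor(det_id)
        # A track starts where there is no 1:1 incoming link.
        starts = pred is None or len(lineage.successors(pred)) != 1
        if not starts:
            continue
        chain = [det_id]
        cur = det_id
        while True:
            succ = lineage.successors(cur)
            if len(succ) != 1:
                break
            cur = succ[0]
            chain.append(cur)
        tracks.append(Track(
            detection_ids=tuple(chain),
            start_t=lineage.detections[chain[0]].t,
            end_t=lineage.detections[chain[-1]].t,
        ))
    return tracks
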