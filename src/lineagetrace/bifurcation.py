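"""Phase-2: tentative bifurcations and their semi-local neighborhoods.

Every detection left without a backward link after phase 1 (an "orphan")
marks a local increase in cell count.  Each orphan is forced into a
tentative 1-to-2 match with a nearby parent; the bifurcation is paired
with a preceding terminating track within a spatiotemporal window, and
the 1:1 endpoint matching that minimizes the total displacement of the
involved nuclei is recorded as the neighborhood's match hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from lineagetrace.linking import FrameIndex
from lineagetrace.model import Detection, Lineage, TrackingConfig, tracks_of


@dataclass
class Bifurcation:
    """A forced 1-to-2 match: parent at frame t, children at frame t+1.

    ``child_a_id`` is the parent's pre-existing phase-1 successor when one
    exists; ``child_b_id`` is the orphan being explained.  When the parent
    had no successor the bifurcation degenerates to a tentative 1:1
    attachment and ``child_a_id`` is None.
    """

    parent_id: int
    child_a_id: Optional[int]
    child_b_id: int
    division_score: float = 0.0
    creation_round: int = 0

    @property
    def child_ids(self) -> Tuple[int, ...]:
        if self.child_a_id is None:
            return (self.child_b_id,)
        return (self.child_a_id, self.child_b_id)

    @property
    def is_degenerate(self) -> bool:
        return self.child_a_id is None


@dataclass
class TerminationCandidate:
    """A dangling track end near a bifurcation."""

    end_id: int
    gap_frames: int          # parent frame minus termination frame
    distance: float          # from the bifurcation centroid


@dataclass
class Neighborhood:
    """A bifurcation plus its paired terminating track and 1:1 hypotheses.

    ``hypothesis_matches`` is the list of (from_id, to_id) endpoint matches
    of the minimum-total-displacement pairing; ``alternatives`` keeps every
    enumerated (cost, matches, termination_end_id) option so the choice can
    be audited.
    """

    bifurcation: Bifurcation
    termination_end_id: Optional[int] = None
    gap_frames: int = 0
    hypothesis_matches: List[Tuple[int, int]] = field(default_factory=list)
    hypothesis_cost: float = float("inf")
    alternatives: List[Tuple[float, Tuple[Tuple[int, int], ...], Optional[int]]] = \
        field(default_factory=list)
    median_nn_distance: float = float("nan")

    @property
    def parent_id(self) -> int:
        return self.bifurcation.parent_id


def find_orphans(lineage: Lineage) -> List[Detection]:
    """All non-deleted detections after the first frame with no predecessor."""
    frames = lineage.frames()
    if not frames:
        return []
    first = frames[0]
    out = []
    for det_id in sorted(lineage.detections):
        if lineage.is_deleted(det_id):
            continue
        det = lineage.detections[det_id]
        if det.t > first and lineage.predecessor(det_id) is None:
            out.append(det)
    return out


def bifurcation_centroid(bif: Bifurcation, lineage: Lineage) -> np.ndarray:
    pts = [lineage.detections[bif.parent_id].position]
    pts += [lineage.detections[c].position for c in bif.child_ids]
    return np.mean(pts, axis=0)


def find_terminations_near(lineage: Lineage, point: np.ndarray, t: int,
                           config: TrackingConfig,
                           exclude=()) -> List[TerminationCandidate]:
    """Dangling track ends within the spatiotemporal window around a point.

    Window: frames [t - termination_window_dt, t] and distance from
    ``point`` of at most termination_window_dx times the median same-frame
    NN distance at t.  Ordered by distance, ties by id.
    """
    idx_t = FrameIndex(lineage.detections_at(t))
    med = idx_t.median_nn_distance()
    max_dist = (config.termination_window_dx * med) if np.isfinite(med) else float("inf")
    exclude = set(exclude)

    cands: List[TerminationCandidate] = []
    for te in range(t - config.termination_window_dt, t + 1):
        for det in lineage.detections_at(te):
            if det.id in exclude:
                continue
            if lineage.successors(det.id):
                continue
            dist = float(np.linalg.norm(det.position - np.asarray(point)))
            if dist <= max_dist:
                cands.append(TerminationCandidate(end_id=det.id, gap_frames=t - te,
                                                  distance=dist))
    cands.sort(key=lambda c: (c.distance, c.end_id))
    return cands


def find_terminations(lineage: Lineage, bif: Bifurcation,
                      config: TrackingConfig) -> List[TerminationCandidate]:
    """Dangling track ends behind a bifurcation (window anchored at the
    parent frame, distances from the bifurcation centroid)."""
    parent = lineage.detections[bif.parent_id]
    return find_terminations_near(
        lineage, bifurcation_centroid(bif, lineage), parent.t, config,
        exclude={bif.parent_id, *bif.child_ids})


def build_neighborhood(bif: Bifurcation, terminations: Sequence[TerminationCandidate],
                       lineage: Lineage,
                       config: Optional[TrackingConfig] = None) -> Neighborhood:
    """Choose the minimum-total-displacement 1:1 endpoint pairing.

    Enumerated options: (a) no termination — both children charged to the
    parent (hypothesis records the parent matched to its nearer child);
    (b) for each candidate termination, each assignment of the two children
    to {parent continuation, termination continuation}.  Detections and
    links inside a proposed gap are ignored: only the endpoints enter the
    cost.  Degenerate (single-child) bifurcations take option (a) only.
    """
    parent = lineage.detections[bif.parent_id]
    children = [lineage.detections[c] for c in bif.child_ids]

    idx_t = FrameIndex(lineage.detections_at(parent.t))
    med = idx_t.median_nn_distance()

    options: List[Tuple[float, Tuple[Tuple[int, int], ...], Optional[int], int]] = []

    if bif.is_degenerate:
        # one child to explain: the parent competes with each dangling end
        ca = children[0]
        options.append((parent.distance_to(ca), ((parent.id, ca.id),), None, 0))
        for term in terminations:
            end = lineage.detections[term.end_id]
            options.append((end.distance_to(ca), ((end.id, ca.id),),
                            term.end_id, term.gap_frames))
    else:
        ca, cb = children
        da, db = parent.distance_to(ca), parent.distance_to(cb)
        near = ca if (da, ca.id) <= (db, cb.id) else cb
        options.append((da + db, ((parent.id, near.id),), None, 0))
        for term in terminations:
            end = lineage.detections[term.end_id]
            for kept, moved in ((ca, cb), (cb, ca)):
                cost = parent.distance_to(kept) + end.distance_to(moved)
                matches = ((parent.id, kept.id), (end.id, moved.id))
                options.append((cost, matches, term.end_id, term.gap_frames))

    options.sort(key=lambda o: (o[0], -1 if o[2] is None else o[2], o[1]))
    cost, matches, term_id, gap = options[0]
    return Neighborhood(
        bifurcation=bif,
        termination_end_id=term_id,
        gap_frames=gap,
        hypothesis_matches=list(matches),
        hypothesis_cost=cost,
        alternatives=[(c, m, e) for c, m, e, _ in options],
        median_nn_distance=med,
    )


def candidate_parents(orphan: Detection, lineage: Lineage, config: TrackingConfig,
                      model=None, creation_round: int = 0) -> List[Bifurcation]:
    """Ranked tentative bifurcations explaining one orphan.

    Candidates are non-deleted detections at the previous frame within
    ``bifurcation_distance_cutoff`` times the larger of the candidate's
    radius and half the median same-frame NN distance (the radius alone
    under-reaches once nuclei shrink below the packing scale); a parent
    that already has two successors cannot host another child.  With a
    fitted model the ranking is by the division log-score of the candidate
    neighborhood (descending); without one, by distance (ascending).
    Ties break on ascending parent id.
    """
    prev = lineage.detections_at(orphan.t - 1)
    med = FrameIndex(prev).median_nn_distance()
    half_spacing = 0.5 * med if np.isfinite(med) else float("inf")
    bifs: List[Bifurcation] = []
    for det in prev:
        if det.id == orphan.id:
            continue
        succ = lineage.successors(det.id)
        if len(succ) >= 2:
            continue
        dist = det.distance_to(orphan)
        if dist > config.bifurcation_distance_cutoff * max(det.radius, half_spacing):
            continue
        child_a = succ[0] if succ else None
        bif = Bifurcation(parent_id=det.id, child_a_id=child_a, child_b_id=orphan.id,
                          creation_round=creation_round)
        if model is not None:
            from lineagetrace.classify import division_log_score, extract_features
            nb = build_neighborhood(bif, find_terminations(lineage, bif, config),
                                    lineage, config)
            fv = extract_features(nb, lineage, config)
            bif.division_score = division_log_score(model, fv)
        else:
            bif.division_score = -dist
        bifs.append(bif)
    bifs.sort(key=lambda b: (-b.division_score, b.parent_id))
    return bifs
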