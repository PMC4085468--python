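"""Phase-3/4: class-specific tracking actions and pipeline orchestration.

Each classified neighborhood triggers one action:

1. division  — the bifurcation is accepted (parent keeps both children).
2. two_cell  — the bifurcation is dissolved into the 1:1 chains of the
   minimum-displacement hypothesis; a detection gap is filled by linear
   interpolation.
3. fp        — the shorter of the two branches is deleted.
4. other     — the worse-matching child is detached and tried against its
   next candidate parent; when candidates are exhausted it is left as an
   unexplained appearance.

Orphans are resolved strictly chronologically (ascending frame, then id).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from lineagetrace.bifurcation import (Bifurcation, Neighborhood, build_neighborhood,
                                      candidate_parents, find_orphans,
                                      find_terminations)
from lineagetrace.classify import (NBModel, Posterior, classify,
                                   extract_features, posterior)
from lineagetrace.linking import link_all
from lineagetrace.model import (STATUS_INTERPOLATED, STATUS_TRACKED,
                                STATUS_UNEXPLAINED, Detection, Lineage,
                                LineageError, TrackingConfig)


@dataclass
class BifurcationRecord:
    """One classified bifurcation and its resolution, for the run report."""

    frame: int
    parent_id: int
    child_ids: Tuple[int, ...]
    termination_end_id: Optional[int]
    features: Tuple[float, ...]
    posterior: Dict[str, float]
    predicted_class: str
    action: str
    rewired_links: List[Tuple[str, int, int]] = field(default_factory=list)
    inserted_ids: List[int] = field(default_factory=list)
    deleted_ids: List[int] = field(default_factory=list)


@dataclass
class TraceReport:
    records: List[BifurcationRecord] = field(default_factory=list)
    unexplained_ids: List[int] = field(default_factory=list)

    def counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for r in self.records:
            out[r.action] = out.get(r.action, 0) + 1
        return out

    def to_dict(self) -> dict:
        return {
            "records": [
                {
                    "frame": r.frame,
                    "parent_id": r.parent_id,
                    "child_ids": list(r.child_ids),
                    "termination_end_id": r.termination_end_id,
                    "features": list(r.features),
                    "posterior": r.posterior,
                    "predicted_class": r.predicted_class,
                    "action": r.action,
                    "rewired_links": [list(x) for x in r.rewired_links],
                    "inserted_ids": r.inserted_ids,
                    "deleted_ids": r.deleted_ids,
                }
                for r in self.records
            ],
            "unexplained_ids": self.unexplained_ids,
            "action_counts": self.counts(),
        }


def apply_division(neighborhood: Neighborhood, lineage: Lineage) -> Lineage:
    """Accept the bifurcation: parent linked to both children."""
    bif = neighborhood.bifurcation
    existing = lineage.successors(bif.parent_id)
    for child in bif.child_ids:
        if child not in existing:
            lineage.add_link(bif.parent_id, child)
    return lineage


def _interpolated_detection(a: Detection, b: Detection, t: int, new_id: int) -> Detection:
    """Detection at frame t on the straight line between a and b."""
    w = (t - a.t) / (b.t - a.t)
    p = (1 - w) * a.position + w * b.position
    return Detection(
        id=new_id, t=t, x=float(p[0]), y=float(p[1]), z=float(p[2]),
        radius=float((1 - w) * a.radius + w * b.radius),
        intensity=float((1 - w) * a.intensity + w * b.intensity),
    )


def _next_id(lineage: Lineage) -> int:
    return max(lineage.detections, default=0) + 1


def _connect_with_gap(lineage: Lineage, end_id: int, child_id: int,
                      record: Optional[BifurcationRecord] = None) -> None:
    """Link a dangling end to a detection gap_frames+1 later, filling the
    gap with interpolated detections."""
    a = lineage.detections[end_id]
    b = lineage.detections[child_id]
    prev = end_id
    for t in range(a.t + 1, b.t):
        det = _interpolated_detection(a, b, t, _next_id(lineage))
        lineage.add_detection(det, status=STATUS_INTERPOLATED)
        lineage.add_link(prev, det.id)
        if record is not None:
            record.inserted_ids.append(det.id)
            record.rewired_links.append(("add", prev, det.id))
        prev = det.id
    lineage.add_link(prev, child_id)
    if record is not None:
        record.rewired_links.append(("add", prev, child_id))


def apply_two_cell(neighborhood: Neighborhood, lineage: Lineage,
                   record: Optional[BifurcationRecord] = None) -> Optional[int]:
    """Dissolve the bifurcation into the hypothesis' 1:1 chains.

    Returns the id of a child re-orphaned by the rewiring (to be re-queued
    by the caller), or None.  Without a termination the better child keeps
    the parent and the other child is returned as a new orphan.
    """
    bif = neighborhood.bifurcation
    parent_id = bif.parent_id
    matches = dict(neighborhood.hypothesis_matches)  # from_id -> to_id

    new_orphan: Optional[int] = None

    # detach any existing parent link that contradicts the hypothesis
    wanted_child = matches.get(parent_id)
    for s in list(lineage.successors(parent_id)):
        if s != wanted_child:
            lineage.remove_link(parent_id, s)
            if record is not None:
                record.rewired_links.append(("remove", parent_id, s))
            new_orphan = s
    if wanted_child is not None and wanted_child not in lineage.successors(parent_id):
        lineage.add_link(parent_id, wanted_child)
        if record is not None:
            record.rewired_links.append(("add", parent_id, wanted_child))
        if new_orphan == wanted_child:
            new_orphan = None

    if neighborhood.termination_end_id is not None:
        end_id = neighborhood.termination_end_id
        moved_child = matches.get(end_id)
        if moved_child is not None and lineage.predecessor(moved_child) is None:
            _connect_with_gap(lineage, end_id, moved_child, record)
            if new_orphan == moved_child:
                new_orphan = None
    return new_orphan


def _branch_detections(lineage: Lineage, start_id: int) -> List[int]:
    """The forward 1:1 chain from start_id (stops at division or end)."""
    out = [start_id]
    cur = start_id
    while True:
        succ = lineage.successors(cur)
        if len(succ) != 1:
            break
        cur = succ[0]
        out.append(cur)
    return out


def apply_fp(neighborhood: Neighborhood, lineage: Lineage,
             record: Optional[BifurcationRecord] = None) -> List[int]:
    """Delete the spurious branch through the bifurcation children.

    The shorter branch (in frames) is deemed the FP; equal lengths break
    toward the branch with the lower summed intensity (dimmer objects are
    likelier optical artifacts), then the lower child id.

    One guarded exception: when the branch slated for deletion matches the
    parent's appearance and motion better than the survivor does, the
    survivor's head detection has hijacked the real cell's forward track
    at phase 1.  In that case only the head is excised; its successors are
    returned so the caller can re-queue them as orphans.
    """
    bif = neighborhood.bifurcation
    parent = lineage.detections[bif.parent_id]
    branches = []
    for child in bif.child_ids:
        dets = _branch_detections(lineage, child)
        total_int = sum(lineage.detections[d].intensity for d in dets)
        branches.append((len(dets), total_int, child, dets))
    branches.sort(key=lambda b: (b[0], b[1], b[2]))
    loser = branches[0]
    survivor = branches[-1] if len(branches) > 1 else None

    requeue: List[int] = []
    if survivor is not None and loser[2] != survivor[2] and survivor[0] > loser[0]:
        loser_score = continuation_score(parent, lineage.detections[loser[2]])
        surv_score = continuation_score(parent, lineage.detections[survivor[2]])
        if loser_score > surv_score:
            head = survivor[2]
            for s in list(lineage.successors(head)):
                lineage.remove_link(head, s)
                requeue.append(s)
                if record is not None:
                    record.rewired_links.append(("remove", head, s))
            lineage.delete_detection(head)
            if record is not None:
                record.deleted_ids.append(head)
            if (lineage.predecessor(loser[2]) is None
                    and len(lineage.successors(bif.parent_id)) < 2):
                lineage.add_link(bif.parent_id, loser[2])
                if record is not None:
                    record.rewired_links.append(("add", bif.parent_id, loser[2]))
            return requeue

    for det_id in loser[3]:
        lineage.delete_detection(det_id)
        if record is not None:
            record.deleted_ids.append(det_id)

    if survivor is not None:
        surv_child = survivor[2]
        if (lineage.predecessor(surv_child) is None
                and not lineage.is_deleted(surv_child)
                and len(lineage.successors(bif.parent_id)) < 2):
            lineage.add_link(bif.parent_id, surv_child)
            if record is not None:
                record.rewired_links.append(("add", bif.parent_id, surv_child))
    return requeue


def continuation_score(parent: Detection, child: Detection) -> float:
    """1:1 continuation plausibility of child following parent (higher is
    better): penalizes displacement and size/intensity change."""
    disp = parent.distance_to(child) / parent.radius
    size = math.log(child.radius / parent.radius)
    if parent.intensity > 0 and child.intensity > 0:
        inten = math.log(child.intensity / parent.intensity)
    else:
        inten = 0.0
    return -(disp * disp + size * size + inten * inten)


def apply_other(neighborhood: Neighborhood, lineage: Lineage,
                record: Optional[BifurcationRecord] = None) -> Optional[int]:
    """Detach the worse-matching child from this bifurcation.

    Returns the detached child id (the caller re-tries it against its next
    candidate parent).  The better child keeps / gains the parent link.
    """
    bif = neighborhood.bifurcation
    parent = lineage.detections[bif.parent_id]
    if bif.is_degenerate:
        return bif.child_b_id
    scored = sorted(
        ((continuation_score(parent, lineage.detections[c]), c) for c in bif.child_ids),
        key=lambda s: (s[0], -s[1]))
    worse = scored[0][1]
    better = scored[-1][1]
    if worse == bif.child_a_id:
        # existing successor is the worse match: swap it out for the orphan
        lineage.remove_link(bif.parent_id, worse)
        lineage.add_link(bif.parent_id, better)
        if record is not None:
            record.rewired_links.append(("remove", bif.parent_id, worse))
            record.rewired_links.append(("add", bif.parent_id, better))
    return worse


def trace_lineage(detections: Sequence[Detection], model: Optional[NBModel],
                  config: TrackingConfig,
                  classifier=None) -> Tuple[Lineage, TraceReport]:
    """Run the full pipeline: phase-1 linking, then bifurcation resolution.

    Orphans are processed chronologically.  Each orphan gets at most
    ``config.max_other_iterations`` re-attachment attempts; children
    detached by two_cell / other actions are re-queued as fresh orphans.
    Deterministic: no randomness anywhere in tracing.

    ``classifier`` optionally overrides the model for classification only
    (signature ``(neighborhood, lineage) -> (class, Posterior)``); this is
    how the training collector drives the loop with a ground-truth oracle
    so that training states match inference states.
    """
    lineage = link_all(detections, config)
    report = TraceReport()
    frames = lineage.frames()
    if not frames:
        return lineage, report
    first_frame = frames[0]

    queue: List[Tuple[int, int]] = [(d.t, d.id) for d in find_orphans(lineage)]
    queue.sort()
    guard = 0
    guard_max = max(10 * len(lineage.detections) * config.max_other_iterations, 1000)

    while queue:
        queue.sort()
        t, orphan_id = queue.pop(0)
        guard += 1
        if guard > guard_max:  # pragma: no cover - safety net
            break
        if lineage.is_deleted(orphan_id) or lineage.predecessor(orphan_id) is not None:
            continue
        orphan = lineage.detections[orphan_id]
        if orphan.t <= first_frame:
            continue

        tried: set = set()
        resolved = False
        for _ in range(config.max_other_iterations):
            cands = [b for b in candidate_parents(orphan, lineage, config, model)
                     if b.parent_id not in tried]
            if not cands:
                # no candidate parent at all, or every candidate rejected
                # as "other": a nearby dangling end may still explain the
                # appearance as a plain 1:1 continuation
                resolved = _direct_termination_repair(orphan, lineage, config, report)
                break
            bif = cands[0]
            tried.add(bif.parent_id)
            terms = find_terminations(lineage, bif, config)
            nb = build_neighborhood(bif, terms, lineage, config)
            if classifier is not None:
                feat = ()
                cls, post = classifier(nb, lineage)
            elif model is None:
                feat = ()
                cls, post = _fallback_classify(nb, lineage)
            else:
                fv = extract_features(nb, lineage, config, medians=model.feature_medians)
                post = posterior(model, fv)
                cls = post.argmax()
                feat = fv.values
            rec = BifurcationRecord(
                frame=orphan.t, parent_id=bif.parent_id, child_ids=bif.child_ids,
                termination_end_id=nb.termination_end_id,
                features=feat, posterior={c: post.prob(c) for c in post.classes},
                predicted_class=cls, action=cls)
            if cls == "division":
                apply_division(nb, lineage)
                report.records.append(rec)
                resolved = True
                break
            if cls == "two_cell":
                new_orphan = apply_two_cell(nb, lineage, rec)
                report.records.append(rec)
                if new_orphan is not None and new_orphan != orphan_id:
                    queue.append((lineage.detections[new_orphan].t, new_orphan))
                resolved = lineage.predecessor(orphan_id) is not None
                if resolved:
                    break
                continue
            if cls == "fp":
                requeue = apply_fp(nb, lineage, rec)
                report.records.append(rec)
                for rid in requeue:
                    if not lineage.is_deleted(rid):
                        queue.append((lineage.detections[rid].t, rid))
                resolved = True
                break
            # other
            detached = apply_other(nb, lineage, rec)
            report.records.append(rec)
            if detached is not None and detached != orphan_id:
                queue.append((lineage.detections[detached].t, detached))
                resolved = lineage.predecessor(orphan_id) is not None
                if resolved:
                    break
        if not resolved and not lineage.is_deleted(orphan_id) \
                and lineage.predecessor(orphan_id) is None:
            lineage.set_status(orphan_id, STATUS_UNEXPLAINED)
            report.unexplained_ids.append(orphan_id)

    _sweep_unexplained_fp_tracks(lineage, config, report, first_frame)
    return lineage, report


def _sweep_unexplained_fp_tracks(lineage: Lineage, config: TrackingConfig,
                                 report: TraceReport, first_frame: int) -> None:
    """Delete isolated short dim tracks left as unexplained appearances.

    A spurious detection whose spawn point offered no candidate parent
    (e.g. every nearby nucleus had just divided) never enters a
    bifurcation; it survives as a track that appears from nowhere, ends
    with no successor, lasts at most ``fp_max_track_length`` frames and is
    markedly dimmer than its surroundings.  Real unexplained appearances
    keep normal intensity and are left untouched.
    """
    from lineagetrace.model import tracks_of

    med_by_frame: Dict[int, float] = {}
    for tr in tracks_of(lineage):
        start = tr.first_id
        if lineage.status.get(start) != STATUS_UNEXPLAINED:
            continue
        if lineage.detections[start].t <= first_frame:
            continue
        if lineage.successors(tr.last_id):
            continue
        if tr.length > config.fp_max_track_length:
            continue
        t_mid = lineage.detections[tr.detection_ids[len(tr.detection_ids) // 2]].t
        if t_mid not in med_by_frame:
            vals = [d.intensity for d in lineage.detections_at(t_mid)]
            med_by_frame[t_mid] = float(np.median(vals)) if vals else 0.0
        med = med_by_frame[t_mid]
        mean_int = float(np.mean([lineage.detections[i].intensity
                                  for i in tr.detection_ids]))
        if med > 0 and mean_int >= 0.6 * med:
            continue
        rec = BifurcationRecord(
            frame=lineage.detections[start].t, parent_id=-1,
            child_ids=(start,), termination_end_id=None, features=(),
            posterior={}, predicted_class="fp", action="fp_sweep",
            deleted_ids=list(tr.detection_ids))
        for det_id in tr.detection_ids:
            lineage.delete_detection(det_id)
        report.records.append(rec)
        if start in report.unexplained_ids:
            report.unexplained_ids.remove(start)


def _direct_termination_repair(orphan: Detection, lineage: Lineage,
                               config: TrackingConfig, report: TraceReport) -> bool:
    """Last-resort repair for an orphan with no candidate parent at all
    (empty previous frame, or every nearby nucleus already divided):
    attach it to the nearest dangling end in the spatiotemporal window,
    filling any gap by interpolation.  Returns True if repaired."""
    from lineagetrace.bifurcation import find_terminations_near

    terms = find_terminations_near(lineage, orphan.position, orphan.t - 1, config,
                                   exclude={orphan.id})
    terms = [x for x in terms if lineage.detections[x.end_id].t < orphan.t]
    if not terms:
        return False
    end = terms[0]
    rec = BifurcationRecord(
        frame=orphan.t, parent_id=-1, child_ids=(orphan.id,),
        termination_end_id=end.end_id, features=(),
        posterior={}, predicted_class="two_cell", action="two_cell_direct")
    _connect_with_gap(lineage, end.end_id, orphan.id, rec)
    report.records.append(rec)
    return True


def _fallback_classify(nb: Neighborhood, lineage: Lineage) -> Tuple[str, Posterior]:
    """Model-free heuristic used only when no classifier is supplied."""
    if nb.termination_end_id is not None:
        cls = "two_cell"
    else:
        cls = "division"
    probs = tuple(1.0 if c == cls else 0.0 for c in ("division", "two_cell", "fp", "other"))
    return cls, Posterior(classes=("division", "two_cell", "fp", "other"),
                          probabilities=probs)
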