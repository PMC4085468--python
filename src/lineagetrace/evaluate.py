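"""Lineage-vs-truth scoring.

Detections are matched to the truth by id when the ids are shared (the
simulator keeps true ids for observed detections); interpolated repair
detections are matched to dropped true detections by frame and position
(tolerance half a radius).  An instantaneous error is a cell-frame whose
backward history step is wrong: wrong, missing or spurious predecessor, an
undeleted false positive, or an incorrectly deleted true cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from lineagetrace.linking import FrameIndex
from lineagetrace.model import Detection, Lineage, STATUS_INTERPOLATED


@dataclass
class EvalReport:
    instantaneous_accuracy: float
    n_cell_frames: int
    n_errors: int
    cumulative_accuracy: Dict[int, float]
    division_ppv: float
    division_sensitivity: float
    n_true_divisions: int
    n_pred_divisions: int
    error_counts: Dict[str, int] = field(default_factory=dict)
    density_bins: List[Tuple[float, float, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "instantaneous_accuracy": self.instantaneous_accuracy,
            "n_cell_frames": self.n_cell_frames,
            "n_errors": self.n_errors,
            "cumulative_accuracy": {str(k): v for k, v in self.cumulative_accuracy.items()},
            "division_ppv": self.division_ppv,
            "division_sensitivity": self.division_sensitivity,
            "n_true_divisions": self.n_true_divisions,
            "n_pred_divisions": self.n_pred_divisions,
            "error_counts": self.error_counts,
            "density_bins": [list(b) for b in self.density_bins],
        }


def density(det: Detection, frame_detections: Sequence[Detection]) -> Optional[float]:
    """(radius(c) + radius(NN(c))) / distance(c, NN(c)); None for lone cells.

    A density of one means the two nuclear shells touch exactly; values
    above one indicate overlap.
    """
    nn = FrameIndex(frame_detections).nearest(det.position, exclude_id=det.id)
    if nn is None:
        return None
    d = det.distance_to(nn)
    if d <= 0:
        return float("inf")
    return (det.radius + nn.radius) / d


def match_detections(pred: Lineage, truth: Lineage) -> Dict[int, Optional[int]]:
    """Map non-deleted predicted detection ids to true detection ids.

    Shared ids map to themselves; remaining predicted detections (e.g.
    interpolated insertions) are greedily matched to unclaimed true
    detections in the same frame within half the true radius.  Unmatched
    predictions map to None (treated as FP).
    """
    mapping: Dict[int, Optional[int]] = {}
    claimed = set()
    for det_id in pred.detections:
        if pred.is_deleted(det_id):
            continue
        if det_id in truth.detections \
                and truth.detections[det_id].t == pred.detections[det_id].t:
            mapping[det_id] = det_id
            claimed.add(det_id)

    unmatched = [i for i in sorted(pred.detections)
                 if not pred.is_deleted(i) and i not in mapping]
    for det_id in unmatched:
        det = pred.detections[det_id]
        cands = []
        for tdet in truth.detections_at(det.t):
            if tdet.id in claimed:
                continue
            d = det.distance_to(tdet)
            if d <= 0.5 * tdet.radius:
                cands.append((d, tdet.id))
        if cands:
            cands.sort()
            mapping[det_id] = cands[0][1]
            claimed.add(cands[0][1])
        else:
            mapping[det_id] = None
    return mapping


def _error_flags(pred: Lineage, truth: Lineage,
                 mapping: Optional[Dict[int, Optional[int]]] = None
                 ) -> Tuple[Dict[int, bool], int, Dict[str, int]]:
    """Per-true-detection error indicator plus FP errors and a breakdown."""
    if mapping is None:
        mapping = match_detections(pred, truth)
    rev: Dict[int, int] = {t: p for p, t in mapping.items() if t is not None}

    counts = {"wrong_predecessor": 0, "missing_predecessor": 0,
              "spurious_predecessor": 0, "missing_detection": 0,
              "undeleted_fp": 0}
    flags: Dict[int, bool] = {}
    for true_id in truth.detections:
        if truth.is_deleted(true_id):
            continue
        pred_id = rev.get(true_id)
        if pred_id is None:
            flags[true_id] = True          # deleted or absent true cell
            counts["missing_detection"] += 1
            continue
        true_parent = truth.predecessor(true_id)
        p_parent = pred.predecessor(pred_id)
        p_parent_true = mapping.get(p_parent) if p_parent is not None else None
        if true_parent is None:
            ok = p_parent is None
            if not ok:
                counts["spurious_predecessor"] += 1
        elif p_parent is None:
            ok = False
            counts["missing_predecessor"] += 1
        else:
            ok = p_parent_true == true_parent
            if not ok:
                counts["wrong_predecessor"] += 1
        flags[true_id] = not ok

    n_fp_errors = 0
    for pred_id, true_id in mapping.items():
        if true_id is None:
            n_fp_errors += 1
            counts["undeleted_fp"] += 1
    return flags, n_fp_errors, counts


def instantaneous_accuracy(pred: Lineage, truth: Lineage,
                           mapping: Optional[Dict[int, Optional[int]]] = None) -> float:
    """1 - (total instantaneous errors over all frames) / (cells in all frames)."""
    flags, n_fp, _ = _error_flags(pred, truth, mapping)
    n = len(flags)
    if n == 0:
        return 1.0
    errors = sum(flags.values()) + n_fp
    return 1.0 - errors / n


def cumulative_accuracy(pred: Lineage, truth: Lineage,
                        cell_of: Dict[int, int],
                        generation_of: Dict[int, int],
                        mapping: Optional[Dict[int, Optional[int]]] = None
                        ) -> Dict[int, float]:
    """Fraction of cells per generation whose entire history is error-free.

    A cell is scored at its last true detection; it is correct iff every
    backward step from there to the first frame matches the truth.
    """
    flags, _, _ = _error_flags(pred, truth, mapping)

    clean: Dict[int, bool] = {}
    for true_id in sorted(truth.detections):   # ascending id == ascending frame per cell
        if truth.is_deleted(true_id):
            continue
        parent = truth.predecessor(true_id)
        ok = not flags[true_id]
        if parent is not None:
            ok = ok and clean[parent]
        clean[true_id] = ok

    per_gen: Dict[int, List[bool]] = {}
    for true_id in truth.detections:
        if truth.is_deleted(true_id):
            continue
        if truth.successors(true_id) and len(truth.successors(true_id)) == 1:
            continue                      # interior detection, not a cell endpoint
        gen = generation_of[cell_of[true_id]]
        per_gen.setdefault(gen, []).append(clean[true_id])
    return {g: float(np.mean(v)) for g, v in sorted(per_gen.items())}


def division_scores(pred: Lineage, truth: Lineage,
                    mapping: Optional[Dict[int, Optional[int]]] = None
                    ) -> Tuple[float, float, int, int, int]:
    """(PPV, sensitivity, TP, n_pred, n_true) for predicted divisions.

    A predicted division is true iff the matched parent truly divides at
    that frame into the matched children.
    """
    if mapping is None:
        mapping = match_detections(pred, truth)
    true_divs = {p: set(truth.successors(p)) for p in truth.detections
                 if len(truth.successors(p)) == 2}
    tp = 0
    n_pred = 0
    for p in pred.detections:
        if pred.is_deleted(p):
            continue
        succ = pred.successors(p)
        if len(succ) != 2:
            continue
        n_pred += 1
        p_true = mapping.get(p)
        if p_true is None or p_true not in true_divs:
            continue
        child_true = {mapping.get(s) for s in succ}
        if child_true == true_divs[p_true]:
            tp += 1
    n_true = len(true_divs)
    ppv = tp / n_pred if n_pred else 1.0
    sens = tp / n_true if n_true else 1.0
    return ppv, sens, tp, n_pred, n_true


def confusion_matrix(pairs: Sequence[Tuple[str, str]],
                     classes: Sequence[str] = ("division", "two_cell", "fp", "other")
                     ) -> np.ndarray:
    """4x4 count matrix, rows = true class, columns = predicted class."""
    idx = {c: i for i, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for true_c, pred_c in pairs:
        m[idx[true_c], idx[pred_c]] += 1
    return m


def density_binned_errors(pred: Lineage, truth: Lineage,
                          n_bins: int = 5,
                          mapping: Optional[Dict[int, Optional[int]]] = None
                          ) -> List[Tuple[float, float, int]]:
    """Error counts stratified by local density of the true detection."""
    flags, _, _ = _error_flags(pred, truth, mapping)
    dens = {}
    by_frame = {t: truth.detections_at(t) for t in truth.frames()}
    for true_id, bad in flags.items():
        det = truth.detections[true_id]
        d = density(det, by_frame[det.t])
        if d is not None and np.isfinite(d):
            dens[true_id] = d
    if not dens:
        return []
    vals = np.array(list(dens.values()))
    edges = np.linspace(vals.min(), vals.max() + 1e-9, n_bins + 1)
    bins = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        n_err = sum(1 for i, d in dens.items() if lo <= d < hi and flags[i])
        bins.append((float(lo), float(hi), int(n_err)))
    return bins


def evaluate_lineages(pred: Lineage, truth: Lineage,
                      cell_of: Optional[Dict[int, int]] = None,
                      generation_of: Optional[Dict[int, int]] = None) -> EvalReport:
    """Full scoring report for a predicted lineage against the truth."""
    mapping = match_detections(pred, truth)
    flags, n_fp, counts = _error_flags(pred, truth, mapping)
    n = len(flags)
    errors = sum(flags.values()) + n_fp
    ppv, sens, tp, n_pred, n_true = division_scores(pred, truth, mapping)
    cum = {}
    if cell_of is not None and generation_of is not None:
        cum = cumulative_accuracy(pred, truth, cell_of, generation_of, mapping)
    return EvalReport(
        instantaneous_accuracy=1.0 - errors / n if n else 1.0,
        n_cell_frames=n,
        n_errors=errors,
        cumulative_accuracy=cum,
        division_ppv=ppv,
        division_sensitivity=sens,
        n_true_divisions=n_true,
        n_pred_divisions=n_pred,
        error_counts=counts,
        density_bins=density_binned_errors(pred, truth, mapping=mapping),
    )
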