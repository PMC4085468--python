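"""Synthetic dividing-embryo generator with ground truth and error injection.

The motion model is a bounded random walk inside a reflecting ellipsoid
with soft pairwise repulsion: the tracker only assumes the limited-motion
displacement regime (per-frame movement well below half the same-frame NN
distance), so realism beyond NN statistics is unnecessary.  Divisions
carry a parametrized signature: the parent's eccentricity ramps up before
division (metaphase-plate proxy) and the children appear symmetrically
about the parent with shrunken radii.

Detection errors are injected independently: false negatives drop interior
track detections (never two adjacent frames of the same cell), false
positives spawn short-lived dim detections adjacent to real nuclei, and
Gaussian jitter perturbs every observed position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from lineagetrace.model import Detection, Lineage, TrackingConfig


@dataclass
class SimConfig:
    n_start_cells: int = 2
    n_frames: int = 50
    cell_cycle_mean: float = 25.0
    cell_cycle_sd: float = 2.0
    motion_step: float = 0.2                  # fraction of own NN distance per frame
    arena: Tuple[float, float, float] = (25.0, 15.0, 15.0)   # ellipsoid semi-axes, um
    base_radius: float = 2.5
    base_intensity: float = 1000.0
    ecc_interphase: float = 0.15
    ecc_metaphase: float = 0.9
    ecc_ramp_frames: int = 3
    child_separation: float = 1.6             # in parent radii, center to center
    child_radius_shrink: float = 0.8
    fp_rate: float = 0.0                      # per true detection per frame
    fn_rate: float = 0.0                      # per droppable true detection
    jitter_sd: float = 0.0                    # microns, per axis
    fp_lifetime_max: int = 3
    fp_radius_factor: float = 0.6
    fp_intensity_factor: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fp_rate < 1.0 and 0.0 <= self.fn_rate < 1.0):
            raise ValueError("fp_rate and fn_rate must lie in [0, 1)")
        if not (0.0 < self.motion_step < 0.5):
            raise ValueError("motion_step must lie in (0, 0.5) to keep the "
                             "safe-link regime satisfiable")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        for name in ("n_start_cells", "n_frames", "cell_cycle_mean", "base_radius",
                     "base_intensity", "child_separation", "child_radius_shrink"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["arena"] = list(self.arena)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        kw = {k: v for k, v in d.items() if k in known}
        if "arena" in kw:
            kw["arena"] = tuple(kw["arena"])
        return cls(**kw)


@dataclass
class ErrorAnnotations:
    """Reconciliation between true and observed detections."""

    obs_to_true: Dict[int, Optional[int]] = field(default_factory=dict)
    dropped_ids: Set[int] = field(default_factory=set)      # true ids lost as FN
    fp_ids: Set[int] = field(default_factory=set)           # observed ids with no truth
    fp_tracks: List[List[int]] = field(default_factory=list)
    jitter_sd: float = 0.0


@dataclass
class SyntheticEmbryo:
    config: SimConfig
    true_lineage: Lineage
    cell_of: Dict[int, int]                  # true detection id -> cell id
    generation_of: Dict[int, int]            # cell id -> generation (divisions before it)
    observed: Optional[List[Detection]] = None
    annotations: Optional[ErrorAnnotations] = None

    def true_detections(self) -> List[Detection]:
        return [self.true_lineage.detections[i] for i in sorted(self.true_lineage.detections)]


class _Cell:
    __slots__ = ("cell_id", "pos", "radius", "intensity", "birth_frame",
                 "cycle_len", "generation", "last_det")

    def __init__(self, cell_id, pos, radius, intensity, birth_frame, cycle_len, generation):
        self.cell_id = cell_id
        self.pos = np.asarray(pos, dtype=float)
        self.radius = float(radius)
        self.intensity = float(intensity)
        self.birth_frame = int(birth_frame)
        self.cycle_len = int(cycle_len)
        self.generation = int(generation)
        self.last_det: Optional[int] = None

    def age(self, t: int) -> int:
        return t - self.birth_frame

    def frames_to_division(self, t: int) -> int:
        return self.cycle_len - self.age(t) - 1


def _inside(pos: np.ndarray, axes: Tuple[float, float, float]) -> float:
    a = np.asarray(axes)
    return float(np.sum((pos / a) ** 2))


def _reflect(pos: np.ndarray, axes: Tuple[float, float, float]) -> np.ndarray:
    rho = _inside(pos, axes)
    if rho > 1.0:
        pos = pos * (0.98 / math.sqrt(rho))
    return pos


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _repel(cells: List[_Cell], axes, n_sweeps: int = 4) -> None:
    """Push overlapping nuclei apart (soft volume exclusion)."""
    for _ in range(n_sweeps):
        moved = False
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                ci, cj = cells[i], cells[j]
                delta = cj.pos - ci.pos
                dist = float(np.linalg.norm(delta))
                min_sep = 1.1 * (ci.radius + cj.radius)
                if dist < min_sep:
                    if dist < 1e-9:
                        delta = np.array([1.0, 0.0, 0.0])
                        dist = 1.0
                    push = 0.5 * (min_sep - dist) * delta / dist
                    ci.pos = _reflect(ci.pos - push, axes)
                    cj.pos = _reflect(cj.pos + push, axes)
                    moved = True
        if not moved:
            break


def _nn_distances(cells: Sequence[_Cell]) -> np.ndarray:
    pts = np.array([c.pos for c in cells])
    if len(pts) < 2:
        return np.full(len(pts), np.inf)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def generate_embryo(config: SimConfig) -> SyntheticEmbryo:
    """Simulate the embryo and record its ground-truth lineage.

    Detection ids are assigned in (frame, cell id) order, so a seeded run
    is bit-reproducible.  Raises if the arena cannot accommodate the
    requested cells.
    """
    rng = np.random.default_rng(config.rng_seed)
    axes = config.arena

    cells: List[_Cell] = []
    next_cell = 0
    for _ in range(config.n_start_cells):
        placed = False
        for _attempt in range(10000):
            pos = (rng.uniform(-1, 1, size=3)) * np.asarray(axes) * 0.7
            if _inside(pos, axes) > 0.7:
                continue
            if all(np.linalg.norm(pos - c.pos) > 3.0 * config.base_radius for c in cells):
                placed = True
                break
        if not placed:
            raise RuntimeError("infeasible packing: cannot place starting cells in arena")
        cyc = max(3, int(round(rng.normal(config.cell_cycle_mean, config.cell_cycle_sd))))
        cells.append(_Cell(next_cell, pos, config.base_radius, config.base_intensity
                           * float(rng.uniform(0.9, 1.1)), 1, cyc, 0))
        next_cell += 1

    lineage = Lineage()
    cell_of: Dict[int, int] = {}
    generation_of: Dict[int, int] = {c.cell_id: 0 for c in cells}
    next_det = 1

    for t in range(1, config.n_frames + 1):
        # record detections for this frame
        for c in sorted(cells, key=lambda c: c.cell_id):
            ttd = c.frames_to_division(t)
            if 0 <= ttd < config.ecc_ramp_frames:
                frac = 1.0 - ttd / config.ecc_ramp_frames
                ecc = config.ecc_interphase + frac * (config.ecc_metaphase
                                                      - config.ecc_interphase)
            else:
                ecc = float(np.clip(config.ecc_interphase
                                    + rng.normal(0, 0.03), 0.0, 1.0))
            det = Detection(id=next_det, t=t, x=float(c.pos[0]), y=float(c.pos[1]),
                            z=float(c.pos[2]), radius=c.radius, intensity=c.intensity,
                            eccentricity=float(ecc))
            lineage.add_detection(det)
            cell_of[det.id] = c.cell_id
            if c.last_det is not None:
                lineage.add_link(c.last_det, det.id)
            c.last_det = det.id
            next_det += 1

        if t == config.n_frames:
            break

        # divisions taking effect at t+1
        new_cells: List[_Cell] = []
        survivors: List[_Cell] = []
        for c in sorted(cells, key=lambda c: c.cell_id):
            if c.frames_to_division(t) <= 0:
                axis = _unit_vector(rng)
                sep = 0.5 * config.child_separation * c.radius
                r_child = c.radius * config.child_radius_shrink
                for sign in (+1.0, -1.0):
                    cyc = max(3, int(round(rng.normal(config.cell_cycle_mean,
                                                      config.cell_cycle_sd))))
                    child = _Cell(next_cell, _reflect(c.pos + sign * sep * axis, axes),
                                  r_child, 0.55 * c.intensity, t + 1, cyc,
                                  c.generation + 1)
                    child.last_det = c.last_det  # link both children to the parent
                    generation_of[child.cell_id] = child.generation
                    new_cells.append(child)
                    next_cell += 1
            else:
                survivors.append(c)

        # bounded random-walk step for surviving cells
        if survivors:
            nn = _nn_distances(cells)
            nn_of = {c.cell_id: d for c, d in zip(cells, nn)}
            for c in survivors:
                d_nn = nn_of[c.cell_id]
                if not np.isfinite(d_nn):
                    d_nn = 4.0 * c.radius
                step = config.motion_step * d_nn * float(rng.uniform(0.0, 1.0))
                c.pos = _reflect(c.pos + step * _unit_vector(rng), axes)

        cells = survivors + new_cells
        _repel(cells, axes)
        # children of a division share last_det (the parent detection);
        # Lineage.add_link enforces the <=2 successor rule for us

    embryo = SyntheticEmbryo(config=config, true_lineage=lineage, cell_of=cell_of,
                             generation_of=generation_of)
    return embryo


# ---------------------------------------------------------------------------
# error injection


def _droppable(lineage: Lineage, det_id: int, dropped: Set[int]) -> bool:
    """FN candidates: strictly interior 1:1 detections whose same-track
    neighbors are intact (gaps stay single-frame)."""
    pred = lineage.predecessor(det_id)
    succ = lineage.successors(det_id)
    if pred is None or len(succ) != 1:
        return False
    if len(lineage.successors(pred)) != 1:
        return False          # right after a division
    if pred in dropped or succ[0] in dropped:
        return False
    # the successor must itself continue 1:1 so the repair window is clean
    if len(lineage.successors(succ[0])) > 1:
        return False
    return True


def inject_errors(embryo: SyntheticEmbryo, config: Optional[SimConfig] = None,
                  rng: Optional[np.random.Generator] = None
                  ) -> Tuple[List[Detection], ErrorAnnotations]:
    """Derive the observed detection set from the ground truth.

    Kept detections keep their true ids; FP detections get fresh ids.  The
    returned annotations exactly reconcile observed and true counts.
    """
    config = config or embryo.config
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    truth = embryo.true_lineage
    ann = ErrorAnnotations(jitter_sd=config.jitter_sd)

    true_ids = sorted(truth.detections)
    for det_id in true_ids:
        if config.fn_rate > 0 and _droppable(truth, det_id, ann.dropped_ids) \
                and rng.random() < config.fn_rate:
            ann.dropped_ids.add(det_id)

    observed: List[Detection] = []
    for det_id in true_ids:
        if det_id in ann.dropped_ids:
            continue
        det = truth.detections[det_id]
        pos = det.position
        if config.jitter_sd > 0:
            pos = pos + rng.normal(0.0, config.jitter_sd, size=3)
        observed.append(Detection(id=det.id, t=det.t, x=float(pos[0]), y=float(pos[1]),
                                  z=float(pos[2]), radius=det.radius,
                                  intensity=det.intensity,
                                  eccentricity=det.eccentricity))
        ann.obs_to_true[det.id] = det.id

    next_id = max(true_ids, default=0) + 1
    n_frames = config.n_frames
    for det_id in true_ids:
        if config.fp_rate <= 0 or rng.random() >= config.fp_rate:
            continue
        src = truth.detections[det_id]
        lifetime = int(rng.integers(1, config.fp_lifetime_max + 1))
        offset = _unit_vector(rng) * 1.5 * src.radius
        pos = src.position + offset
        track: List[int] = []
        for k in range(lifetime):
            t = src.t + k
            if t > n_frames:
                break
            if config.jitter_sd > 0:
                pos = pos + rng.normal(0.0, config.jitter_sd, size=3)
            fp = Detection(id=next_id, t=t, x=float(pos[0]), y=float(pos[1]),
                           z=float(pos[2]),
                           radius=src.radius * config.fp_radius_factor,
                           intensity=src.intensity * config.fp_intensity_factor,
                           eccentricity=0.3)
            observed.append(fp)
            ann.obs_to_true[fp.id] = None
            ann.fp_ids.add(fp.id)
            track.append(fp.id)
            next_id += 1
            pos = pos + _unit_vector(rng) * 0.2 * src.radius
        if track:
            ann.fp_tracks.append(track)

    observed.sort(key=lambda d: (d.t, d.id))
    embryo.observed = observed
    embryo.annotations = ann
    return observed, ann


# ---------------------------------------------------------------------------
# idealized cumulative-error simulation


def simulate_cumulative_accuracy(error_rate: float, n_frames: int, cycle_frames: int,
                                 n_reps: int, seed: int = 0) -> np.ndarray:
    """Fraction of cells with an error-free history, per generation.

    An idealized lineage starts from one cell and divides synchronously
    every ``cycle_frames`` frames.  An independent error is introduced at
    each (cell, frame) with probability ``error_rate``; a cell counts as
    correct only if no error occurred anywhere along its history.  Returns
    the mean fraction correct at the end of each generation over
    ``n_reps`` replicates.
    """
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_gens = (n_frames - 1) // cycle_frames + 1 if cycle_frames < n_frames else 1
    acc = np.zeros(n_gens, dtype=float)
    for _ in range(n_reps):
        clean = np.ones(1, dtype=bool)
        g = 0
        for f in range(1, n_frames + 1):
            clean &= rng.random(clean.size) >= error_rate
            if f % cycle_frames == 0 and f < n_frames:
                acc[g] += clean.mean()
                g += 1
                clean = np.repeat(clean, 2)
        acc[g] += clean.mean()
    return acc / n_reps


# ---------------------------------------------------------------------------
# truth labeling and training-set collection


def _cell_of_obs(obs_id: int, embryo: SyntheticEmbryo,
                 ann: ErrorAnnotations) -> Optional[int]:
    true_id = ann.obs_to_true.get(obs_id)
    if true_id is None:
        return None
    return embryo.cell_of.get(true_id)


def label_neighborhood(nb, embryo: SyntheticEmbryo, ann: ErrorAnnotations) -> str:
    """Ground-truth class of a tentative bifurcation neighborhood."""
    bif = nb.bifurcation
    truth = embryo.true_lineage
    p_true = ann.obs_to_true.get(bif.parent_id)
    orphan_cell = _cell_of_obs(bif.child_b_id, embryo, ann)
    cells = [_cell_of_obs(c, embryo, ann) for c in bif.child_ids]

    if any(c is None for c in cells):
        return "fp"

    if p_true is not None and not bif.is_degenerate:
        true_succ = truth.successors(p_true)
        if len(true_succ) == 2:
            succ_cells = {embryo.cell_of[s] for s in true_succ}
            if set(cells) == succ_cells:
                return "division"
    if p_true is not None and bif.is_degenerate:
        true_succ = truth.successors(p_true)
        if len(true_succ) == 2 and orphan_cell in {embryo.cell_of[s] for s in true_succ}:
            return "division"
        if len(true_succ) == 1 and embryo.cell_of[true_succ[0]] == orphan_cell:
            return "two_cell"

    if nb.termination_end_id is not None:
        term_cell = _cell_of_obs(nb.termination_end_id, embryo, ann)
        if term_cell is not None and term_cell == orphan_cell:
            return "two_cell"
    return "other"


def make_training_set(n_per_class: int, sim_config: Optional[SimConfig] = None,
                      tracking_config: Optional[TrackingConfig] = None,
                      seed: int = 0, max_embryos: int = 200):
    """Collect labeled neighborhood feature vectors from simulated embryos.

    The full resolution loop is driven over error-injected embryos with a
    ground-truth oracle standing in for the classifier, so the lineage
    states in which neighborhoods are measured match the states the fitted
    classifier will see at inference time (e.g. the first daughter of a
    division arrives as a degenerate attachment, the second as a proper
    two-child bifurcation).  Returns ``(features, labels)`` with up to
    ``n_per_class`` examples per class.
    """
    from lineagetrace.classify import CLASSES, Posterior, extract_features
    from lineagetrace.resolve import trace_lineage

    tcfg = tracking_config or TrackingConfig()
    base = sim_config or SimConfig(n_start_cells=6, n_frames=40,
                                   cell_cycle_mean=14.0, cell_cycle_sd=2.0,
                                   fp_rate=0.03, fn_rate=0.02, jitter_sd=0.05)

    feats: List = []
    labels: List[str] = []
    counts = {c: 0 for c in CLASSES}

    for k in range(max_embryos):
        if all(counts[c] >= n_per_class for c in CLASSES):
            break
        cfg = SimConfig.from_dict({**base.to_dict(), "rng_seed": seed + 1000 * k})
        embryo = generate_embryo(cfg)
        observed, ann = inject_errors(embryo, cfg)

        def oracle(nb, lineage):
            label = label_neighborhood(nb, embryo, ann)
            if counts[label] < n_per_class:
                feats.append(extract_features(nb, lineage, tcfg))
                labels.append(label)
                counts[label] += 1
            probs = tuple(1.0 if c == label else 0.0 for c in CLASSES)
            return label, Posterior(classes=CLASSES, probabilities=probs)

        trace_lineage(observed, None, tcfg, classifier=oracle)

        # non-top candidate neighborhoods: the natural source of "other"
        # examples (and of two_cell examples seen through a wrong parent),
        # which a perfect oracle run rarely visits
        if counts["other"] < n_per_class:
            from lineagetrace.bifurcation import (build_neighborhood,
                                                  candidate_parents,
                                                  find_orphans,
                                                  find_terminations)
            from lineagetrace.linking import link_all
            lin1 = link_all(observed, tcfg)
            for orphan in find_orphans(lin1):
                if counts["other"] >= n_per_class:
                    break
                for bif in candidate_parents(orphan, lin1, tcfg, model=None)[1:3]:
                    nb = build_neighborhood(bif, find_terminations(lin1, bif, tcfg),
                                            lin1, tcfg)
                    label = label_neighborhood(nb, embryo, ann)
                    if counts[label] >= n_per_class:
                        continue
                    feats.append(extract_features(nb, lin1, tcfg))
                    labels.append(label)
                    counts[label] += 1
    return feats, labels
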