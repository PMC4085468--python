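"""Feature measurement on semi-local neighborhoods and Naive Bayes posteriors.

Four bifurcation classes are modeled: ``division`` (a real cell division),
``two_cell`` (two non-dividing nuclei — excessive movement or a detection
gap, paired with a terminating track), ``fp`` (a spurious detection), and
``other`` (the neighborhood cannot explain the bifurcation, e.g. a child
attached to the wrong mother).  Class-conditional feature distributions
are univariate Gaussians, fit from labeled training neighborhoods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from lineagetrace.bifurcation import Neighborhood, bifurcation_centroid
from lineagetrace.linking import FrameIndex
from lineagetrace.model import Detection, Lineage, TrackingConfig

CLASSES: Tuple[str, ...] = ("division", "two_cell", "fp", "other")

FEATURE_NAMES: Tuple[str, ...] = (
    "child_size_ratio",            # min/max child radius
    "child_intensity_ratio",       # min/max child intensity
    "parent_eccentricity",         # metaphase-plate proxy (imputed if absent)
    "child_gap_ratio",             # child-child distance / parent diameter
    "child_angle",                 # angle at parent between the two children
    "child_displacement_ratio",    # mean parent->child displacement / parent radius
    "child_condensation_ratio",    # mean child radius / parent radius
    "shorter_branch_length",       # forward frames of the shorter branch (capped)
    "termination_gap_frames",      # frames between termination and bifurcation
    "termination_distance_ratio",  # term end distance / median NN distance
    "parent_density",              # (r_p + r_NN) / NN distance at parent frame
    "parent_intensity_ratio",      # parent intensity / frame median intensity
)

_ECC_DEFAULT = 0.5  # fallback when no training medians are available


@dataclass(frozen=True)
class FeatureVector:
    values: Tuple[float, ...]
    names: Tuple[str, ...] = FEATURE_NAMES

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass
class NBModel:
    """Class priors plus per-class, per-feature Gaussian parameters."""

    classes: Tuple[str, ...]
    priors: np.ndarray                  # shape (C,)
    means: np.ndarray                   # shape (C, F)
    sds: np.ndarray                     # shape (C, F), strictly positive
    feature_names: Tuple[str, ...] = FEATURE_NAMES
    feature_medians: Optional[np.ndarray] = None   # imputation values, shape (F,)

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if abs(self.priors.sum() - 1.0) > 1e-12:
            raise ValueError("class priors must sum to 1")
        if (self.priors < 0).any():
            raise ValueError("class priors must be non-negative")
        if (self.sds <= 0).any():
            raise ValueError("all feature sds must be positive")

    def to_dict(self) -> dict:
        d = {
            "classes": list(self.classes),
            "feature_names": list(self.feature_names),
            "priors": self.priors.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
        }
        if self.feature_medians is not None:
            d["feature_medians"] = self.feature_medians.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NBModel":
        med = d.get("feature_medians")
        return cls(
            classes=tuple(d["classes"]),
            priors=np.asarray(d["priors"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            feature_names=tuple(d["feature_names"]),
            feature_medians=None if med is None else np.asarray(med, dtype=float),
        )


@dataclass(frozen=True)
class Posterior:
    classes: Tuple[str, ...]
    probabilities: Tuple[float, ...]

    def prob(self, cls: str) -> float:
        return self.probabilities[self.classes.index(cls)]

    def argmax(self) -> str:
        # fixed class-order tie break: first index of the maximum wins
        arr = np.asarray(self.probabilities)
        return self.classes[int(np.argmax(arr))]


# ---------------------------------------------------------------------------
# feature extraction


def _branch_length(lineage: Lineage, det_id: int, cap: int) -> int:
    """Frames in the forward 1:1 chain from det_id, inclusive, capped."""
    n = 1
    cur = det_id
    while n < cap:
        succ = lineage.successors(cur)
        if len(succ) != 1:
            break
        cur = succ[0]
        n += 1
    return n


def extract_features(neighborhood: Neighborhood, lineage: Lineage,
                     config: Optional[TrackingConfig] = None,
                     medians: Optional[np.ndarray] = None) -> FeatureVector:
    """Measure the fixed-order feature vector of a neighborhood.

    A missing parent eccentricity is imputed from ``medians`` when given
    (training medians carried on the model), else a neutral constant.
    Degenerate single-child bifurcations duplicate the lone child so the
    child-pair features stay defined.
    """
    config = config or TrackingConfig()
    bif = neighborhood.bifurcation
    parent = lineage.detections[bif.parent_id]
    kids = [lineage.detections[c] for c in bif.child_ids]
    if len(kids) == 1:
        kids = [kids[0], kids[0]]
    ca, cb = kids

    r = (min(ca.radius, cb.radius) / max(ca.radius, cb.radius))
    imax = max(ca.intensity, cb.intensity)
    i_ratio = (min(ca.intensity, cb.intensity) / imax) if imax > 0 else 1.0

    if parent.eccentricity is not None:
        ecc = parent.eccentricity
    elif medians is not None and np.isfinite(medians[2]):
        ecc = float(medians[2])
    else:
        ecc = _ECC_DEFAULT

    gap_ratio = ca.distance_to(cb) / (2.0 * parent.radius)

    va = ca.position - parent.position
    vb = cb.position - parent.position
    na, nb_ = np.linalg.norm(va), np.linalg.norm(vb)
    if na > 0 and nb_ > 0 and bif.child_a_id is not None:
        cosang = float(np.clip(np.dot(va, vb) / (na * nb_), -1.0, 1.0))
        angle = math.acos(cosang)
    else:
        angle = 0.0

    disp_ratio = 0.5 * (na + nb_) / parent.radius
    cond_ratio = 0.5 * (ca.radius + cb.radius) / parent.radius

    cap = config.fp_max_track_length + 2
    lengths = sorted(_branch_length(lineage, c, cap) for c in set(bif.child_ids))
    shorter = float(lengths[0])

    if neighborhood.termination_end_id is not None:
        gap = float(min(neighborhood.gap_frames, config.termination_window_dt))
        end = lineage.detections[neighborhood.termination_end_id]
        centroid = bifurcation_centroid(bif, lineage)
        med = neighborhood.median_nn_distance
        if not np.isfinite(med) or med <= 0:
            med = 2.0 * parent.radius
        term_ratio = float(np.linalg.norm(end.position - centroid)) / med
        term_ratio = min(term_ratio, 2.0 * config.termination_window_dx)
    else:
        gap = 0.0
        term_ratio = 2.0 * config.termination_window_dx  # sentinel: nothing nearby

    idx_t = FrameIndex(lineage.detections_at(parent.t))
    nn = idx_t.nearest(parent.position, exclude_id=parent.id)
    if nn is None:
        density = 0.0
    else:
        density = (parent.radius + nn.radius) / parent.distance_to(nn)

    intensities = [d.intensity for d in idx_t.detections]
    med_int = float(np.median(intensities)) if intensities else 0.0
    pint_ratio = parent.intensity / med_int if med_int > 0 else 1.0

    values = (r, i_ratio, ecc, gap_ratio, angle, disp_ratio, cond_ratio,
              shorter, gap, term_ratio, density, pint_ratio)
    return FeatureVector(values=tuple(float(v) for v in values))


# ---------------------------------------------------------------------------
# model fitting and inference


def fit(features: Sequence[FeatureVector], labels: Sequence[str],
        classes: Tuple[str, ...] = CLASSES) -> NBModel:
    """Fit priors and per-class Gaussian feature distributions.

    Priors are empirical class frequencies.  Standard deviations are
    floored at 1e-6 times the global feature range so a constant feature
    cannot produce a degenerate likelihood.  NaN feature entries (missing
    optional measurements) are imputed with the per-feature median of the
    finite training values.
    """
    if len(features) != len(labels):
        raise ValueError("features and labels must have equal length")
    X = np.array([f.as_array() for f in features], dtype=float)
    y = np.asarray(labels)

    medians = np.nanmedian(X, axis=0)
    nan_rows, nan_cols = np.where(np.isnan(X))
    X[nan_rows, nan_cols] = medians[nan_cols]

    counts = {c: int((y == c).sum()) for c in classes}
    for c, n in counts.items():
        if n < 2:
            raise ValueError(f"class {c!r} needs at least 2 training examples, got {n}")

    rng_span = X.max(axis=0) - X.min(axis=0)
    sd_floor = np.maximum(1e-6 * rng_span, 1e-6)

    priors = np.array([counts[c] for c in classes], dtype=float)
    priors /= priors.sum()
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    sds = np.vstack([X[y == c].std(axis=0, ddof=1) for c in classes])
    sds = np.maximum(sds, sd_floor)
    return NBModel(classes=classes, priors=priors, means=means, sds=sds,
                   feature_medians=medians)


def _impute(model: NBModel, M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float).copy()
    bad = ~np.isfinite(M)
    if bad.any():
        fill = (model.feature_medians if model.feature_medians is not None
                else model.means.mean(axis=0))
        M[bad] = np.asarray(fill)[bad]
    return M


def log_joint(model: NBModel, M: np.ndarray) -> np.ndarray:
    """Unnormalized per-class log P(class) + log P(M | class)."""
    M = _impute(model, M)
    ll = norm.logpdf(M[None, :], loc=model.means, scale=model.sds).sum(axis=1)
    with np.errstate(divide="ignore"):
        return np.log(model.priors) + ll


def posterior(model: NBModel, M) -> Posterior:
    """Normalized class posterior, computed in log space."""
    if isinstance(M, FeatureVector):
        M = M.as_array()
    lj = log_joint(model, np.asarray(M, dtype=float))
    probs = np.exp(lj - logsumexp(lj))
    probs /= probs.sum()
    return Posterior(classes=model.classes, probabilities=tuple(float(p) for p in probs))


def division_log_score(model: NBModel, fv: FeatureVector) -> float:
    """Log joint of the division class, used to rank candidate parents."""
    lj = log_joint(model, fv.as_array())
    return float(lj[model.classes.index("division")])


def classify(model: NBModel, neighborhood: Neighborhood, lineage: Lineage,
             config: Optional[TrackingConfig] = None) -> Tuple[str, Posterior]:
    """Extract features and return (argmax class, posterior)."""
    fv = extract_features(neighborhood, lineage, config,
                          medians=model.feature_medians)
    post = posterior(model, fv)
    return post.argmax(), post
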