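"""Valence/arousal label construction.

Self-assessed valence and arousal (1-9 scale, circumplex model of affect) are
mapped to one-hot emotion labels under three schemes:

* ``valence2``  — [HV, LV], split at the valence threshold;
* ``arousal2``  — [HA, LA], split at the arousal threshold;
* ``quadrant4`` — [HAHV, HALV, LALV, LAHV], the four quadrants of the
  valence-arousal plane.

The threshold defaults to (5, 5), the centre of the rating scale.  A seeded
k-means on the observed (valence, arousal) cloud is provided as a diagnostic
that the centroid mean sits near (5, 5); labeling itself always uses the fixed
configured threshold so that labels are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError

#: Class name order per scheme; fixes the one-hot component order.
SCHEME_CLASSES: dict[str, tuple[str, ...]] = {
    "valence2": ("HV", "LV"),
    "arousal2": ("HA", "LA"),
    "quadrant4": ("HAHV", "HALV", "LALV", "LAHV"),
}

DEFAULT_THRESHOLD: tuple[float, float] = (5.0, 5.0)


def _check_rating(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or not (1.0 <= value <= 9.0):
        raise ValidationError(f"rating {name}={value!r} outside [1, 9]")
    return value


@dataclass(frozen=True)
class SelfAssessment:
    """One trial's self-assessment ratings, each on the 1-9 SAM scale.

    Dominance and liking are carried for completeness but unused downstream.
    """

    valence: float
    arousal: float
    dominance: float = 5.0
    liking: float = 5.0

    def __post_init__(self) -> None:
        for name in ("valence", "arousal", "dominance", "liking"):
            object.__setattr__(self, name, _check_rating(name, getattr(self, name)))


@dataclass(frozen=True)
class EmotionLabel:
    """A one-hot emotion label under a 2- or 4-class scheme."""

    scheme: str
    class_name: str
    onehot: tuple[int, ...]

    @property
    def class_index(self) -> int:
        return self.onehot.index(1)

    @property
    def n_classes(self) -> int:
        return len(self.onehot)


@dataclass
class ClusterResult:
    """Output of Lloyd's algorithm on rating points."""

    k: int
    centroids: np.ndarray  # (k, d)
    assignments: np.ndarray  # (n,)
    inertia: float
    inertia_history: list[float] = field(default_factory=list)


def _kmeans_pp_init(pts: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding: first centre uniform, then D^2 sampling."""
    n = pts.shape[0]
    centroids = np.empty((k, pts.shape[1]))
    centroids[0] = pts[rng.integers(n)]
    d2 = np.sum((pts - centroids[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with chosen centres
            centroids[j] = pts[rng.integers(n)]
            continue
        probs = d2 / total
        centroids[j] = pts[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((pts - centroids[j]) ** 2, axis=1))
    return centroids


def lloyd_iterate(
    pts: np.ndarray, centroids: np.ndarray, max_iter: int
) -> ClusterResult:
    """Run Lloyd's algorithm from explicit initial centroids to convergence.

    Exposed separately so a re-run from the identical initialization can serve
    as a reference for :func:`kmeans`.
    """
    centroids = np.array(centroids, dtype=float, copy=True)
    k = centroids.shape[0]
    assignments = np.full(pts.shape[0], -1)
    history: list[float] = []
    for _ in range(max_iter):
        d2 = np.sum((pts[:, None, :] - centroids[None, :, :]) ** 2, axis=2)
        new_assign = np.argmin(d2, axis=1)
        inertia = float(d2[np.arange(pts.shape[0]), new_assign].sum())
        history.append(inertia)
        for j in range(k):
            mask = new_assign == j
            if mask.any():
                centroids[j] = pts[mask].mean(axis=0)
            else:
                # re-seed an empty cluster at the point farthest from its centre
                worst = np.argmax(d2[np.arange(pts.shape[0]), new_assign])
                centroids[j] = pts[worst]
        if np.array_equal(new_assign, assignments):
            break
        assignments = new_assign
    d2 = np.sum((pts[:, None, :] - centroids[None, :, :]) ** 2, axis=2)
    assignments = np.argmin(d2, axis=1)
    inertia = float(d2[np.arange(pts.shape[0]), assignments].sum())
    return ClusterResult(k, centroids, assignments, inertia, history)


def kmeans(
    points, k: int, seed: int = 0, max_iter: int = 100
) -> ClusterResult:
    """Seeded k-means (k-means++-style init, then Lloyd's to convergence).

    Parameters
    ----------
    points : array-like, shape (n, 2)
        (valence, arousal) pairs, though any dimensionality is accepted.
    k : int
        Number of clusters; requires at least ``k`` distinct points.
    seed : int
        Seeds the initialization; the result is deterministic per seed.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    if np.unique(pts, axis=0).shape[0] < k:
        raise InputError(
            f"need at least {k} distinct points for k={k} clusters, "
            f"got {np.unique(pts, axis=0).shape[0]}"
        )
    rng = np.random.default_rng(seed)
    init = _kmeans_pp_init(pts, k, rng)
    return lloyd_iterate(pts, init, max_iter)


def derive_threshold(clusters: ClusterResult) -> tuple[float, float]:
    """Coordinate-wise mean of the centroids — the data-driven threshold.

    Diagnostic only: the labeling pipeline always applies the configured
    threshold (default (5, 5)); this checks how close the cluster structure
    puts the natural split to that default.
    """
    mean = clusters.centroids.mean(axis=0)
    return float(mean[0]), float(mean[1])


def assign_label(
    r: SelfAssessment,
    scheme: str,
    threshold: tuple[float, float] = DEFAULT_THRESHOLD,
) -> EmotionLabel:
    """Map a rating to a one-hot label.

    "High" means strictly greater than the threshold; a rating exactly at the
    threshold maps to "low", keeping the 2-class labels exact marginals of the
    4-class quadrants.
    """
    if scheme not in SCHEME_CLASSES:
        raise ValidationError(f"unknown scheme {scheme!r}")
    v_thr, a_thr = threshold
    hv = r.valence > v_thr
    ha = r.arousal > a_thr
    if scheme == "valence2":
        name = "HV" if hv else "LV"
    elif scheme == "arousal2":
        name = "HA" if ha else "LA"
    else:
        name = {  # (ha, hv) -> quadrant
            (True, True): "HAHV",
            (True, False): "HALV",
            (False, False): "LALV",
            (False, True): "LAHV",
        }[(ha, hv)]
    classes = SCHEME_CLASSES[scheme]
    onehot = tuple(int(c == name) for c in classes)
    return EmotionLabel(scheme=scheme, class_name=name, onehot=onehot)


def label_table(
    trials,
    scheme: str,
    threshold: tuple[float, float] = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Label every trial; returns the exportable table.

    Columns: subject_id, video_id, valence, arousal, scheme, class_name.
    """
    rows = []
    for t in trials:
        lab = assign_label(t.ratings, scheme, threshold)
        rows.append(
            {
                "subject_id": t.subject_id,
                "video_id": t.video_id,
                "valence": t.ratings.valence,
                "arousal": t.ratings.arousal,
                "scheme": scheme,
                "class_name": lab.class_name,
            }
        )
    return pd.DataFrame(rows)
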