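"""Spherical face-space experiments.

A single competitive pool is trained on exemplar clouds living on the
positive octant of the unit sphere. After training, each classifier's weight
vector is itself a point on the octant, so the map of classifiers can be read
in the same (azimuth, elevation) chart as the stimuli. Two phenomena are
probed here:

* **Holism emergence** — with few classifiers and anisotropic exemplar
  variance, classifiers line up along the high-variance dimension and ignore
  the minor one; more classifiers (or more balanced variance) force them to
  become sensitive to both dimensions.

* **Exposure asymmetry** — with two exemplar populations of equal variance
  but unequal exposure (e.g., 1000 vs 100 presentations per epoch),
  classifiers crowd the frequently seen region, thinning coverage of the
  rarely seen one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import PoolParams, TrainSchedule, train_pool
from .geometry import unit_to_azel
from .synth import FacePointSet, PopulationSpec, sample_face_space

__all__ = [
    "ClassifierMap",
    "run_face_space_experiment",
    "run_holism_condition",
    "assign_win_regions",
    "classifier_density_by_group",
    "classifier_spread",
]


@dataclass
class ClassifierMap:
    """A trained spherical face-space map and its provenance."""

    weights: np.ndarray  # (N, 3), unit rows
    classifier_azel: np.ndarray  # (N, 2) degrees
    params: PoolParams
    schedule: TrainSchedule
    specs: tuple[PopulationSpec, ...]
    seed: int
    points: FacePointSet  # the training exemplars


def run_face_space_experiment(
    specs: list[PopulationSpec] | tuple[PopulationSpec, ...],
    params: PoolParams,
    schedule: TrainSchedule,
    seed: int,
) -> ClassifierMap:
    """Sample exemplars, train one pool on them, and return the trained map."""
    points = sample_face_space(list(specs), seed)
    result = train_pool(points.points, params, schedule, seed)
    return ClassifierMap(
        weights=result.weights,
        classifier_azel=unit_to_azel(result.weights),
        params=params,
        schedule=schedule,
        specs=tuple(specs),
        seed=seed,
        points=points,
    )


def run_holism_condition(
    ratio: float,
    n_classifiers: int,
    seed: int,
    *,
    n_exemplars: int = 500,
    major_sd: float = 12.0,
    center: tuple[float, float] = (45.0, 45.0),
    r: float = 0.001,
    alpha: float | None = None,
    epochs: int = 2000,
) -> ClassifierMap:
    """One cell of the variance-ratio x classifier-count sweep.

    ``ratio`` scales the standard deviation of the minor dimension (azimuth)
    relative to the fixed major dimension (elevation): exemplars are drawn
    from a single normal cluster with s.d. ``(ratio * major_sd, major_sd)``
    degrees. The sweep's signature result is that the minor-dimension spread
    of the trained classifiers grows with either ``ratio`` or
    ``n_classifiers``.

    ``alpha`` defaults to the pool size N: sharp rank competition is what
    lets a large pool retain selectivity along the minor dimension; with a
    flat exponent the attraction of mid-ranked neurons toward every stimulus
    collapses every pool onto the major axis at steady state. Training runs
    to steady state (2000 epochs at r = 0.001 is well past convergence for
    500 exemplars).
    """
    spec = PopulationSpec(
        center_azel=center,
        sd_azel=(ratio * major_sd, major_sd),
        count=n_exemplars,
        label="sweep",
    )
    params = PoolParams(
        N=n_classifiers, r=r,
        alpha=float(n_classifiers) if alpha is None else alpha,
    )
    return run_face_space_experiment([spec], params, TrainSchedule(epochs=epochs), seed)


def assign_win_regions(cmap: ClassifierMap, points: FacePointSet) -> np.ndarray:
    """Winning classifier index per point (inner-product argmax).

    The induced partition of the octant is the spherical Voronoi tessellation
    under inner-product similarity; ties go to the lowest classifier index.
    """
    return np.argmax(points.points @ cmap.weights.T, axis=1)


def _group_centroids(points: FacePointSet, labels: list) -> np.ndarray:
    cents = []
    for lab in labels:
        sub = points.points[points.labels == lab]
        c = sub.mean(axis=0)
        cents.append(c / np.linalg.norm(c))
    return np.array(cents)


def classifier_winner_groups(
    cmap: ClassifierMap, points: FacePointSet | None = None
) -> np.ndarray:
    """Group label per classifier: the group whose points it wins most often.

    Classifiers that win no point at all are assigned to the group whose
    centroid is nearest in weight space.
    """
    if points is None:
        points = cmap.points
    group_labels = [s.label for s in cmap.specs]
    winners = assign_win_regions(cmap, points)
    n = cmap.weights.shape[0]
    counts = np.zeros((n, len(group_labels)), dtype=int)
    lab_index = {lab: i for i, lab in enumerate(group_labels)}
    for w, lab in zip(winners, points.labels):
        counts[w, lab_index[lab]] += 1
    assigned = np.array(group_labels, dtype=object)[np.argmax(counts, axis=1)]
    orphan = counts.sum(axis=1) == 0
    if np.any(orphan):
        cents = _group_centroids(points, group_labels)
        sims = cmap.weights[orphan] @ cents.T
        assigned[orphan] = np.array(group_labels, dtype=object)[np.argmax(sims, axis=1)]
    return assigned


def classifier_density_by_group(
    cmap: ClassifierMap, points: FacePointSet | None = None
) -> dict[str, int]:
    """How many classifiers cover each exemplar group's region of the space."""
    assigned = classifier_winner_groups(cmap, points)
    return {
        s.label: int(np.sum(assigned == s.label)) for s in cmap.specs
    }


def classifier_spread(cmap: ClassifierMap) -> tuple[float, float]:
    """Standard deviation of classifier positions per chart dimension
    (azimuth, elevation), in degrees."""
    sd = cmap.classifier_azel.std(axis=0, ddof=1)
    return float(sd[0]), float(sd[1])
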