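"""Cortical topography through local lateral excitation.

A 9 x 9 sheet of neurons (one competitive pool of 81 classifiers) is trained
on five clustered object categories with unequal exemplar counts. Each
neuron's output gains ``h`` times the average output of its (up to) eight
grid neighbors, which couples learning between cortical neighbors: with
``h = 0`` category preference is scattered randomly over the sheet, while
increasing ``h`` produces spatially contiguous patches of category-selective
neurons — quantified here by the neighbor-agreement index, the fraction of
neighboring neuron pairs sharing a preferred category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import PoolParams, TrainSchedule, train_pool
from .geometry import unit_to_azel
from .synth import FacePointSet, PopulationSpec, sample_face_space
from .topology import GridTopology

__all__ = [
    "CorticalMapResult",
    "default_category_specs",
    "run_cortical_experiment",
    "preferred_category",
    "neighbor_agreement",
]

# Five well-separated category centers in the (azimuth, elevation) chart,
# with exposure counts 50, 40, 20, 50, 100 — unequal visual diets.
_DEFAULT_CENTERS = [(18.0, 18.0), (18.0, 72.0), (72.0, 18.0), (72.0, 72.0), (45.0, 45.0)]
_DEFAULT_COUNTS = (50, 40, 20, 50, 100)
_DEFAULT_SD = 6.0


def default_category_specs(
    counts: tuple[int, ...] = _DEFAULT_COUNTS, sd: float = _DEFAULT_SD
) -> list[PopulationSpec]:
    """The five clustered object categories of the topography experiments."""
    return [
        PopulationSpec(center_azel=c, sd_azel=(sd, sd), count=n,
                       label=f"category_{i + 1}")
        for i, (c, n) in enumerate(zip(_DEFAULT_CENTERS, counts))
    ]


@dataclass
class CorticalMapResult:
    """Trained sheet: weights, per-neuron category preference, topography."""

    weights: np.ndarray  # (81, 3) unit rows
    classifier_azel: np.ndarray
    preferred: np.ndarray  # (81,) category label per neuron
    h: float
    agreement_index: float
    topology: GridTopology
    points: FacePointSet
    specs: tuple[PopulationSpec, ...]
    seed: int


def preferred_category(
    weights: np.ndarray,
    specs: list[PopulationSpec] | tuple[PopulationSpec, ...],
    points: FacePointSet,
) -> np.ndarray:
    """Category label per neuron: the category whose exemplars it wins most.

    A neuron that wins no exemplar at all falls back to the category whose
    centroid is nearest in weight space.
    """
    labels = [s.label for s in specs]
    winners = np.argmax(points.points @ weights.T, axis=1)
    n = weights.shape[0]
    counts = np.zeros((n, len(labels)), dtype=int)
    lab_index = {lab: i for i, lab in enumerate(labels)}
    for w, lab in zip(winners, points.labels):
        counts[w, lab_index[lab]] += 1
    out = np.array(labels, dtype=object)[np.argmax(counts, axis=1)]
    orphan = counts.sum(axis=1) == 0
    if np.any(orphan):
        cents = []
        for lab in labels:
            c = points.points[points.labels == lab].mean(axis=0)
            cents.append(c / np.linalg.norm(c))
        sims = weights[orphan] @ np.array(cents).T
        out[orphan] = np.array(labels, dtype=object)[np.argmax(sims, axis=1)]
    return out


def neighbor_agreement(labels: np.ndarray, topology: GridTopology) -> float:
    """Fraction of unordered neighbor pairs sharing a label, in [0, 1]."""
    labels = np.asarray(labels)
    if labels.shape[0] != topology.n_neurons:
        raise ValueError("one label per neuron is required")
    pairs = topology.neighbor_pairs()
    return float(np.mean(labels[pairs[:, 0]] == labels[pairs[:, 1]]))


def run_cortical_experiment(
    category_specs: list[PopulationSpec] | None = None,
    h: float = 0.0,
    seed: int = 0,
    *,
    topology: GridTopology | None = None,
    r: float = 0.001,
    alpha: float = 1.0,
    epochs: int = 1000,
) -> CorticalMapResult:
    """Train the neuron sheet on the clustered categories at lateral gain h.

    The lateral term enters the output and therefore, through the Hebbian
    rule, the learning itself. ``h = 0`` is bit-identical to a plain pool run
    with the same seed.

    ``alpha`` defaults to 1 (a flat rank profile, as in the hierarchical
    model's output layer): lateral excitation reorganizes the sheet only
    where mid-ranked neurons retain plasticity, since the coupling acts by
    scaling output-dependent learning. A steep exponent confines learning to
    the top-ranked neurons and leaves category preference unchanged across
    lateral gains. 1000 epochs is past convergence of the agreement index
    for the default category set.
    """
    if h < 0:
        raise ValueError("lateral gain h must be non-negative")
    specs = default_category_specs() if category_specs is None else list(category_specs)
    topology = GridTopology(9, 9) if topology is None else topology
    n = topology.n_neurons
    params = PoolParams(N=n, r=r, alpha=float(n) if alpha is None else alpha)
    points = sample_face_space(specs, seed)
    result = train_pool(
        points.points, params, TrainSchedule(epochs=epochs), seed,
        topology=topology, h=h,
    )
    preferred = preferred_category(result.weights, specs, points)
    return CorticalMapResult(
        weights=result.weights,
        classifier_azel=unit_to_azel(result.weights),
        preferred=preferred,
        h=h,
        agreement_index=neighbor_agreement(preferred, topology),
        topology=topology,
        points=points,
        specs=tuple(specs),
        seed=seed,
    )
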