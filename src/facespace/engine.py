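"""Rank-based competitive Hebbian learning kernel.

A pool of ``N`` neurons holds one non-negative, unit-norm weight vector each.
For a stimulus ``x`` the pool computes

* activations  ``gamma_i = sum_k x_k w_ik``  (inner products),
* ranks ``eta_i`` (1 = most active, ties broken by lowest index),
* a rank-based learning scale ``mu_i = r ((N - eta_i) / (N - 1))**alpha``,
* graded inhibited outputs
  ``y_i = (gamma_i - kappa * gav_i) / (gamma_max - kappa * gav_i)``,
  where ``gav_i`` is the mean activation of the ``avg_count`` most active
  *other* neurons, and
* a Hebbian update ``eps_i = mu_i y_i x + (1 - mu_i) w_i`` followed by
  renormalization of each row to unit length.

The same kernel drives the spherical face-space model, both layers of the
image hierarchy, and (with additive lateral excitation over a grid sheet)
the cortical-map simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np

from ._core import train_core
from ._rand import child_rng
from .topology import GridTopology

__all__ = [
    "PoolParams",
    "TrainSchedule",
    "ActivationState",
    "TrainResult",
    "DegenerateInputError",
    "init_weights",
    "compute_activation",
    "rank_activations",
    "learning_scale",
    "pool_output",
    "lateral_pool_output",
    "hebbian_step",
    "train_pool",
    "frozen_state",
    "check_weight_matrix",
]

_NORM_TOL = 1e-9


class DegenerateInputError(ValueError):
    """All activations are zero, so competition cannot resolve a winner."""


@dataclass(frozen=True)
class PoolParams:
    """Parameters of one inhibitory pool.

    Parameters
    ----------
    N : number of neurons (classifiers) in the pool, at least 2.
    r : Hebbian learning rate.
    alpha : rank exponent controlling how sharply learning falls off with
        rank; ``alpha = N`` makes the runner-up learn at roughly one third
        the winner's rate.
    kappa : inhibition constant in [0, 1); 0 disables graded inhibition.
    avg_count : how many most-active peers enter the inhibition baseline
        ``gamma_av`` (effectively ``min(avg_count, N - 1)``).
    clip_negative_y : if True, negative inhibited outputs are clipped to 0
        before learning; default off, matching the model equations as given.
    """

    N: int
    r: float
    alpha: float
    kappa: float = 0.3
    avg_count: int = 10
    clip_negative_y: bool = False

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2 (rank scale divides by N - 1)")
        if self.r <= 0:
            raise ValueError("learning rate r must be positive")
        if self.alpha <= 0:
            raise ValueError("rank exponent alpha must be positive")
        if not 0.0 <= self.kappa < 1.0:
            raise ValueError("kappa must lie in [0, 1)")
        if self.avg_count < 1:
            raise ValueError("avg_count must be positive")

    @cached_property
    def mu_table(self) -> np.ndarray:
        """Learning scale per rank, ``mu_table[eta - 1] = mu(eta)``."""
        eta = np.arange(1, self.N + 1, dtype=float)
        table = self.r * ((self.N - eta) / (self.N - 1.0)) ** self.alpha
        table.setflags(write=False)
        return table


@dataclass(frozen=True)
class TrainSchedule:
    """Epoch loop controls.

    ``epochs`` full passes over the stimulus set, each in a freshly shuffled
    pseudo-random order. If ``convergence_tol`` is set, training stops early
    once the mean absolute weight change over an epoch falls below it.
    """

    epochs: int = 100
    convergence_tol: float | None = None
    record_history: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.convergence_tol is not None and self.convergence_tol < 0:
            raise ValueError("convergence_tol must be non-negative")


@dataclass
class ActivationState:
    """Per-stimulus pool state: activations, ranks, inhibition terms, outputs.

    ``y`` is the output that drives learning and downstream layers. Without
    lateral excitation ``y`` equals ``y_base``; with it, ``y`` additionally
    carries ``h`` times the neighbor average of ``y_base``.
    """

    gamma: np.ndarray
    eta: np.ndarray
    gamma_max: float
    gamma_av: np.ndarray
    y: np.ndarray
    y_base: np.ndarray


@dataclass
class TrainResult:
    """Trained weights plus per-epoch diagnostics.

    ``max_norm_deviation`` is the largest deviation of any post-update weight
    row norm from 1 seen during training; ``max_winner_output_deviation`` the
    largest deviation of the winning neuron's inhibited output from 1. Both
    should sit at floating-point rounding level on a healthy run.
    """

    weights: np.ndarray
    epochs_run: int
    mean_weight_change: list[float] = field(default_factory=list)
    winner_entropy: list[float] = field(default_factory=list)
    max_norm_deviation: float = 0.0
    max_winner_output_deviation: float = 0.0


def check_weight_matrix(weights: np.ndarray, tol: float = _NORM_TOL) -> None:
    """Raise if any row is not unit-norm or any entry is negative."""
    weights = np.asarray(weights)
    if weights.ndim != 2:
        raise ValueError("weight matrix must be 2-D (N x K)")
    if np.any(weights < 0):
        raise ValueError("weight entries must be non-negative")
    norms = np.linalg.norm(weights, axis=1)
    if np.any(np.abs(norms - 1.0) > tol):
        raise ValueError("every weight row must have unit Euclidean norm")


def init_weights(params: PoolParams, K: int, seed) -> np.ndarray:
    """Random positive unit-norm weight rows, reproducible per seed.

    Entries are uniform on (0, 1] then each row is scaled to unit length,
    which places every row strictly inside the positive orthant of the unit
    sphere. ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if K < 2:
        raise ValueError("input dimensionality K must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(seed, "init")
    w = 1.0 - rng.random((params.N, K))  # uniform on (0, 1]
    return w / np.linalg.norm(w, axis=1, keepdims=True)


def compute_activation(weights: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Inner-product activations ``gamma_i = sum_k x_k w_ik``."""
    weights = np.asarray(weights, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or weights.ndim != 2 or weights.shape[1] != x.shape[0]:
        raise ValueError(
            f"shape mismatch: weights {weights.shape} vs input {x.shape}"
        )
    return weights @ x


def rank_activations(gamma: np.ndarray) -> np.ndarray:
    """Activation ranks: 1 = most active; ties go to the lowest index."""
    gamma = np.asarray(gamma)
    order = np.argsort(-gamma, kind="stable")
    eta = np.empty(gamma.shape[0], dtype=np.intp)
    eta[order] = np.arange(1, gamma.shape[0] + 1)
    return eta


def learning_scale(eta, params: PoolParams):
    """Rank-based learning scale ``mu = r ((N - eta) / (N - 1))**alpha``."""
    eta_arr = np.asarray(eta)
    if np.any(eta_arr < 1) or np.any(eta_arr > params.N):
        raise ValueError(f"rank out of range 1..{params.N}")
    out = params.mu_table[eta_arr - 1]
    return float(out) if np.isscalar(eta) or eta_arr.ndim == 0 else out


def _inhibition_terms(gamma: np.ndarray, params: PoolParams):
    """Ranks, per-neuron peer-average activation, and inhibited outputs."""
    n = gamma.shape[0]
    order = np.argsort(-gamma, kind="stable")
    eta = np.empty(n, dtype=np.intp)
    eta[order] = np.arange(1, n + 1)
    m = min(params.avg_count, n - 1)
    cs = np.cumsum(gamma[order])
    # neurons inside the top-m take the top-(m+1) total minus themselves
    gamma_av = np.where(eta <= m, (cs[m] - gamma) / m, cs[m - 1] / m)
    gamma_max = gamma[order[0]]
    base = gamma - params.kappa * gamma_av
    y = base / (gamma_max - params.kappa * gamma_av)
    return eta, gamma_av, gamma_max, y


def pool_output(gamma: np.ndarray, params: PoolParams) -> ActivationState:
    """Graded inhibited outputs of a pool.

    Each neuron's ``gamma_av`` is the mean of the ``min(avg_count, N-1)``
    largest activations among the *other* neurons and appears in both the
    numerator and denominator of its output, so the most active neuron's
    output is exactly 1. Outputs of weakly active neurons may be negative;
    they are not clipped unless the pool's ``clip_negative_y`` is set.
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape[0] != params.N:
        raise ValueError(f"expected {params.N} activations, got {gamma.shape[0]}")
    if np.max(gamma) <= 0.0:
        raise DegenerateInputError("no strictly positive activation in pool")
    eta, gamma_av, gamma_max, y = _inhibition_terms(gamma, params)
    if params.clip_negative_y:
        y = np.maximum(y, 0.0)
    return ActivationState(
        gamma=gamma, eta=eta, gamma_max=float(gamma_max),
        gamma_av=gamma_av, y=y, y_base=y,
    )


def lateral_pool_output(
    gamma: np.ndarray,
    params: PoolParams,
    topology: GridTopology,
    h: float,
) -> ActivationState:
    """Pool output with additive local lateral excitation.

    Each neuron's output is its inhibited output plus ``h`` times the simple
    average of the inhibited outputs of its available grid neighbors (3, 5 or
    8 depending on position). ``h = 0`` reproduces :func:`pool_output`
    exactly.
    """
    if h < 0:
        raise ValueError("lateral gain h must be non-negative")
    if topology.n_neurons != params.N:
        raise ValueError("topology size does not match pool size")
    state = pool_output(gamma, params)
    state.y = state.y_base + h * topology.neighbor_average(state.y_base)
    return state


def _hebbian_update(
    weights: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    eta: np.ndarray,
    params: PoolParams,
) -> np.ndarray:
    """Apply ``eps = mu y x + (1 - mu) w`` and renormalize active rows.

    Rows with ``mu = 0`` (the rank-N neuron) are left bitwise untouched.
    Negative entries are clipped to zero before renormalization to keep the
    weights on the non-negative sphere octant.
    """
    mu = params.mu_table[eta - 1]
    active = mu > 0.0
    if not np.any(active):
        return weights
    mu_a = mu[active, None]
    eps = mu_a * y[active, None] * x + (1.0 - mu_a) * weights[active]
    np.maximum(eps, 0.0, out=eps)
    norms = np.linalg.norm(eps, axis=1, keepdims=True)
    dead = norms[:, 0] == 0.0
    if np.any(dead):
        warnings.warn(
            "degenerate Hebbian update (zero-norm row); leaving row unchanged",
            RuntimeWarning,
            stacklevel=3,
        )
        eps[dead] = weights[active][dead]
        norms[dead] = 1.0
    out = weights.copy()
    out[active] = eps / norms
    return out


def hebbian_step(
    weights: np.ndarray,
    x: np.ndarray,
    state: ActivationState,
    params: PoolParams,
) -> np.ndarray:
    """One Hebbian weight update from a computed activation state."""
    x = np.asarray(x, dtype=float)
    return _hebbian_update(np.asarray(weights, dtype=float), x, state.y,
                           state.eta, params)


def train_pool(
    dataset: Sequence[np.ndarray] | np.ndarray,
    params: PoolParams,
    schedule: TrainSchedule,
    seed: int,
    *,
    topology: GridTopology | None = None,
    h: float = 0.0,
    initial_weights: np.ndarray | None = None,
) -> TrainResult:
    """Train one pool on a stimulus set.

    Weights are initialized from the seed's ``init`` stream (unless
    ``initial_weights`` is given) and each epoch presents every stimulus once
    in a freshly shuffled order drawn from the ``shuffle`` stream. Stimuli
    that are identically zero are skipped — they carry no signal and would
    make the competition degenerate. The run is fully deterministic given
    ``(dataset, params, schedule, seed)``.

    With a ``topology``, outputs (and hence learning) include lateral
    excitation at gain ``h``; ``h = 0`` is bit-identical to the plain pool.
    """
    data = np.asarray(dataset, dtype=float)
    if data.ndim != 2 or data.shape[0] == 0:
        raise ValueError("dataset must be a non-empty (M, K) array")
    if topology is not None and topology.n_neurons != params.N:
        raise ValueError("topology size does not match pool size")
    if h < 0:
        raise ValueError("lateral gain h must be non-negative")

    if initial_weights is None:
        weights = init_weights(params, data.shape[1], child_rng(seed, "init"))
    else:
        weights = np.array(initial_weights, dtype=float)
        check_weight_matrix(weights)
    shuffle_rng = child_rng(seed, "shuffle")
    n_data = data.shape[0]
    perms = np.stack(
        [shuffle_rng.permutation(n_data) for _ in range(schedule.epochs)]
    ).astype(np.int64)

    if topology is not None and h > 0.0:
        nb_index, nb_counts = topology._index, topology._counts
        nb_index = nb_index.astype(np.int64)
        nb_counts = nb_counts.astype(np.int64)
    else:
        nb_index = np.zeros((0, 8), dtype=np.int64)
        nb_counts = np.zeros(0, dtype=np.int64)

    conv_tol = -1.0 if schedule.convergence_tol is None else schedule.convergence_tol
    (weights, epochs_run, deltas, winner_counts, max_norm_dev, max_winner_dev,
     dead_updates) = train_core(
        weights, data, perms, np.asarray(params.mu_table), params.kappa,
        min(params.avg_count, params.N - 1), params.clip_negative_y,
        nb_index, nb_counts, h, conv_tol,
    )
    if dead_updates:
        warnings.warn(
            f"{dead_updates} degenerate Hebbian updates (zero-norm rows) were "
            "skipped during training",
            RuntimeWarning, stacklevel=2,
        )
    result = TrainResult(
        weights=weights,
        epochs_run=int(epochs_run),
        max_norm_deviation=float(max_norm_dev),
        max_winner_output_deviation=float(max_winner_dev),
    )
    if schedule.record_history:
        result.mean_weight_change = [float(d) for d in deltas[:epochs_run]]
        for counts in winner_counts[:epochs_run]:
            p = counts / max(counts.sum(), 1)
            nz = p[p > 0]
            result.winner_entropy.append(float(-(nz * np.log2(nz)).sum()))
    return result


def frozen_state(
    weights: np.ndarray,
    x: np.ndarray,
    params: PoolParams,
    *,
    topology: GridTopology | None = None,
    h: float = 0.0,
) -> ActivationState:
    """Evaluate a trained pool on one stimulus with learning disabled."""
    gamma = compute_activation(weights, x)
    if topology is not None and h > 0.0:
        return lateral_pool_output(gamma, params, topology, h)
    return pool_output(gamma, params)
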