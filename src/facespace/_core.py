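"""Inner training loop: reference and accelerated implementations.

The per-presentation update (activation -> stable ranks -> graded inhibition
-> optional lateral excitation -> Hebbian step with renormalization) is
implemented twice with identical arithmetic: a plain-NumPy reference
(`train_core_py`) and a numba-compiled twin (`train_core_jit`) used by
default when numba is importable. The two paths agree to floating-point
rounding; a regression test pins their equivalence. Both return, besides the
trained weights, running diagnostics: per-epoch mean absolute weight change,
per-epoch winner counts, and the worst deviations of post-update row norms
from 1 and of the winner's inhibited output from 1.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

__all__ = ["train_core", "train_core_py", "HAVE_NUMBA"]


def train_core_py(
    weights: np.ndarray,
    data: np.ndarray,
    perms: np.ndarray,
    mu_table: np.ndarray,
    kappa: float,
    m_avg: int,
    clip_y: bool,
    nb_index: np.ndarray,
    nb_counts: np.ndarray,
    h: float,
    conv_tol: float,
):
    """Reference NumPy implementation of the epoch loop (see module docs).

    ``nb_counts`` of length 0 disables lateral excitation entirely;
    ``conv_tol < 0`` disables early stopping.
    """
    weights = weights.copy()
    n, _ = weights.shape
    n_epochs, m_data = perms.shape
    lateral = h > 0.0 and nb_counts.shape[0] > 0
    deltas = np.zeros(n_epochs)
    winner_counts = np.zeros((n_epochs, n), dtype=np.int64)
    max_norm_dev = 0.0
    max_winner_dev = 0.0
    dead_updates = 0
    epochs_run = 0

    for e in range(n_epochs):
        start = weights.copy()
        for t in range(m_data):
            x = data[perms[e, t]]
            gamma = weights @ x
            gamma_max = gamma.max()
            if gamma_max <= 0.0:
                continue
            order = np.argsort(-gamma, kind="stable")
            eta = np.empty(n, dtype=np.intp)
            eta[order] = np.arange(1, n + 1)
            cs = np.cumsum(gamma[order])
            gamma_av = np.where(eta <= m_avg, (cs[m_avg] - gamma) / m_avg,
                                cs[m_avg - 1] / m_avg)
            denom = gamma_max - kappa * gamma_av
            y = (gamma - kappa * gamma_av) / denom
            winner = order[0]
            max_winner_dev = max(max_winner_dev, abs(y[winner] - 1.0))
            winner_counts[e, winner] += 1
            if clip_y:
                y = np.maximum(y, 0.0)
            if lateral:
                padded = np.append(y, 0.0)
                y = y + h * padded[nb_index].sum(axis=1) / nb_counts
            mu = mu_table[eta - 1]
            active = mu > 0.0
            mu_a = mu[active, None]
            eps = mu_a * y[active, None] * x + (1.0 - mu_a) * weights[active]
            np.maximum(eps, 0.0, out=eps)
            norms = np.sqrt((eps * eps).sum(axis=1))
            dead = norms == 0.0
            if dead.any():
                dead_updates += int(dead.sum())
                eps[dead] = weights[active][dead]
                norms[dead] = 1.0
            rows = eps / norms[:, None]
            weights[active] = rows
            max_norm_dev = max(
                max_norm_dev,
                float(np.abs(np.sqrt((rows * rows).sum(axis=1)) - 1.0).max()),
            )
        epochs_run += 1
        deltas[e] = np.abs(weights - start).mean()
        if conv_tol >= 0.0 and deltas[e] < conv_tol:
            break
    return (weights, epochs_run, deltas, winner_counts, max_norm_dev,
            max_winner_dev, dead_updates)


if HAVE_NUMBA:

    @numba.njit(cache=True)
    def _jit_loop(weights, data, perms, mu_table, kappa, m_avg, clip_y,
                  nb_index, nb_counts, h, conv_tol):  # pragma: no cover
        n, k = weights.shape
        n_epochs, m_data = perms.shape
        lateral = h > 0.0 and nb_counts.shape[0] > 0
        deltas = np.zeros(n_epochs)
        winner_counts = np.zeros((n_epochs, n), dtype=np.int64)
        max_norm_dev = 0.0
        max_winner_dev = 0.0
        dead_updates = 0
        epochs_run = 0

        gamma = np.empty(n)
        eta = np.empty(n, dtype=np.int64)
        order = np.empty(n, dtype=np.int64)
        gamma_av = np.empty(n)
        y = np.empty(n)
        y_lat = np.empty(n)
        row = np.empty(k)
        start = np.empty((n, k))

        for e in range(n_epochs):
            start[:, :] = weights
            for t in range(m_data):
                x = data[perms[e, t]]
                gamma_max = -1.0
                for i in range(n):
                    s = 0.0
                    for j in range(k):
                        s += weights[i, j] * x[j]
                    gamma[i] = s
                    if s > gamma_max:
                        gamma_max = s
                if gamma_max <= 0.0:
                    continue
                # stable descending order: repeated selection of the largest
                # remaining activation, earliest index first on ties
                taken = np.zeros(n, dtype=numba.boolean)
                for pos in range(n):
                    best = -1
                    best_val = 0.0
                    for i in range(n):
                        if not taken[i] and (best == -1 or gamma[i] > best_val):
                            best = i
                            best_val = gamma[i]
                    taken[best] = True
                    order[pos] = best
                    eta[best] = pos + 1
                # prefix sums of the sorted activations
                cs_m_minus = 0.0
                cs_m = 0.0
                run = 0.0
                for pos in range(m_avg + 1):
                    run += gamma[order[pos]]
                    if pos == m_avg - 1:
                        cs_m_minus = run
                    if pos == m_avg:
                        cs_m = run
                for i in range(n):
                    if eta[i] <= m_avg:
                        gav = (cs_m - gamma[i]) / m_avg
                    else:
                        gav = cs_m_minus / m_avg
                    gamma_av[i] = gav
                    y[i] = (gamma[i] - kappa * gav) / (gamma_max - kappa * gav)
                winner = order[0]
                dev = abs(y[winner] - 1.0)
                if dev > max_winner_dev:
                    max_winner_dev = dev
                winner_counts[e, winner] += 1
                if clip_y:
                    for i in range(n):
                        if y[i] < 0.0:
                            y[i] = 0.0
                if lateral:
                    for i in range(n):
                        s = 0.0
                        for q in range(nb_counts[i]):
                            s += y[nb_index[i, q]]
                        y_lat[i] = y[i] + h * s / nb_counts[i]
                else:
                    for i in range(n):
                        y_lat[i] = y[i]
                for i in range(n):
                    mu = mu_table[eta[i] - 1]
                    if mu <= 0.0:
                        continue
                    coef = mu * y_lat[i]
                    keep = 1.0 - mu
                    ssq = 0.0
                    for j in range(k):
                        v = coef * x[j] + keep * weights[i, j]
                        if v < 0.0:
                            v = 0.0
                        row[j] = v
                        ssq += v * v
                    nrm = np.sqrt(ssq)
                    if nrm == 0.0:
                        dead_updates += 1  # degenerate: leave row unchanged
                        continue
                    ssq2 = 0.0
                    for j in range(k):
                        w = row[j] / nrm
                        weights[i, j] = w
                        ssq2 += w * w
                    d = abs(np.sqrt(ssq2) - 1.0)
                    if d > max_norm_dev:
                        max_norm_dev = d
            epochs_run += 1
            acc = 0.0
            for i in range(n):
                for j in range(k):
                    acc += abs(weights[i, j] - start[i, j])
            deltas[e] = acc / (n * k)
            if conv_tol >= 0.0 and deltas[e] < conv_tol:
                break
        return (weights, epochs_run, deltas, winner_counts, max_norm_dev,
                max_winner_dev, dead_updates)


def train_core(
    weights, data, perms, mu_table, kappa, m_avg, clip_y,
    nb_index, nb_counts, h, conv_tol,
):
    """Dispatch to the numba loop when available, else the NumPy reference."""
    if HAVE_NUMBA:
        return _jit_loop(
            weights.copy(), np.ascontiguousarray(data), perms, mu_table,
            float(kappa), int(m_avg), bool(clip_y),
            nb_index, nb_counts, float(h), float(conv_tol),
        )
    return train_core_py(
        weights, data, perms, mu_table, kappa, m_avg, clip_y,
        nb_index, nb_counts, h, conv_tol,
    )
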