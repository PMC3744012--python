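"""Unit and property tests for the competitive Hebbian kernel."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import facespace as fs
from facespace._core import HAVE_NUMBA, train_core, train_core_py
from facespace.engine import DegenerateInputError, check_weight_matrix


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "w_row, x, expected",
    [
        ((1, 0, 0), (1, 0, 0), 1.0),
        ((1, 0, 0), (0, 1, 0), 0.0),
        ((0.6, 0.8, 0), (0.5, 0.5, 0), 0.7),
    ],
)
def test_activation_is_inner_product(w_row, x, expected):
    gamma = fs.compute_activation(np.array([w_row], dtype=float), np.array(x, dtype=float))
    assert gamma[0] == pytest.approx(expected, abs=1e-12)


def test_activation_rejects_shape_mismatch():
    with pytest.raises(ValueError):
        fs.compute_activation(np.eye(3), np.ones(4))


@pytest.mark.parametrize(
    "gamma, expected",
    [
        ((0.9, 0.3, 0.6), (1, 3, 2)),
        ((0.5, 0.5), (1, 2)),  # tie -> lowest index gets the better rank
        ((0.1, 0.2, 0.3, 0.4), (4, 3, 2, 1)),
    ],
)
def test_rank_activations(gamma, expected):
    assert tuple(fs.rank_activations(np.array(gamma))) == expected


def test_learning_scale_endpoints_and_runner_up_ratio():
    params = fs.PoolParams(N=16, r=0.001, alpha=16.0)
    assert fs.learning_scale(1, params) == pytest.approx(0.001)
    assert fs.learning_scale(16, params) == 0.0
    # the runner-up learns at about one third the winner's rate
    ratio = fs.learning_scale(2, params) / fs.learning_scale(1, params)
    assert ratio == pytest.approx((14 / 15) ** 16, abs=1e-15)
    assert abs(ratio - 1 / 3) < 0.01 * (1 / 3) + 0.01  # within a percent of a third

    mu = fs.learning_scale(np.arange(1, 17), params)
    assert np.all(np.diff(mu) < 0)  # strictly decreasing in rank
    with pytest.raises(ValueError):
        fs.learning_scale(0, params)
    with pytest.raises(ValueError):
        fs.learning_scale(17, params)


def test_pool_output_hand_evaluated_example():
    params = fs.PoolParams(N=3, r=0.001, alpha=3.0, kappa=0.3, avg_count=10)
    state = fs.pool_output(np.array([0.9, 0.6, 0.3]), params)
    assert state.y == pytest.approx([1.0, 0.58333333333, 0.11111111111], abs=1e-9)
    assert state.gamma_max == 0.9
    assert tuple(state.eta) == (1, 2, 3)


def test_pool_output_kappa_zero_reduces_to_max_normalization():
    params = fs.PoolParams(N=4, r=0.001, alpha=4.0, kappa=0.0)
    gamma = np.array([0.2, 0.8, 0.4, 0.1])
    state = fs.pool_output(gamma, params)
    assert np.allclose(state.y, gamma / gamma.max())
    assert state.y[1] == 1.0


def test_pool_output_winner_is_exactly_one():
    rng = np.random.default_rng(0)
    params = fs.PoolParams(N=12, r=0.001, alpha=12.0)
    for _ in range(50):
        gamma = rng.random(12) + 1e-6
        state = fs.pool_output(gamma, params)
        assert state.y[np.argmax(gamma)] == 1.0


def test_pool_output_degenerate_input_raises():
    params = fs.PoolParams(N=3, r=0.001, alpha=3.0)
    with pytest.raises(DegenerateInputError):
        fs.pool_output(np.zeros(3), params)


# ---------------------------------------------------------------------------
# Hebbian update
# ---------------------------------------------------------------------------

def test_hebbian_step_rank_last_row_unchanged():
    params = fs.PoolParams(N=2, r=0.5, alpha=1.0, kappa=0.0)
    w = np.array([[1.0, 0.0], [0.0, 1.0]])
    x = np.array([1.0, 0.0])
    state = fs.pool_output(fs.compute_activation(w, x), params)
    new = fs.hebbian_step(w, x, state, params)
    # rank-2 neuron has mu = 0: bitwise unchanged
    assert new[1] is not w[1]
    assert np.array_equal(new[1], w[1])


def test_hebbian_step_full_replacement():
    # mu = 1 and y = 1 for the winner replaces its row by the (unit) input
    params = fs.PoolParams(N=2, r=1.0, alpha=1.0, kappa=0.0)
    w = np.array([[np.sqrt(0.5), np.sqrt(0.5)], [0.0, 1.0]])
    x = np.array([1.0, 0.0])
    state = fs.pool_output(fs.compute_activation(w, x), params)
    new = fs.hebbian_step(w, x, state, params)
    assert np.allclose(new[0], x, atol=1e-12)


def test_hebbian_step_hand_evaluated_mixture():
    # eps = 0.5*1*x + 0.5*w = (0.5, 0.5, 0) -> renormalized
    params = fs.PoolParams(N=2, r=0.5, alpha=1.0, kappa=0.0)
    w = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    x = np.array([0.0, 1.0, 0.0])
    gamma = fs.compute_activation(w, x)  # (0, 0) -> degenerate; drive manually
    state = fs.ActivationState(
        gamma=gamma, eta=np.array([1, 2]), gamma_max=1.0,
        gamma_av=np.zeros(2), y=np.array([1.0, 0.0]), y_base=np.array([1.0, 0.0]),
    )
    new = fs.hebbian_step(w, x, state, params)
    assert np.allclose(new[0], [np.sqrt(0.5), np.sqrt(0.5), 0.0], atol=1e-9)


def test_init_weights_unit_norm_positive_and_reproducible():
    params = fs.PoolParams(N=50, r=0.001, alpha=50.0)
    w1 = fs.init_weights(params, 3, seed=5)
    w2 = fs.init_weights(params, 3, seed=5)
    assert np.array_equal(w1, w2)
    assert np.all(w1 > 0)
    assert np.allclose(np.linalg.norm(w1, axis=1), 1.0, atol=1e-12)
    check_weight_matrix(w1)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _normalize_rows(a):
    return a / np.linalg.norm(a, axis=1, keepdims=True)


def _transcription_oracle(weights, data, order, params):
    """Independent straight-line transcription of the update equations.

    gamma = w . x; mu = r((N - eta)/(N - 1))^alpha; y = (gamma - k*gav) /
    (gmax - k*gav); eps = mu*y*x + (1 - mu)*w; w <- eps/|eps|, written as
    plainly as possible and independent of the engine's vectorized path.
    """
    w = np.array(weights, dtype=float)
    n = params.N
    for idx in order:
        x = data[idx]
        gamma = np.array([float(np.dot(w[i], x)) for i in range(n)])
        # stable ranks: highest gamma first, lowest index wins ties
        by_rank = sorted(range(n), key=lambda i: (-gamma[i], i))
        eta = {i: pos + 1 for pos, i in enumerate(by_rank)}
        m = min(params.avg_count, n - 1)
        new_w = w.copy()
        for i in range(n):
            others = sorted((gamma[j] for j in range(n) if j != i), reverse=True)
            gav = sum(others[:m]) / m
            y = (gamma[i] - params.kappa * gav) / (gamma.max() - params.kappa * gav)
            mu = params.r * ((n - eta[i]) / (n - 1)) ** params.alpha
            eps = mu * y * x + (1 - mu) * w[i]
            eps = np.maximum(eps, 0.0)
            if eta[i] < n:  # mu > 0
                new_w[i] = eps / np.sqrt(np.sum(eps * eps))
        w = new_w
    return w


def test_train_pool_matches_literal_transcription():
    """Five presentations on a 3-neuron, 3-input pool agree with an
    independent literal transcription of the model equations to 1e-12."""
    rng = np.random.default_rng(12)
    data = _normalize_rows(rng.random((5, 3)) + 0.05)
    params = fs.PoolParams(N=3, r=0.01, alpha=3.0)
    w0 = fs.init_weights(params, 3, seed=99)

    order = np.arange(5)
    expected = _transcription_oracle(w0, data, order, params)

    got = train_core(
        w0.copy(), data, order[None, :].astype(np.int64),
        np.asarray(params.mu_table), params.kappa, min(params.avg_count, 2),
        False, np.zeros((0, 8), np.int64), np.zeros(0, np.int64), 0.0, -1.0,
    )[0]
    assert np.max(np.abs(got - expected)) <= 1e-12


def test_train_pool_deterministic_and_convergent_on_repeated_stimulus():
    params = fs.PoolParams(N=3, r=0.05, alpha=3.0)
    x = np.array([0.6, 0.64, 0.48])
    x = x / np.linalg.norm(x)
    data = np.tile(x, (1, 1))
    r1 = fs.train_pool(data, params, fs.TrainSchedule(epochs=30), seed=4)
    r2 = fs.train_pool(data, params, fs.TrainSchedule(epochs=30), seed=4)
    assert np.array_equal(r1.weights, r2.weights)
    # the winner's weight vector is pulled toward the repeated stimulus
    sims = r1.weights @ x
    w0 = fs.init_weights(params, 3, seed=4)
    assert sims.max() > (w0 @ x).max()


def test_train_pool_rejects_empty_dataset():
    params = fs.PoolParams(N=3, r=0.01, alpha=3.0)
    with pytest.raises(ValueError):
        fs.train_pool(np.empty((0, 3)), params, fs.TrainSchedule(epochs=1), seed=0)


def test_train_pool_conservation_diagnostics():
    """Row norms stay at 1 (1e-9) and the winner's inhibited output at 1
    (1e-12) throughout training."""
    params = fs.PoolParams(N=16, r=0.001, alpha=16.0)
    spec = fs.PopulationSpec(center_azel=(45, 45), sd_azel=(10, 10),
                             count=200, label="s")
    points = fs.sample_face_space([spec], seed=2)
    res = fs.train_pool(points.points, params, fs.TrainSchedule(epochs=50), seed=2)
    assert res.max_norm_deviation < 1e-9
    assert res.max_winner_output_deviation < 1e-12
    check_weight_matrix(res.weights)


@pytest.mark.skipif(not HAVE_NUMBA, reason="accelerated path not available")
def test_reference_and_accelerated_loops_agree():
    rng = np.random.default_rng(3)
    data = _normalize_rows(rng.random((40, 5)) + 0.01)
    params = fs.PoolParams(N=9, r=0.01, alpha=9.0)
    w0 = fs.init_weights(params, 5, seed=8)
    perms = np.stack([np.random.default_rng(i).permutation(40) for i in range(10)])
    topo = fs.GridTopology(3, 3)
    nb_i = topo._index.astype(np.int64)
    nb_c = topo._counts.astype(np.int64)
    for h, nbi, nbc in [(0.0, np.zeros((0, 8), np.int64), np.zeros(0, np.int64)),
                        (0.7, nb_i, nb_c)]:
        args = (w0.copy(), data, perms.astype(np.int64), np.asarray(params.mu_table),
                params.kappa, 8, False, nbi, nbc, h, -1.0)
        w_py = train_core_py(*args)[0]
        w_jit = train_core(*args)[0]
        assert np.max(np.abs(w_py - w_jit)) < 1e-14


# ---------------------------------------------------------------------------
# lateral excitation
# ---------------------------------------------------------------------------

def test_lateral_h_zero_reproduces_plain_output():
    topo = fs.GridTopology(3, 3)
    params = fs.PoolParams(N=9, r=0.001, alpha=9.0)
    gamma = np.linspace(0.1, 1.0, 9)
    plain = fs.pool_output(gamma, params)
    lat = fs.lateral_pool_output(gamma, params, topo, h=0.0)
    assert np.array_equal(plain.y, lat.y)


def test_lateral_equal_base_outputs_double_at_h_one():
    # if every base output is v, each neighbor average is v, so output is 2v
    topo = fs.GridTopology(3, 3)
    params = fs.PoolParams(N=9, r=0.001, alpha=9.0, kappa=0.0)
    state = fs.lateral_pool_output(np.full(9, 0.5), params, topo, h=1.0)
    # base outputs are all 1 here (ties, kappa=0): outputs all equal 2
    assert np.allclose(state.y, 2.0 * state.y_base)


def test_lateral_rejects_negative_gain():
    topo = fs.GridTopology(3, 3)
    params = fs.PoolParams(N=9, r=0.001, alpha=9.0)
    with pytest.raises(ValueError):
        fs.lateral_pool_output(np.ones(9), params, topo, h=-0.1)


def test_h_zero_training_bitwise_equals_plain_training():
    spec = fs.PopulationSpec(center_azel=(45, 45), sd_azel=(8, 8), count=60, label="s")
    pts = fs.sample_face_space([spec], seed=1)
    topo = fs.GridTopology(3, 3)
    params = fs.PoolParams(N=9, r=0.01, alpha=9.0)
    plain = fs.train_pool(pts.points, params, fs.TrainSchedule(epochs=10), seed=1)
    lat = fs.train_pool(pts.points, params, fs.TrainSchedule(epochs=10), seed=1,
                        topology=topo, h=0.0)
    assert np.array_equal(plain.weights, lat.weights)


# ---------------------------------------------------------------------------
# grid topology
# ---------------------------------------------------------------------------

def test_grid_neighbor_counts():
    topo = fs.GridTopology(9, 9)
    counts = topo._counts.reshape(9, 9)
    assert counts[0, 0] == 3 and counts[0, 8] == 3 and counts[8, 0] == 3
    assert counts[0, 4] == 5 and counts[4, 0] == 5
    assert np.all(counts[1:-1, 1:-1] == 8)
    # corner neighborhood of a 3x3 grid has exactly 3 members
    small = fs.GridTopology(3, 3)
    assert len(small.neighbors(0)) == 3
    assert sorted(small.neighbors(0)) == [1, 3, 4]


def test_grid_neighbor_average_matches_direct_computation():
    topo = fs.GridTopology(4, 5)
    rng = np.random.default_rng(0)
    v = rng.random(20)
    avg = topo.neighbor_average(v)
    for i in range(20):
        nb = topo.neighbors(i)
        assert avg[i] == pytest.approx(v[nb].mean(), abs=1e-12)


# ---------------------------------------------------------------------------
# properties (hypothesis)
# ---------------------------------------------------------------------------

@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    gamma=hnp.arrays(
        np.float64, st.integers(2, 20),
        elements=st.floats(1e-3, 1.0, allow_nan=False),
    )
)
def test_winner_output_is_one_and_ranks_are_permutation(gamma):
    n = gamma.shape[0]
    params = fs.PoolParams(N=n, r=0.001, alpha=float(n))
    state = fs.pool_output(gamma, params)
    assert sorted(state.eta) == list(range(1, n + 1))
    assert state.y[np.argmax(gamma)] == 1.0
    assert state.gamma_max == gamma.max()


@settings(max_examples=20, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000), n=st.integers(2, 12))
def test_unit_norm_conservation_under_training(seed, n):
    rng = np.random.default_rng(seed)
    data = _normalize_rows(rng.random((15, 4)) + 0.01)
    params = fs.PoolParams(N=n, r=0.05, alpha=float(n))
    res = fs.train_pool(data, params, fs.TrainSchedule(epochs=3), seed=seed)
    assert res.max_norm_deviation < 1e-9
    assert np.all(res.weights >= 0)
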