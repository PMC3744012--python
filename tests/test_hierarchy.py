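"""Two-layer image hierarchy: front end, training, output analyses."""

import numpy as np
import pytest

import facespace as fs
from facespace.hierarchy import (
    N_POOLS,
    PATCH,
    WORKING_GRID,
    _layer1_outputs,
    extract_patches,
    layer1_response,
)


# ---------------------------------------------------------------------------
# front end
# ---------------------------------------------------------------------------

def test_preprocess_constant_image_maps_to_zeros():
    out = fs.preprocess_image(np.full((256, 256), 0.37))
    assert out.shape == (WORKING_GRID, WORKING_GRID)
    assert np.all(out == 0.0)


def test_preprocess_output_range(face_images):
    out = fs.preprocess_image(face_images[0])
    assert out.min() == 0.0
    assert out.max() == 1.0


def test_preprocess_point_response_is_radially_symmetric():
    # a 2x2 source centered on the image midpoint (127.5, 127.5), which is
    # also a block-averaging boundary, so both filters' isotropy survives
    # the downsampling symmetrically
    img = np.zeros((256, 256))
    img[127:129, 127:129] = 1.0
    out = fs.preprocess_image(img)
    assert np.max(np.abs(out - out.T)) < 1e-6
    assert np.max(np.abs(out - out[::-1, :])) < 1e-6
    assert np.max(np.abs(out - out[:, ::-1])) < 1e-6


def test_patches_tile_the_working_grid_exactly():
    rng = np.random.default_rng(0)
    grid = rng.random((WORKING_GRID, WORKING_GRID))
    patches = extract_patches(grid)
    assert patches.shape == (N_POOLS, PATCH * PATCH)
    rebuilt = np.empty_like(grid)
    for p in range(N_POOLS):
        a, b = divmod(p, 4)
        rebuilt[16 * a: 16 * a + 16, 16 * b: 16 * b + 16] = patches[p].reshape(16, 16)
    assert np.array_equal(rebuilt, grid)


# ---------------------------------------------------------------------------
# training and forward pass
# ---------------------------------------------------------------------------

def test_trained_hierarchy_shapes_and_norms(small_hierarchy):
    net = small_hierarchy
    assert net.layer1_weights.shape == (16, 9, 256)
    assert net.layer2_weights.shape == (5, 144)
    for pool in net.layer1_weights:
        assert np.allclose(np.linalg.norm(pool, axis=1), 1.0, atol=1e-9)
    assert np.allclose(np.linalg.norm(net.layer2_weights, axis=1), 1.0, atol=1e-9)


def test_hierarchy_training_is_deterministic(face_images):
    cfg = fs.HierarchyConfig(N2=5, seed=21, layer1_epochs=3, layer2_epochs=3)
    a = fs.train_hierarchy(face_images[:6], cfg)
    b = fs.train_hierarchy(face_images[:6], cfg)
    assert np.array_equal(a.layer1_weights, b.layer1_weights)
    assert np.array_equal(a.layer2_weights, b.layer2_weights)


def test_layer2_response_winner_normalized_and_repeatable(small_hierarchy, face_images):
    code1 = fs.layer2_response(small_hierarchy, face_images[0])
    code2 = fs.layer2_response(small_hierarchy, face_images[0])
    assert np.array_equal(code1.y2, code2.y2)
    assert code1.ranked_order == code2.ranked_order
    assert code1.y2.max() == 1.0
    assert code1.y2[code1.ranked_order[0]] == 1.0


def test_forward_pass_matches_straight_line_evaluation(small_hierarchy, face_images):
    """The library's layered forward pass equals a direct, independently
    written evaluation of the same equations to 1e-12."""
    net = small_hierarchy
    img = face_images[1]
    grid = fs.preprocess_image(img, net.config.front_end)
    p1 = net.config.layer1_params

    def plain_pool_y(gamma, kappa, avg_count):
        n = gamma.shape[0]
        m = min(avg_count, n - 1)
        y = np.empty(n)
        for i in range(n):
            others = np.sort(np.delete(gamma, i))[::-1]
            gav = others[:m].mean()
            y[i] = (gamma[i] - kappa * gav) / (gamma.max() - kappa * gav)
        return y

    code_parts = []
    for p in range(16):
        a, b = divmod(p, 4)
        patch = grid[16 * a: 16 * a + 16, 16 * b: 16 * b + 16].reshape(-1)
        gamma = net.layer1_weights[p] @ patch
        if gamma.max() <= 0:
            code_parts.append(np.zeros(9))
        else:
            code_parts.append(plain_pool_y(gamma, p1.kappa, p1.avg_count))
    y1 = np.concatenate(code_parts)
    gamma2 = net.layer2_weights @ y1
    y2 = plain_pool_y(gamma2, net.config.kappa, 10)

    code = fs.layer2_response(net, img)
    assert np.max(np.abs(code.y2 - y2)) <= 1e-12
    assert np.max(np.abs(layer1_response(net, img) - y1)) <= 1e-12


def test_silent_patch_produces_silent_pool(small_hierarchy):
    patches = np.zeros((16, 256))
    patches[0, :] = 0.5  # only pool 0 gets drive
    y = _layer1_outputs(patches, small_hierarchy.layer1_weights,
                        small_hierarchy.config.layer1_params)
    assert np.all(y[9:] == 0.0)
    assert y[:9].max() == 1.0


# ---------------------------------------------------------------------------
# output analyses
# ---------------------------------------------------------------------------

def _code(order, pop=None):
    n = len(order)
    y = np.empty(n)
    y[list(order)] = np.linspace(1, 0.1, n)
    return fs.OutputCode(y2=y, ranked_order=tuple(order), population=pop)


def test_unique_code_count_definition():
    codes = [_code((0, 1, 2)), _code((1, 0, 2)), _code((2, 1, 0))]
    assert fs.unique_code_count(codes)[0] == 3
    codes = [_code((0, 1, 2)), _code((0, 1, 2)), _code((2, 1, 0))]
    assert fs.unique_code_count(codes)[0] == 1  # shared codes are both non-unique


def test_unique_code_fractions_by_population():
    codes = [_code((0, 1, 2), "own"), _code((0, 1, 2), "own"),
             _code((1, 0, 2), "own"), _code((2, 1, 0), "other")]
    total, fractions = fs.unique_code_count(codes)
    assert total == 2
    assert fractions == {"other": 1.0, "own": pytest.approx(1 / 3)}


@pytest.mark.parametrize(
    "before, after, n, expected",
    [
        ((0, 1, 2, 3, 4), (0, 1, 2, 3, 4), 3, 1.0),
        ((0, 1, 2, 3, 4), (4, 3, 2, 1, 0), 2, 0.0),
        ((2, 5, 7, 0, 1, 3, 4, 6, 8, 9), (2, 7, 9, 0, 1, 3, 4, 5, 6, 8), 3, 2 / 3),
    ],
)
def test_topn_overlap(before, after, n, expected):
    a = _code(before)
    b = _code(after)
    assert fs.topn_overlap(a, b, n) == pytest.approx(expected)


def test_topn_overlap_rejects_bad_n():
    a = _code((0, 1, 2))
    with pytest.raises(ValueError):
        fs.topn_overlap(a, a, 0)
    with pytest.raises(ValueError):
        fs.topn_overlap(a, a, 4)


def test_cluster_outputs_separable_blobs_and_duplicates():
    rng = np.random.default_rng(5)
    blob_a = rng.normal(0.0, 0.05, size=(8, 6))
    blob_b = rng.normal(5.0, 0.05, size=(8, 6))
    codes = [fs.OutputCode(y2=v, ranked_order=tuple(np.argsort(-v)))
             for v in np.vstack([blob_a, blob_b])]
    labels, tree = fs.cluster_outputs(codes, k=2)
    assert len(set(labels[:8])) == 1
    assert len(set(labels[8:])) == 1
    assert labels[0] != labels[8]

    dup = [codes[0], codes[0], codes[5]]
    _, tree = fs.cluster_outputs(dup, k=2)
    assert tree[0, 2] == 0.0  # identical vectors merge first at zero height

    with pytest.raises(ValueError):
        fs.cluster_outputs(codes, k=len(codes) + 1)


def test_component_projection_properties():
    rng = np.random.default_rng(8)
    vectors = rng.random((12, 10))
    vectors[3] = vectors[2]  # duplicated code
    codes = [fs.OutputCode(y2=v, ranked_order=tuple(np.argsort(-v)))
             for v in vectors]
    proj = fs.component_projection(codes, n_components=4)
    assert proj.coordinates.shape == (12, 4)
    assert np.all(np.diff(proj.explained_variance) <= 1e-12)
    assert np.allclose(proj.coordinates[2], proj.coordinates[3], atol=1e-9)
    assert proj.winning_neuron[2] == proj.winning_neuron[3]


def test_holistic_test_table_layout(small_hierarchy, face_images):
    table = fs.holistic_test(small_hierarchy, face_images,
                             n_per_population=3, seed=0)
    assert set(table.columns) == {"population", "manipulation", "n", "overlap"}
    assert set(table["population"]) == {"own", "other"}
    assert set(table["manipulation"]) == {"delete", "exchange"}
    assert set(table["n"]) == {1, 2, 3, 4, 5}
    assert table["overlap"].between(0, 1).all()


def test_holistic_test_identity_control(small_hierarchy, face_images):
    # an unmanipulated stimulus reproduces its own code exactly: overlap 1
    code = fs.layer2_response(small_hierarchy, face_images[0])
    again = fs.layer2_response(small_hierarchy, face_images[0])
    for n in range(1, 6):
        assert fs.topn_overlap(code, again, n) == 1.0


def test_holistic_test_warns_on_small_population(small_hierarchy, face_images):
    with pytest.warns(RuntimeWarning):
        fs.holistic_test(small_hierarchy, face_images, n_per_population=20,
                         seed=0)


def test_unique_codes_grow_with_output_count(face_images):
    """Larger output pools can individuate more stimuli: the number of unique
    ranked codes is non-decreasing in N2 on a fixed stimulus set."""
    counts = []
    for n2 in (5, 10, 25):
        cfg = fs.HierarchyConfig(N2=n2, seed=31, layer1_epochs=10,
                                 layer2_epochs=30)
        net = fs.train_hierarchy(face_images, cfg)
        codes = [fs.layer2_response(net, im) for im in face_images]
        counts.append(fs.unique_code_count(codes)[0])
    assert counts[0] <= counts[1] <= counts[2]
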