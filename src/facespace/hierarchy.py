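"""Two-layer competitive hierarchy trained on face images.

The front end mimics early visual filtering: a Laplacian-of-Gaussian edge
detector followed by Gaussian smoothing (s.d. 5 px), amplitude-normalized to
[0, 1] and block-averaged onto a 64 x 64 working grid. Layer 1 is a 4 x 4
grid of independent inhibitory pools, each of 9 neurons, and each seeing only
its own 16 x 16-pixel patch of the working grid. Layer 2 is a single fully
connected pool of ``N2`` neurons reading the concatenated 144-long vector of
layer-1 outputs.

Training is phased: layer 1 self-organizes first (100 epochs, rank exponent
equal to the pool size), then layer 2 learns on the frozen layer-1 code
(300 epochs, rank exponent 1). Four read-outs quantify what the trained
network represents: unique ranked-order codes, Ward-linkage clustering of the
output vectors, projection onto leading variance axes, and the stability of
the top-n most active neurons under lower-half image manipulations (the
holistic-sensitivity probe).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter, gaussian_laplace
from sklearn.decomposition import PCA

from ._rand import child_rng, child_seed
from .engine import PoolParams, TrainSchedule, pool_output, train_pool
from .synth import SyntheticFaceImage, make_manipulated

__all__ = [
    "FrontEndConfig",
    "HierarchyConfig",
    "TrainedHierarchy",
    "OutputCode",
    "preprocess_image",
    "extract_patches",
    "train_hierarchy",
    "layer1_response",
    "layer2_response",
    "unique_code_count",
    "cluster_outputs",
    "component_projection",
    "topn_overlap",
    "holistic_test",
]

WORKING_GRID = 64
POOL_GRID = 4  # 4 x 4 arrangement of layer-1 pools
PATCH = WORKING_GRID // POOL_GRID  # 16 x 16 pixel patches
N_POOLS = POOL_GRID * POOL_GRID


@dataclass(frozen=True)
class FrontEndConfig:
    """Edge-detection front end: LoG scale and output smoothing."""

    log_sigma: float = 2.0
    smooth_sigma: float = 5.0


@dataclass(frozen=True)
class HierarchyConfig:
    """Architecture and training schedule of the two-layer network."""

    N1: int = 9  # neurons per layer-1 pool
    N2: int = 10  # layer-2 output neurons
    r: float = 0.001
    kappa: float = 0.3
    layer1_epochs: int = 100
    layer2_epochs: int = 300
    seed: int = 0
    front_end: FrontEndConfig = field(default_factory=FrontEndConfig)

    @property
    def layer1_params(self) -> PoolParams:
        # rank exponent equal to the pool size, as in the face-space model
        return PoolParams(N=self.N1, r=self.r, alpha=float(self.N1),
                          kappa=self.kappa)

    @property
    def layer2_params(self) -> PoolParams:
        # a flat rank exponent spreads learning across the output pool
        return PoolParams(N=self.N2, r=self.r, alpha=1.0, kappa=self.kappa)


@dataclass
class TrainedHierarchy:
    """Frozen weights of both layers plus the configuration that made them."""

    layer1_weights: np.ndarray  # (16, N1, 256)
    layer2_weights: np.ndarray  # (N2, 16 * N1)
    config: HierarchyConfig


@dataclass
class OutputCode:
    """Layer-2 output vector and its ranked order for one stimulus."""

    y2: np.ndarray
    ranked_order: tuple[int, ...]  # neuron indices, most active first
    stimulus_id: int | None = None
    population: str | None = None


def preprocess_image(
    img: SyntheticFaceImage | np.ndarray, cfg: FrontEndConfig = FrontEndConfig()
) -> np.ndarray:
    """Edge-based 64 x 64 representation of a 256 x 256 image in [0, 1].

    Pipeline: Laplacian of Gaussian at ``log_sigma`` -> Gaussian smoothing at
    ``smooth_sigma`` -> 4 x 4 block averaging down to the working grid ->
    per-image min-max rescale to [0, 1]. A constant input has no edges and
    maps to all zeros.

    Because the signed filter response is rescaled to [0, 1], edge-free image
    regions sit at a mid-level pedestal rather than at zero. This matters for
    the holistic manipulations: a blanked lower half drives its pools with a
    flat, face-independent input whose inhibited outputs are near-uniform —
    a mild perturbation of the code — whereas another face's lower half
    injects structured evidence for the wrong identity.
    """
    pixels = img.pixels if isinstance(img, SyntheticFaceImage) else np.asarray(img)
    if pixels.shape != (256, 256):
        raise ValueError("expected a 256 x 256 image")
    out = gaussian_laplace(pixels.astype(float), sigma=cfg.log_sigma)
    out = gaussian_filter(out, sigma=cfg.smooth_sigma)
    block = 256 // WORKING_GRID
    out = out.reshape(WORKING_GRID, block, WORKING_GRID, block).mean(axis=(1, 3))
    lo, hi = out.min(), out.max()
    if hi - lo < 1e-12:
        return np.zeros_like(out)
    return (out - lo) / (hi - lo)


def extract_patches(grid: np.ndarray) -> np.ndarray:
    """(16, 256) array of flattened 16 x 16 patches tiling the working grid.

    Pool ``(a, b)`` (row-major) sees rows ``16a:16a+16`` and columns
    ``16b:16b+16``; the patches tile the grid exactly with no overlap.
    """
    if grid.shape != (WORKING_GRID, WORKING_GRID):
        raise ValueError("expected the 64 x 64 working grid")
    tiles = grid.reshape(POOL_GRID, PATCH, POOL_GRID, PATCH)
    return tiles.transpose(0, 2, 1, 3).reshape(N_POOLS, PATCH * PATCH)


def _layer1_outputs(
    patches: np.ndarray, layer1_weights: np.ndarray, params: PoolParams
) -> np.ndarray:
    """Concatenated inhibited outputs of all 16 pools for one stimulus.

    A pool whose patch carries no signal (all-zero activations) emits zeros.
    """
    ys = np.empty((N_POOLS, params.N))
    for p in range(N_POOLS):
        gamma = layer1_weights[p] @ patches[p]
        if gamma.max() <= 0.0:
            ys[p] = 0.0
        else:
            ys[p] = pool_output(gamma, params).y
    return ys.reshape(-1)


def train_hierarchy(
    images: list[SyntheticFaceImage], cfg: HierarchyConfig
) -> TrainedHierarchy:
    """Phased training of the full hierarchy on an image set.

    Phase 1 trains the 16 layer-1 pools independently on their own patches
    while layer 2 is frozen; phase 2 trains layer 2 on the concatenated
    layer-1 output vectors of the now-frozen layer 1. Deterministic given
    ``(images, cfg)``.
    """
    if not images:
        raise ValueError("image list must be non-empty")
    grids = np.array([preprocess_image(im, cfg.front_end) for im in images])
    patches = np.array([extract_patches(g) for g in grids])  # (M, 16, 256)

    p1 = cfg.layer1_params
    sched1 = TrainSchedule(epochs=cfg.layer1_epochs)
    layer1 = np.empty((N_POOLS, cfg.N1, PATCH * PATCH))
    for p in range(N_POOLS):
        res = train_pool(
            patches[:, p, :], p1, sched1,
            seed=int(child_seed(cfg.seed, "layer1", p).generate_state(1)[0] >> 1),
        )
        layer1[p] = res.weights

    codes = np.array([_layer1_outputs(pt, layer1, p1) for pt in patches])
    res2 = train_pool(
        codes, cfg.layer2_params, TrainSchedule(epochs=cfg.layer2_epochs),
        seed=int(child_seed(cfg.seed, "layer2").generate_state(1)[0] >> 1),
    )
    return TrainedHierarchy(layer1_weights=layer1, layer2_weights=res2.weights,
                            config=cfg)


def layer1_response(net: TrainedHierarchy, img: SyntheticFaceImage) -> np.ndarray:
    """Frozen layer-1 code (length 16 * N1) for one image."""
    grid = preprocess_image(img, net.config.front_end)
    return _layer1_outputs(extract_patches(grid), net.layer1_weights,
                           net.config.layer1_params)


def layer2_response(net: TrainedHierarchy, img: SyntheticFaceImage) -> OutputCode:
    """Full frozen forward pass; ranked order ties go to the lowest index."""
    code = layer1_response(net, img)
    gamma = net.layer2_weights @ code
    y2 = pool_output(gamma, net.config.layer2_params).y
    order = tuple(int(i) for i in np.argsort(-y2, kind="stable"))
    return OutputCode(
        y2=y2, ranked_order=order,
        stimulus_id=getattr(img, "face_id", None),
        population=getattr(img, "population", None),
    )


def unique_code_count(codes: list[OutputCode]) -> tuple[int, dict[str, float]]:
    """How many stimuli evoke a ranked order shared by no other stimulus.

    Returns the total count and, for every population present, the fraction
    of its members with a unique code.
    """
    if len(codes) < 2:
        raise ValueError("need at least two codes")
    from collections import Counter

    tally = Counter(c.ranked_order for c in codes)
    unique = [tally[c.ranked_order] == 1 for c in codes]
    n_unique = int(sum(unique))
    fractions: dict[str, float] = {}
    pops = {c.population for c in codes if c.population is not None}
    for pop in sorted(pops):
        members = [u for c, u in zip(codes, unique) if c.population == pop]
        fractions[pop] = sum(members) / len(members)
    return n_unique, fractions


def cluster_outputs(
    codes: list[OutputCode], k: int = 6
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering of output vectors (Ward, Euclidean).

    Returns ``(labels, linkage_matrix)`` with the tree cut at ``k`` clusters;
    the full merge tree supports dendrogram rendering.
    """
    if k > len(codes):
        raise ValueError("k may not exceed the number of codes")
    y = np.array([c.y2 for c in codes])
    tree = linkage(y, method="ward", metric="euclidean")
    labels = fcluster(tree, t=k, criterion="maxclust")
    return labels, tree


@dataclass
class ComponentProjection:
    coordinates: np.ndarray  # (M, n_components)
    explained_variance: np.ndarray
    winning_neuron: np.ndarray  # (M,) winning layer-2 neuron per code


def component_projection(
    codes: list[OutputCode], n_components: int = 4
) -> ComponentProjection:
    """Mean-centered projection of output vectors onto leading variance axes,
    with each code tagged by its winning output neuron for region overlays."""
    if len(codes) < 3:
        raise ValueError("need at least three codes")
    y = np.array([c.y2 for c in codes])
    n_components = min(n_components, y.shape[0], y.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(y)
    winners = np.array([c.ranked_order[0] for c in codes])
    return ComponentProjection(
        coordinates=coords,
        explained_variance=pca.explained_variance_,
        winning_neuron=winners,
    )


def topn_overlap(before: OutputCode, after: OutputCode, n: int) -> float:
    """Fraction of the top-n most active neurons shared before and after a
    manipulation (1.0 = identical active set)."""
    if not 1 <= n <= len(before.ranked_order):
        raise ValueError("n must lie in 1..N2")
    a = set(before.ranked_order[:n])
    b = set(after.ranked_order[:n])
    return len(a & b) / n


def holistic_test(
    net: TrainedHierarchy,
    images: list[SyntheticFaceImage],
    n_per_population: int = 7,
    manipulations: tuple[str, ...] = ("delete", "exchange"),
    n_range: tuple[int, ...] = (1, 2, 3, 4, 5),
    seed: int = 0,
) -> pd.DataFrame:
    """Top-n code stability under lower-half manipulations, by population.

    For each population, ``n_per_population`` faces are sampled (seeded);
    each is manipulated and the mean top-n overlap between the original and
    manipulated codes is tabulated per (population, manipulation, n) cell.
    Exchange partners are drawn from the same population and are never the
    face itself.
    """
    rng = child_rng(seed, "holistic")
    rows = []
    populations = sorted({im.population for im in images})
    for pop in populations:
        members = [im for im in images if im.population == pop]
        if len(members) < n_per_population:
            warnings.warn(
                f"population {pop!r} has only {len(members)} faces; using all",
                RuntimeWarning, stacklevel=2,
            )
            chosen = list(members)
        else:
            idx = rng.choice(len(members), size=n_per_population, replace=False)
            chosen = [members[i] for i in idx]
        for face in chosen:
            base_code = layer2_response(net, face)
            for kind in manipulations:
                partner = None
                if kind == "exchange":
                    others = [im for im in members if im is not face]
                    partner = others[int(rng.integers(len(others)))]
                manip = make_manipulated(face, partner, kind)
                manip_code = layer2_response(net, manip)
                for n in n_range:
                    rows.append(
                        {
                            "population": pop,
                            "manipulation": kind,
                            "n": n,
                            "face_id": face.face_id,
                            "overlap": topn_overlap(base_code, manip_code, n),
                        }
                    )
    detail = pd.DataFrame(rows)
    return (
        detail.groupby(["population", "manipulation", "n"], as_index=False)["overlap"]
        .mean()
    )
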