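"""Synthetic stimuli for all experiments.

Two families of inputs are generated here:

* **Face-space point clouds** — labeled exemplars on the positive octant of
  the unit sphere, sampled as independent normals in the (azimuth, elevation)
  chart and mapped to unit vectors. These drive the spherical face-space and
  cortical-map experiments.

* **Parametric face images** — 256 x 256 grayscale renderings controlled by
  eight real-valued feature parameters (head width/height, eye separation,
  eye size, nose length, mouth width, mouth position, brow height). Two
  populations ("own" and "other") are drawn from multivariate normals whose
  centers differ by a configurable shift along several feature dimensions,
  emulating exposure to a familiar and an unfamiliar group of faces. The
  renderer keeps all upper-face features strictly in rows 0-127 and the
  mouth strictly in rows 128-255 so that half-image manipulations (delete /
  exchange / offset of the lower half) cleanly separate the features.

The renderer is deliberately schematic: the phenomena exercised downstream
are about exposure statistics, not photorealism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from ._rand import child_rng
from .geometry import azel_to_unit

__all__ = [
    "ConfigurationError",
    "PopulationSpec",
    "FacePointSet",
    "FaceParams",
    "SyntheticFaceImage",
    "sample_face_space",
    "render_face",
    "sample_face_population",
    "make_manipulated",
    "save_image",
    "load_image",
]

RESOLUTION = 256
HALF_ROW = 128  # upper/lower split of the image
BACKGROUND = 0.5  # mid-gray so deleting a half adds no strong new edges


class ConfigurationError(ValueError):
    """A generator spec is inconsistent with its constraints."""


# ---------------------------------------------------------------------------
# face-space point clouds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """Normal cluster of exemplars in the (azimuth, elevation) chart."""

    center_azel: tuple[float, float]
    sd_azel: tuple[float, float]
    count: int
    label: str

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be positive")
        if min(self.sd_azel) <= 0:
            raise ValueError("standard deviations must be positive")


@dataclass
class FacePointSet:
    """Labeled exemplars on the positive octant of the unit sphere."""

    points: np.ndarray  # (M, 3), unit rows, non-negative entries
    labels: np.ndarray  # (M,) category labels
    azel: np.ndarray  # (M, 2) degrees

    def __len__(self) -> int:
        return self.points.shape[0]

    @classmethod
    def from_azel(cls, azel: np.ndarray, labels) -> "FacePointSet":
        azel = np.asarray(azel, dtype=float)
        return cls(points=azel_to_unit(azel), labels=np.asarray(labels),
                   azel=azel)

    def subset(self, label) -> "FacePointSet":
        mask = self.labels == label
        return FacePointSet(self.points[mask], self.labels[mask],
                            self.azel[mask])

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.points, columns=["x", "y", "z"])
        df[["azimuth", "elevation"]] = self.azel
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FacePointSet":
        df = pd.read_csv(path)
        return cls(
            points=df[["x", "y", "z"]].to_numpy(),
            labels=df["label"].to_numpy(),
            azel=df[["azimuth", "elevation"]].to_numpy(),
        )


def sample_face_space(specs: Sequence[PopulationSpec], seed: int) -> FacePointSet:
    """Sample labeled exemplar clouds on the sphere octant.

    Each spec's points have azimuth and elevation drawn from independent
    normals and are rejection-resampled to stay inside the chart square
    [0, 90] x [0, 90] (the positive octant). A spec whose distribution puts
    most of its mass outside the octant (more than half of all draws
    rejected) raises :class:`ConfigurationError`.
    """
    if not specs:
        raise ValueError("at least one population spec is required")
    all_azel, all_labels = [], []
    for i, spec in enumerate(specs):
        rng = child_rng(seed, "facespace", i, spec.label)
        accepted: list[np.ndarray] = []
        n_accepted = drawn = 0
        while n_accepted < spec.count:
            batch = max(spec.count - n_accepted, 32)
            az = rng.normal(spec.center_azel[0], spec.sd_azel[0], batch)
            el = rng.normal(spec.center_azel[1], spec.sd_azel[1], batch)
            ok = (az >= 0) & (az <= 90) & (el >= 0) & (el <= 90)
            drawn += batch
            kept = np.column_stack([az[ok], el[ok]])
            accepted.append(kept)
            n_accepted += kept.shape[0]
            if drawn >= max(2 * spec.count, 64) and n_accepted < drawn / 2:
                raise ConfigurationError(
                    f"population {spec.label!r} lies mostly outside the "
                    f"positive octant ({drawn - n_accepted}/{drawn} draws rejected)"
                )
        azel = np.concatenate(accepted)[: spec.count]
        all_azel.append(azel)
        all_labels.append(np.full(spec.count, spec.label, dtype=object))
    azel = np.concatenate(all_azel)
    labels = np.concatenate(all_labels)
    return FacePointSet.from_azel(azel, labels)


# ---------------------------------------------------------------------------
# parametric face images
# ---------------------------------------------------------------------------

# (default, sd, low, high) per feature parameter, units: pixels on the
# 256-grid except where noted
_PARAM_TABLE = {
    "head_width": (88.0, 6.0, 58.0, 112.0),  # ellipse semi-axis
    "head_height": (104.0, 5.0, 86.0, 122.0),  # ellipse semi-axis
    "eye_separation": (30.0, 5.0, 8.0, 50.0),  # half distance between eyes
    "eye_size": (6.5, 1.0, 3.5, 9.5),  # Gaussian blob s.d.
    "nose_length": (26.0, 5.0, 12.0, 42.0),
    "mouth_width": (27.0, 10.0, 8.0, 48.0),  # half width
    "mouth_row": (172.0, 15.0, 136.0, 208.0),  # vertical position, lower half
    "brow_height": (68.0, 5.0, 50.0, 92.0),  # brow row, upper half
}

PARAM_NAMES = tuple(_PARAM_TABLE)


@dataclass(frozen=True)
class FaceParams:
    """Real-valued face feature parameters (see module docstring)."""

    head_width: float = _PARAM_TABLE["head_width"][0]
    head_height: float = _PARAM_TABLE["head_height"][0]
    eye_separation: float = _PARAM_TABLE["eye_separation"][0]
    eye_size: float = _PARAM_TABLE["eye_size"][0]
    nose_length: float = _PARAM_TABLE["nose_length"][0]
    mouth_width: float = _PARAM_TABLE["mouth_width"][0]
    mouth_row: float = _PARAM_TABLE["mouth_row"][0]
    brow_height: float = _PARAM_TABLE["brow_height"][0]

    def __post_init__(self) -> None:
        for f in fields(self):
            _, _, lo, hi = _PARAM_TABLE[f.name]
            v = getattr(self, f.name)
            if not lo <= v <= hi:
                raise ValueError(
                    f"{f.name}={v} outside the renderer's valid range [{lo}, {hi}]"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, values) -> "FaceParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))


@dataclass
class SyntheticFaceImage:
    """Rendered grayscale face with its population label and parameters."""

    pixels: np.ndarray  # (256, 256) in [0, 1]
    population: str
    feature_params: FaceParams
    jitter_seed: int = 0
    face_id: int | None = None


def _ridge(dist: np.ndarray, width: float) -> np.ndarray:
    """Smooth unit-height profile that decays over ``width`` pixels."""
    return np.exp(-0.5 * (dist / width) ** 2)


def render_face(params: FaceParams, jitter_seed: int = 0) -> SyntheticFaceImage:
    """Render a schematic 256 x 256 grayscale face.

    Deterministic given ``(params, jitter_seed)``. Upper-face features (brows,
    eyes, nose) are confined to rows 0-127 and the mouth to rows 128-255;
    features are drawn with smooth Gaussian intensity profiles so that an
    edge-detecting front end sees gradual, informative gradients rather than
    binary steps.
    """
    rows, cols = np.mgrid[0:RESOLUTION, 0:RESOLUTION].astype(float)
    cx = cy = RESOLUTION / 2.0
    img = np.full((RESOLUTION, RESOLUTION), BACKGROUND)

    # head: dark elliptical outline; the interior stays at the background
    # level so that blanking a half-image to the background introduces no
    # spurious edge along the cut line itself. The outline fades below the
    # jaw, as contour contrast does on real faces (chin merging into neck).
    f = ((cols - cx) / params.head_width) ** 2 + ((rows - cy) / params.head_height) ** 2
    outline_gain = 0.08 + 0.22 / (1.0 + np.exp((rows - 185.0) / 8.0))
    img -= outline_gain * _ridge(f - 1.0, 0.06)

    inside = 1.0 / (1.0 + np.exp((f - 1.0) * 10.0))  # soft head-interior mask

    upper = np.zeros_like(img)
    # hair cap: dark region from the head top down to a hairline tied to the
    # brows; its lower edge is a strong, identity-bearing horizontal contour
    hairline = params.brow_height - 14.0
    hair = inside / (1.0 + np.exp((rows - hairline) / 3.0))
    upper -= 0.30 * hair
    eye_row = params.brow_height + 16.0
    for sign in (-1.0, 1.0):
        ex = cx + sign * params.eye_separation
        d2 = (cols - ex) ** 2 + (rows - eye_row) ** 2
        upper -= 0.40 * np.exp(-0.5 * d2 / params.eye_size**2)
        # brow: short horizontal bar above each eye
        brow = _ridge(rows - params.brow_height, 2.5) * _ridge(
            cols - ex, params.eye_size * 1.6
        )
        upper -= 0.25 * brow
    # nose: vertical wedge widening toward its base, ending above the midline
    nose_base = 124.0
    nose_top = nose_base - params.nose_length
    along = np.clip((rows - nose_top) / params.nose_length, 0.0, 1.0)
    nose_width = 1.5 + 2.5 * along
    in_rows = _ridge(rows - np.clip(rows, nose_top, nose_base), 1.5)
    upper -= 0.28 * in_rows * _ridge(cols - cx, nose_width)
    upper[HALF_ROW:, :] = 0.0  # upper-face features end at the midline

    lower = np.zeros_like(img)
    mouth_cols = 1.0 / (1.0 + np.exp((np.abs(cols - cx) - params.mouth_width) / 2.0))
    lower -= 0.40 * _ridge(rows - params.mouth_row, 3.0) * mouth_cols
    # cheek highlights flanking the mouth
    for sign in (-1.0, 1.0):
        chx = cx + sign * (params.mouth_width + 22.0)
        d2 = (cols - chx) ** 2 + (rows - (params.mouth_row - 8.0)) ** 2
        lower += 0.08 * np.exp(-0.5 * d2 / 12.0**2)
    lower *= inside
    lower[:HALF_ROW, :] = 0.0  # lower features never cross the midline

    img += upper + lower
    # faint smooth texture so flat regions are not perfectly constant;
    # kept well below feature edge energy so codes reflect features, not grain
    noise = child_rng(jitter_seed, "texture").standard_normal(img.shape)
    img += 0.002 * gaussian_filter(noise, sigma=4.0)
    np.clip(img, 0.0, 1.0, out=img)
    return SyntheticFaceImage(pixels=img, population="unlabeled",
                              feature_params=params, jitter_seed=jitter_seed)


# default between-population shift, in units of the per-dimension s.d.
# Concentrated on upper-face geometry (as with real facial morphology
# differences between populations), so population identity survives
# lower-half manipulations.
DEFAULT_POPULATION_SHIFT = {
    "eye_separation": -4.0,
    "brow_height": 4.0,
    "head_width": -4.0,
}

# individuals are distinct people: any two sampled faces of one population
# are at least this far apart in s.d.-normalized parameter space
DEFAULT_MIN_SEPARATION = 1.5


def sample_face_population(
    n_own: int,
    n_other: int,
    seed: int,
    shift_sd: dict[str, float] | None = None,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> list[SyntheticFaceImage]:
    """Draw and render two face populations with a separable mean shift.

    Feature parameters for the "own" population are drawn from independent
    normals at the renderer defaults; the "other" population shares the
    covariance but its center is displaced by ``shift_sd[dim]`` standard
    deviations along each listed dimension (default: 4 s.d. on eye
    separation, brow height and head width), which makes the two populations
    linearly separable in parameter space. Out-of-range draws are clipped to
    the renderer's valid box.

    Because the populations emulate sets of distinct people, draws are
    rejection-resampled so that any two faces of one population are at least
    ``min_separation`` s.d.-normalized parameter-space units apart — a
    normal cloud would otherwise occasionally produce near-duplicate
    individuals.
    """
    if n_own < 1 or n_other < 1:
        raise ValueError("both population counts must be >= 1")
    shift_sd = DEFAULT_POPULATION_SHIFT if shift_sd is None else shift_sd
    rng = child_rng(seed, "faces")
    images: list[SyntheticFaceImage] = []
    face_id = 0
    for population, n in (("own", n_own), ("other", n_other)):
        accepted: list[np.ndarray] = []
        attempts = 0
        while len(accepted) < n:
            attempts += 1
            if attempts > 200 * n:
                raise ConfigurationError(
                    "cannot place faces at the requested minimum separation"
                )
            values = {}
            z = np.empty(len(PARAM_NAMES))
            for d, name in enumerate(PARAM_NAMES):
                mean, sd, lo, hi = _PARAM_TABLE[name]
                if population == "other":
                    mean = mean + shift_sd.get(name, 0.0) * sd
                v = float(np.clip(rng.normal(mean, sd), lo, hi))
                values[name] = v
                z[d] = (v - mean) / sd
            if any(np.linalg.norm(z - a) < min_separation for a in accepted):
                continue
            accepted.append(z)
            jitter = int(rng.integers(0, 2**31 - 1))
            img = render_face(FaceParams(**values), jitter_seed=jitter)
            img.population = population
            img.face_id = face_id
            images.append(img)
            face_id += 1
    return images


ManipulationKind = Literal["delete", "exchange", "offset"]


def make_manipulated(
    a: SyntheticFaceImage,
    b: SyntheticFaceImage | None,
    kind: ManipulationKind,
    offset_px: int = 32,
) -> SyntheticFaceImage:
    """Lower-half image manipulations probing holistic sensitivity.

    ``delete`` blanks rows 128-255 to the background gray; ``exchange``
    replaces them with the lower half of face ``b``; ``offset`` shifts them
    horizontally by ``offset_px`` pixels, filling vacated columns with the
    background. The upper half is always untouched.
    """
    pixels = a.pixels.copy()
    if kind == "delete":
        pixels[HALF_ROW:, :] = BACKGROUND
    elif kind == "exchange":
        if b is None:
            raise ValueError("exchange requires a second face")
        if b.pixels.shape != a.pixels.shape:
            raise ValueError("images must share the same resolution")
        pixels[HALF_ROW:, :] = b.pixels[HALF_ROW:, :]
    elif kind == "offset":
        lower = np.full_like(pixels[HALF_ROW:, :], BACKGROUND)
        if offset_px >= 0:
            lower[:, offset_px:] = a.pixels[HALF_ROW:, : RESOLUTION - offset_px]
        else:
            lower[:, :offset_px] = a.pixels[HALF_ROW:, -offset_px:]
        pixels[HALF_ROW:, :] = lower
    else:
        raise ValueError(f"unknown manipulation kind {kind!r}")
    return replace_image(a, pixels)


def replace_image(a: SyntheticFaceImage, pixels: np.ndarray) -> SyntheticFaceImage:
    return SyntheticFaceImage(
        pixels=pixels, population=a.population,
        feature_params=a.feature_params, jitter_seed=a.jitter_seed,
        face_id=a.face_id,
    )


# ---------------------------------------------------------------------------
# image I/O: 8-bit grayscale PNG + JSON sidecar
# ---------------------------------------------------------------------------

def save_image(img: SyntheticFaceImage, path) -> None:
    path = Path(path)
    arr = np.round(img.pixels * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
    sidecar = {
        "population": img.population,
        "feature_params": dict(zip(PARAM_NAMES, img.feature_params.as_array().tolist())),
        "jitter_seed": img.jitter_seed,
        "face_id": img.face_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_image(path) -> SyntheticFaceImage:
    path = Path(path)
    arr = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
    meta = json.loads(path.with_suffix(".json").read_text())
    return SyntheticFaceImage(
        pixels=arr,
        population=meta["population"],
        feature_params=FaceParams(**meta["feature_params"]),
        jitter_seed=meta.get("jitter_seed", 0),
        face_id=meta.get("face_id"),
    )
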