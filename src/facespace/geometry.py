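"""Azimuth/elevation chart of the positive octant of the unit sphere.

Face-space stimuli and classifier weight vectors are unit 3-vectors with
non-negative entries. Because they carry only two degrees of freedom they are
plotted and analyzed in a flat (azimuth, elevation) chart, both in degrees and
both in [0, 90] on the positive octant:

    azimuth   = atan2(v2, v1)
    elevation = arcsin(v3)
    v = (cos el cos az, cos el sin az, sin el)

At the pole (elevation 90) azimuth is undefined and returned as 0 by
convention. The round trip chart -> sphere -> chart is exact to well below
1e-9 degrees away from the pole.
"""

from __future__ import annotations

import numpy as np

__all__ = ["unit_to_azel", "azel_to_unit", "project_azimuth_elevation"]

_UNIT_TOL = 1e-9


def unit_to_azel(v: np.ndarray) -> np.ndarray:
    """(azimuth, elevation) in degrees for unit 3-vectors (rows or single)."""
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    pts = np.atleast_2d(v)
    if pts.shape[1] != 3:
        raise ValueError("expected 3-vectors")
    az = np.degrees(np.arctan2(pts[:, 1], pts[:, 0]))
    # pole convention: both equatorial components zero -> azimuth 0
    at_pole = (pts[:, 0] == 0.0) & (pts[:, 1] == 0.0)
    az[at_pole] = 0.0
    el = np.degrees(np.arcsin(np.clip(pts[:, 2], -1.0, 1.0)))
    out = np.column_stack([az, el])
    return out[0] if single else out


def azel_to_unit(azel: np.ndarray) -> np.ndarray:
    """Unit 3-vectors for (azimuth, elevation) pairs in degrees."""
    azel = np.asarray(azel, dtype=float)
    single = azel.ndim == 1
    pairs = np.atleast_2d(azel)
    az = np.radians(pairs[:, 0])
    el = np.radians(pairs[:, 1])
    out = np.column_stack(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
    )
    return out[0] if single else out


def project_azimuth_elevation(v: np.ndarray) -> tuple[float, float]:
    """Chart coordinates of one unit vector; rejects non-unit input."""
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError("expected a single 3-vector")
    if abs(np.linalg.norm(v) - 1.0) > 1e-6:
        raise ValueError("input must be unit length")
    az, el = unit_to_azel(v)
    return float(az), float(el)
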