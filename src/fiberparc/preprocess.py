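"""Deterministic geometric preprocessing of streamlines and subtractograms.

Covers arc-length resampling to a fixed point count, per-axis affine
min-max normalization into [-1, 1]^3, the two tractogram-centering
strategies (bounding-box midpoint vs. center of mass), hemisphere
assignment by centroid x-coordinate, and uniform subtractogram sampling.

The hemisphere rule operates on pre-normalization world coordinates:
x=0 is the anatomical midline only before per-sample rescaling.
Normalization statistics are computed per subtractogram over the union of
its streamlines' points (training re-normalizes after augmentation, so the
same per-subtractogram convention is used at inference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .tractogram_io import Tractogram

__all__ = [
    "NormalizationRecord",
    "Subtractogram",
    "resample_streamline",
    "minmax_normalize",
    "bounding_box_center",
    "center_of_mass",
    "center_to_atlas",
    "hemisphere_of",
    "sample_subtractogram",
]


@dataclass
class NormalizationRecord:
    """Per-axis min/max (mm) that parameterized an affine min-max normalization."""

    per_axis_min: np.ndarray
    per_axis_max: np.ndarray

    def __post_init__(self):
        self.per_axis_min = np.asarray(self.per_axis_min, dtype=np.float64)
        self.per_axis_max = np.asarray(self.per_axis_max, dtype=np.float64)
        if np.any(self.per_axis_max <= self.per_axis_min):
            raise ValueError("normalization requires min < max on every axis")

    def apply(self, points: np.ndarray) -> np.ndarray:
        span = self.per_axis_max - self.per_axis_min
        return 2.0 * (points - self.per_axis_min) / span - 1.0

    def invert(self, normalized: np.ndarray) -> np.ndarray:
        span = self.per_axis_max - self.per_axis_min
        return (normalized + 1.0) / 2.0 * span + self.per_axis_min


@dataclass
class Subtractogram:
    """A fixed-size, jointly normalized sample of resampled streamlines.

    ``streamlines`` has shape (context_size, n_points, 3) with every
    coordinate in [-1, 1]; ``labels`` are optional per-streamline cluster
    ids; ``unilateral`` records hemisphere restriction ('left'/'right') if
    the sample was drawn from a single hemisphere.
    """

    streamlines: np.ndarray
    labels: Optional[np.ndarray] = None
    norm: Optional[NormalizationRecord] = None
    unilateral: Optional[str] = None

    def __post_init__(self):
        self.streamlines = np.asarray(self.streamlines, dtype=np.float64)
        if self.streamlines.ndim != 3 or self.streamlines.shape[2] != 3:
            raise ValueError("subtractogram array must have shape (context, n_points, 3)")
        if self.streamlines.shape[0] < 1:
            raise ValueError("context_size must be >= 1")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if len(self.labels) != self.streamlines.shape[0]:
                raise ValueError("one label per streamline required")

    @property
    def context_size(self) -> int:
        return self.streamlines.shape[0]

    @property
    def n_points(self) -> int:
        return self.streamlines.shape[1]


def resample_streamline(points: np.ndarray, n_points: int = 15) -> np.ndarray:
    """Resample a polyline to ``n_points`` equally spaced in arc length.

    Linear interpolation along the original polyline; the first and last
    output points equal the original endpoints exactly.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 2:
        raise ValueError("streamline must be an (n>=2, 3) array")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0.0:
        raise ValueError("zero-length streamline (all points identical)")
    targets = np.linspace(0.0, total, n_points)
    out = np.empty((n_points, 3))
    for a in range(3):
        out[:, a] = np.interp(targets, cum, points[:, a])
    out[0], out[-1] = points[0], points[-1]
    return out


def minmax_normalize(points: np.ndarray):
    """Affine min-max normalization of each axis into [-1, 1].

    Per axis a: x' = 2 (x - min_a) / (max_a - min_a) - 1, so the per-axis
    minimum maps to -1 and the maximum to +1. Returns the normalized array
    (same shape) and a :class:`NormalizationRecord` for traceability.
    Degenerate axes (max == min) are an error.
    """
    points = np.asarray(points, dtype=np.float64)
    flat = points.reshape(-1, 3)
    rec = NormalizationRecord(flat.min(axis=0), flat.max(axis=0))
    return rec.apply(points), rec


def _all_points(t) -> np.ndarray:
    if isinstance(t, Tractogram):
        return np.vstack(t.streamlines)
    return np.asarray(t, dtype=np.float64).reshape(-1, 3)


def bounding_box_center(t) -> np.ndarray:
    """Per-axis midpoint of the coordinate-wise min and max: c = (min + max) / 2.

    Unlike the center of mass, this is invariant to streamline duplication
    and to asymmetric streamline density, which is what makes it robust for
    centering tractograms with unilateral fiber loss.
    """
    p = _all_points(t)
    return (p.min(axis=0) + p.max(axis=0)) / 2.0


def center_of_mass(t) -> np.ndarray:
    """Mean over all streamline points (density-weighted tractogram center)."""
    return _all_points(t).mean(axis=0)


def center_to_atlas(t: Tractogram, c_atlas=(0.0, 0.0, 0.0),
                    strategy: str = "bbox") -> Tractogram:
    """Translate a tractogram so its center coincides with ``c_atlas``.

    Applies x_centered = x + (c_atlas - c) to every point, with c the
    bounding-box center (strategy='bbox') or center of mass ('com').
    """
    if strategy == "bbox":
        c = bounding_box_center(t)
    elif strategy == "com":
        c = center_of_mass(t)
    else:
        raise ValueError("strategy must be 'bbox' or 'com'")
    shift = np.asarray(c_atlas, dtype=np.float64) - c
    return Tractogram(
        streamlines=[s + shift for s in t.streamlines],
        labels=t.labels,
        source_meta=dict(t.source_meta),
    )


def hemisphere_of(points: np.ndarray) -> str:
    """'left' if the streamline's mean x-coordinate is < 0, else 'right'.

    RAS convention: x < 0 is the subject's left. The boundary x̄ = 0 is
    assigned to the right hemisphere.
    """
    points = np.asarray(points, dtype=np.float64)
    return "left" if points[:, 0].mean() < 0 else "right"


def sample_subtractogram(
    t: Tractogram,
    context_size: int,
    unilateral: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
    n_points: Optional[int] = None,
) -> Subtractogram:
    """Draw a uniformly random, jointly normalized subtractogram.

    Streamlines must already share a fixed point count (pass ``n_points``
    to resample on the fly). When ``unilateral`` is given, the pool is
    restricted to streamlines on that hemisphere (world-coordinate rule).
    Sampling is without replacement when the pool is large enough, with
    replacement otherwise, so the contract stays total for small pools.
    """
    if rng is None:
        rng = np.random.default_rng()
    if len(t) < 1:
        raise ValueError("cannot sample from an empty tractogram")
    if context_size < 1:
        raise ValueError("context_size must be >= 1")
    streamlines = t.streamlines
    if n_points is not None:
        streamlines = [resample_streamline(s, n_points) for s in streamlines]
    pool = np.arange(len(streamlines))
    if unilateral is not None:
        if unilateral not in ("left", "right"):
            raise ValueError("unilateral must be 'left' or 'right'")
        mask = np.array([hemisphere_of(s) == unilateral for s in streamlines])
        pool = pool[mask]
        if pool.size == 0:
            raise ValueError(f"no streamlines in the {unilateral} hemisphere")
    replace = pool.size < context_size
    idx = rng.choice(pool, size=context_size, replace=replace)
    arr = np.stack([streamlines[i] for i in idx])
    normalized, rec = minmax_normalize(arr)
    labels = None if t.labels is None else t.labels[idx]
    return Subtractogram(
        streamlines=normalized, labels=labels, norm=rec, unilateral=unilateral
    )
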