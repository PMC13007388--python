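"""Training-time augmentation of subtractograms.

Rotation (one rigid rotation per subtractogram, widest range about the
left-right axis), i.i.d. Gaussian point jitter in normalized units,
per-streamline order reversal (flip), and the re-normalization that keeps
the transformer input inside [-1, 1]^3. Hemisphere dropout itself is a
sampling decision made at batch-assembly time (see :mod:`fiberparc.train`);
its rate ``p_hemi`` lives here with the other augmentation knobs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import Subtractogram, minmax_normalize

__all__ = [
    "AugmentConfig",
    "random_rotation",
    "add_noise",
    "flip_streamlines",
    "augment_subtractogram",
]


@dataclass
class AugmentConfig:
    """Augmentation hyperparameters.

    rot_lr_deg, rot_ap_deg, rot_si_deg
        Half-ranges (degrees) of the uniform rotation-angle draws about the
        left-right (x), anterior-posterior (y), and superior-inferior (z)
        axes. Defaults 45, 10, 10.
    noise_sigma
        Std of the i.i.d. Gaussian offset added to every coordinate, in
        normalized [-1, 1] units. Default 0.001.
    p_flip
        Per-streamline probability of reversing point order. Default 0.5.
    p_hemi
        Fraction of training subtractograms restricted to one hemisphere
        (hemisphere dropout). Default 0.3.
    """

    rot_lr_deg: float = 45.0
    rot_ap_deg: float = 10.0
    rot_si_deg: float = 10.0
    noise_sigma: float = 0.001
    p_flip: float = 0.5
    p_hemi: float = 0.3

    def __post_init__(self):
        if min(self.rot_lr_deg, self.rot_ap_deg, self.rot_si_deg) < 0:
            raise ValueError("rotation half-ranges must be >= 0")
        if not (0 <= self.p_flip <= 1 and 0 <= self.p_hemi <= 1):
            raise ValueError("p_flip and p_hemi must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(rot_lr_deg=0, rot_ap_deg=0, rot_si_deg=0,
                   noise_sigma=0, p_flip=0, p_hemi=0)


def _rotation_matrix(angles_rad: np.ndarray) -> np.ndarray:
    """Extrinsic composition R = Rz @ Ry @ Rx (x applied first)."""
    ax, ay, az = angles_rad
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def random_rotation(sub: Subtractogram, cfg: AugmentConfig,
                    rng: np.random.Generator) -> Subtractogram:
    """Apply one random rigid rotation to the whole subtractogram.

    Angles are drawn uniformly from [-half_range, +half_range] per axis and
    the rotation acts about the origin of the normalized frame; the later
    re-normalization absorbs any bounding-box change.
    """
    half = np.deg2rad([cfg.rot_lr_deg, cfg.rot_ap_deg, cfg.rot_si_deg])
    angles = rng.uniform(-half, half)
    rot = _rotation_matrix(angles)
    return Subtractogram(
        streamlines=sub.streamlines @ rot.T,
        labels=sub.labels,
        norm=sub.norm,
        unilateral=sub.unilateral,
    )


def add_noise(sub: Subtractogram, cfg: AugmentConfig,
              rng: np.random.Generator) -> Subtractogram:
    """Add i.i.d. zero-mean Gaussian jitter (std ``noise_sigma``) to every coordinate."""
    noise = rng.normal(0.0, cfg.noise_sigma, size=sub.streamlines.shape) \
        if cfg.noise_sigma > 0 else 0.0
    return Subtractogram(
        streamlines=sub.streamlines + noise,
        labels=sub.labels,
        norm=sub.norm,
        unilateral=sub.unilateral,
    )


def flip_streamlines(sub: Subtractogram, cfg: AugmentConfig,
                     rng: np.random.Generator) -> Subtractogram:
    """Independently reverse each streamline's point order with probability ``p_flip``.

    Streamlines are orientation-free, so forward and reversed point orders
    represent the same fiber; flipping promotes directional invariance.
    """
    arr = sub.streamlines.copy()
    flip = rng.random(arr.shape[0]) < cfg.p_flip
    arr[flip] = arr[flip, ::-1, :]
    return Subtractogram(
        streamlines=arr, labels=sub.labels, norm=sub.norm, unilateral=sub.unilateral
    )


def augment_subtractogram(sub: Subtractogram, cfg: AugmentConfig,
                          rng: np.random.Generator) -> Subtractogram:
    """Rotate, jitter, flip, then min-max re-normalize back into [-1, 1]^3.

    Labels, context size, and point count are untouched.
    """
    out = random_rotation(sub, cfg, rng)
    out = add_noise(out, cfg, rng)
    out = flip_streamlines(out, cfg, rng)
    normalized, rec = minmax_normalize(out.streamlines)
    return Subtractogram(
        streamlines=normalized, labels=out.labels, norm=rec, unilateral=out.unilateral
    )
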