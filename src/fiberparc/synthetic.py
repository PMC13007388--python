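"""Labeled tractogram phantoms: coherent mirrored bundles, outliers, ablation.

Bundles are smooth cubic centerlines with per-streamline rigid lateral
offsets (Gaussian, clipped at 3.5 sigma so hemisphere membership is a
construction guarantee), small per-point jitter, and random end
truncation. Phantoms mirror right-hemisphere bundles across the midline
(x -> -x) into distinct left classes, add a configurable fraction of
incoherent outlier streamlines (random high-curvature curves spanning the
same volume), and can be unilaterally ablated to emulate the severe
one-sided streamline loss seen after hemispherotomy, including midline
truncation of commissural fibers into residual fragments.

The default geometry loosely imitates a vertical projection bundle
(CST-like), an arched association bundle (AF-like), a dorsal
anterior-posterior bundle (SLF-like), and - in the hemispherotomy preset -
an arching commissural bundle (CC-like). No anatomical fidelity is
claimed; the point is to exercise hemisphere logic, outlier handling, and
ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from .preprocess import hemisphere_of
from .tractogram_io import LabelMap, Tractogram

__all__ = [
    "BundleSpec",
    "PhantomSpec",
    "make_bundle",
    "make_phantom",
    "ablate_hemisphere",
    "bilateral6_spec",
    "hemispherotomy_spec",
]


@dataclass
class BundleSpec:
    """Geometry of one synthetic bundle.

    control_points: >= 3 anchors (mm) of the smooth centerline.
    lateral_sigma: std (mm) of the rigid per-streamline offset.
    length_jitter: (lo, hi) fractional truncation drawn per end.
    """

    name: str
    control_points: np.ndarray
    lateral_sigma: float
    n_streamlines: int
    hemisphere: str = "right"
    length_jitter: tuple = (0.0, 0.1)
    point_jitter: float = 0.15

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, dtype=np.float64)
        if self.control_points.ndim != 2 or self.control_points.shape[1] != 3 \
                or self.control_points.shape[0] < 3:
            raise ValueError("control_points must be a (>=3, 3) array")
        if self.lateral_sigma <= 0:
            raise ValueError("lateral_sigma must be > 0")
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be >= 1")
        if self.hemisphere not in ("left", "right", "commissural"):
            raise ValueError("hemisphere must be left/right/commissural")

    def mirrored(self, name: Optional[str] = None) -> "BundleSpec":
        """Reflect across the midsagittal plane (x -> -x)."""
        side = {"right": "left", "left": "right"}.get(self.hemisphere,
                                                      "commissural")
        return replace(
            self,
            name=name or self.name + "_mirror",
            control_points=self.control_points * np.array([-1.0, 1.0, 1.0]),
            hemisphere=side,
        )


@dataclass
class PhantomSpec:
    """A whole phantom: bundles (mirrored if requested) plus outliers."""

    bundles: list
    mirror: bool = True
    outlier_fraction: float = 0.1
    n_points_raw: int = 50
    seed: int = 0
    clusters_per_tract: int = 1

    def __post_init__(self):
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must lie in [0, 1)")
        if self.clusters_per_tract < 1:
            raise ValueError("clusters_per_tract must be >= 1")


def _centerline(control_points: np.ndarray) -> CubicSpline:
    seg = np.linalg.norm(np.diff(control_points, axis=0), axis=1)
    if np.all(seg == 0):
        raise ValueError("degenerate control points (zero extent)")
    u = np.concatenate([[0.0], np.cumsum(seg)])
    return CubicSpline(u / u[-1], control_points, axis=0)


# rigid offsets are clipped at this many sigmas so that bundles keep a
# guaranteed margin from the midline (hemisphere membership by construction)
_OFFSET_CLIP_SIGMA = 3.5


def make_bundle(spec: BundleSpec, rng: np.random.Generator,
                n_points_raw: int = 50) -> list:
    """Generate the bundle's streamlines (list of (n_points_raw, 3) arrays)."""
    spline = _centerline(spec.control_points)
    lo, hi = spec.length_jitter
    streamlines = []
    for _ in range(spec.n_streamlines):
        t0 = rng.uniform(lo, hi) if hi > lo else lo
        t1 = 1.0 - (rng.uniform(lo, hi) if hi > lo else lo)
        ts = np.linspace(t0, t1, n_points_raw)
        pts = spline(ts)
        offset = rng.normal(0.0, spec.lateral_sigma, size=3)
        offset = np.clip(offset, -_OFFSET_CLIP_SIGMA * spec.lateral_sigma,
                         _OFFSET_CLIP_SIGMA * spec.lateral_sigma)
        if spec.point_jitter > 0:
            pts = pts + rng.normal(0.0, spec.point_jitter, size=pts.shape)
        streamlines.append(pts + offset)
    return streamlines


def _outlier_streamline(rng, low, high, n_points_raw):
    """A random high-curvature 3-anchor curve inside the phantom volume."""
    anchors = rng.uniform(low, high, size=(3, 3))
    while np.all(np.linalg.norm(np.diff(anchors, axis=0), axis=1) < 1.0):
        anchors = rng.uniform(low, high, size=(3, 3))
    spline = _centerline(anchors)
    ts = np.linspace(0.0, 1.0, n_points_raw)
    return spline(ts) + rng.normal(0.0, 0.3, size=(n_points_raw, 3))


def make_phantom(spec: PhantomSpec, rng: Optional[np.random.Generator] = None):
    """Build the labeled phantom; returns ``(Tractogram, LabelMap)``.

    Mirroring reflects every non-commissural bundle into a distinct class
    on the opposite hemisphere. Outliers get the distinguished last tract
    id. With ``clusters_per_tract > 1`` the emitted labels are cluster ids
    mapping many-to-one onto tracts (the outlier keeps a single cluster).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    bundles = []
    for b in spec.bundles:
        bundles.append(b)
        if spec.mirror and b.hemisphere != "commissural":
            suffix = "_L" if b.hemisphere == "right" else "_R"
            bundles.append(b.mirrored(name=b.name.rstrip("_RL") + suffix))
    if len(bundles) < 2:
        raise ValueError("phantom needs >= 2 bundles after mirroring")
    streamlines, tract_labels = [], []
    names = {}
    for tract_id, b in enumerate(bundles):
        names[tract_id] = b.name
        sl = make_bundle(b, rng, n_points_raw=spec.n_points_raw)
        streamlines.extend(sl)
        tract_labels.extend([tract_id] * len(sl))
    outlier_id = len(bundles)
    names[outlier_id] = "outlier"
    n_bundle = len(streamlines)
    f = spec.outlier_fraction
    if f > 0:
        allp = np.vstack([s for s in streamlines])
        low, high = allp.min(axis=0), allp.max(axis=0)
        n_total_target = int(round(n_bundle / (1.0 - f)))
        n_out = rng.binomial(n_total_target, f)
        for _ in range(n_out):
            streamlines.append(
                _outlier_streamline(rng, low, high, spec.n_points_raw))
            tract_labels.append(outlier_id)
    tract_labels = np.asarray(tract_labels, dtype=np.int64)
    # optional many-to-one cluster refinement
    k = spec.clusters_per_tract
    if k == 1:
        labels = tract_labels
        lm = LabelMap.identity(len(bundles), outlier_id=outlier_id,
                               tract_names=names)
    else:
        cluster_to_tract = {}
        for tid in range(len(bundles)):
            for j in range(k):
                cluster_to_tract[tid * k + j] = tid
        outlier_cluster = len(bundles) * k
        cluster_to_tract[outlier_cluster] = outlier_id
        labels = np.where(
            tract_labels == outlier_id,
            outlier_cluster,
            tract_labels * k + rng.integers(0, k, size=len(tract_labels)),
        )
        lm = LabelMap(cluster_to_tract=cluster_to_tract, tract_names=names,
                      outlier_id=outlier_id)
    order = rng.permutation(len(streamlines))
    t = Tractogram(
        streamlines=[streamlines[i] for i in order],
        labels=labels[order],
    )
    return t, lm


def ablate_hemisphere(t: Tractogram, side: str, keep_fraction: float,
                      rng: np.random.Generator) -> Tractogram:
    """Emulate unilateral (hemispherotomy-like) streamline loss.

    Streamlines on the named side are retained independently with
    probability ``keep_fraction``; the other side is untouched.
    Midline-crossing (commissural) streamlines are truncated at the
    midline with probability 1 - keep_fraction, leaving the residual
    fragment on the preserved side.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if not 0 <= keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in [0, 1]")
    keep_sign = 1.0 if side == "left" else -1.0  # preserved side of x
    streamlines, labels = [], []
    for i, s in enumerate(t.streamlines):
        x = s[:, 0]
        crosses = x.min() < 0 < x.max()
        if crosses:
            if rng.random() < 1.0 - keep_fraction:
                mask = (x * keep_sign) > 0
                if mask.sum() < 2:
                    continue
                s = s[mask]
        elif hemisphere_of(s) == side:
            if rng.random() >= keep_fraction:
                continue
        streamlines.append(s)
        if t.labels is not None:
            labels.append(t.labels[i])
    return Tractogram(
        streamlines=streamlines,
        labels=np.asarray(labels, dtype=np.int64) if t.labels is not None else None,
        source_meta=dict(t.source_meta),
    )


def _default_bundles(n_streamlines: int) -> list:
    """CST-like, AF-like, SLF-like right-hemisphere bundles (mm, RAS)."""
    return [
        BundleSpec(
            name="cst_R",
            control_points=[[26, -22, -40], [22, -18, -5], [20, -12, 30],
                            [24, -8, 55]],
            lateral_sigma=3.0,
            n_streamlines=n_streamlines,
        ),
        BundleSpec(
            name="af_R",
            control_points=[[42, 28, 2], [46, 0, 28], [44, -30, 22],
                            [40, -38, -12]],
            lateral_sigma=3.0,
            n_streamlines=n_streamlines,
        ),
        BundleSpec(
            name="slf_R",
            control_points=[[28, -42, 34], [31, -10, 42], [29, 18, 38],
                            [27, 38, 28]],
            lateral_sigma=3.0,
            n_streamlines=n_streamlines,
        ),
    ]


def bilateral6_spec(n_per_bundle: int = 1800, outlier_fraction: float = 0.1,
                    seed: int = 0, clusters_per_tract: int = 1) -> PhantomSpec:
    """Default bilateral phantom: 3 mirrored pairs (6 classes) + outliers.

    At the defaults this yields ~12,000 streamlines of which ~10% are
    outliers.
    """
    return PhantomSpec(
        bundles=_default_bundles(n_per_bundle),
        mirror=True,
        outlier_fraction=outlier_fraction,
        seed=seed,
        clusters_per_tract=clusters_per_tract,
    )


def hemispherotomy_spec(n_per_bundle: int = 1800, outlier_fraction: float = 0.1,
                        seed: int = 0) -> PhantomSpec:
    """Bilateral phantom plus an arching commissural (CC-like) bundle.

    Intended to be passed through :func:`ablate_hemisphere` to emulate the
    post-hemispherotomy regime, including commissural residual fragments.
    """
    bundles = _default_bundles(n_per_bundle)
    bundles.append(
        BundleSpec(
            name="cc",
            control_points=[[-42, 8, 18], [-20, 12, 42], [0, 14, 50],
                            [20, 12, 42], [42, 8, 18]],
            lateral_sigma=3.0,
            n_streamlines=n_per_bundle,
            hemisphere="commissural",
        )
    )
    return PhantomSpec(bundles=bundles, mirror=True,
                       outlier_fraction=outlier_fraction, seed=seed)
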