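"""Streamline I/O: TRK/TCK reading and writing, length filtering, prediction tables.

All in-memory coordinates are world-space RAS millimeters (x > 0 is the
subject's right); on-disk voxel conventions are resolved at this boundary
via the file header affine. A whitespace-delimited text dialect (one
streamline per blank-line-separated block, extension ``.txt``) is supported
for small fixtures.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Tractogram",
    "LabelMap",
    "read_tractogram",
    "write_tractogram",
    "filter_by_length",
    "streamline_length",
    "write_predictions",
    "read_predictions",
    "read_label_map",
    "write_label_map",
    "split_by_tract",
]

_FORMATS = ("trk", "tck", "txt")


class TractogramFormatError(ValueError):
    """Raised for unreadable, corrupt, or unsupported streamline files."""


@dataclass
class Tractogram:
    """A collection of streamlines in RAS mm, with optional per-streamline labels.

    Parameters
    ----------
    streamlines : list of (n_i, 3) float arrays
        Each streamline is an ordered 3-D polyline with at least 2 points.
    labels : optional int array, one entry per streamline
    source_meta : dict
        Opaque record of the source file header (affine, voxel sizes),
        preserved on round-trip.
    """

    streamlines: list
    labels: Optional[np.ndarray] = None
    source_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.streamlines = [np.asarray(s, dtype=np.float64) for s in self.streamlines]
        for i, s in enumerate(self.streamlines):
            if s.ndim != 2 or s.shape[1] != 3:
                raise ValueError(f"streamline {i} is not an (n, 3) array")
            if s.shape[0] < 2:
                raise ValueError(f"streamline {i} has fewer than 2 points")
            if not np.all(np.isfinite(s)):
                raise ValueError(f"streamline {i} contains non-finite coordinates")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if len(self.labels) != len(self.streamlines):
                raise ValueError(
                    f"{len(self.labels)} labels for {len(self.streamlines)} streamlines"
                )

    def __len__(self) -> int:
        return len(self.streamlines)

    def subset(self, indices: Sequence[int]) -> "Tractogram":
        """Order-preserving selection of streamlines (labels carried along)."""
        indices = np.asarray(indices)
        return Tractogram(
            streamlines=[self.streamlines[i] for i in indices],
            labels=None if self.labels is None else self.labels[indices],
            source_meta=dict(self.source_meta),
        )


@dataclass
class LabelMap:
    """Total map from model cluster ids to anatomical tract ids.

    The label taxonomy follows the common atlas convention: a fine
    clustering (e.g. 1600 clusters) is mapped many-to-one onto anatomical
    tracts plus one distinguished outlier (false-positive) class.
    """

    cluster_to_tract: dict
    tract_names: dict
    outlier_id: int

    def __post_init__(self):
        if self.outlier_id not in set(self.cluster_to_tract.values()) | set(
            self.tract_names
        ):
            # the outlier id must exist somewhere in the tract id space
            self.tract_names.setdefault(self.outlier_id, "outlier")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_to_tract)

    @property
    def tract_ids(self) -> list:
        return sorted(self.tract_names)

    def map(self, cluster_ids: np.ndarray) -> np.ndarray:
        """Elementwise cluster→tract lookup; unknown ids raise KeyError."""
        cluster_ids = np.asarray(cluster_ids)
        out = np.empty(cluster_ids.shape, dtype=np.int64)
        for i, c in np.ndenumerate(cluster_ids):
            if int(c) not in self.cluster_to_tract:
                raise KeyError(f"unknown cluster id {int(c)}")
            out[i] = self.cluster_to_tract[int(c)]
        return out

    @classmethod
    def identity(cls, n_tracts: int, outlier_id: Optional[int] = None,
                 tract_names: Optional[dict] = None) -> "LabelMap":
        """Identity map where clusters coincide with tracts."""
        if outlier_id is None:
            outlier_id = n_tracts
        ids = list(range(n_tracts)) + [outlier_id]
        names = tract_names or {i: f"tract_{i}" for i in range(n_tracts)}
        names = dict(names)
        names[outlier_id] = names.get(outlier_id, "outlier")
        return cls(
            cluster_to_tract={i: i for i in ids},
            tract_names=names,
            outlier_id=outlier_id,
        )


def streamline_length(points: np.ndarray) -> float:
    """Polyline arc length in mm (sum of consecutive segment lengths)."""
    points = np.asarray(points, dtype=np.float64)
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def _infer_format(path: str, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in _FORMATS:
            raise TractogramFormatError(
                f"unsupported format {fmt!r}; supported: {', '.join(_FORMATS)}"
            )
        return fmt
    ext = os.path.splitext(str(path))[1].lower().lstrip(".")
    if ext not in _FORMATS:
        raise TractogramFormatError(
            f"cannot infer streamline format from extension {ext!r} of {path!r}; "
            f"supported formats: {', '.join(_FORMATS)}"
        )
    return ext


def _read_text(path: str) -> list:
    streamlines, block = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if line.startswith("#"):
                continue
            if not line:
                if block:
                    streamlines.append(np.array(block, dtype=np.float64))
                    block = []
                continue
            vals = line.split()
            if len(vals) != 3:
                raise TractogramFormatError(
                    f"{path}:{lineno}: expected 3 whitespace-separated "
                    f"coordinates, got {len(vals)}"
                )
            try:
                block.append([float(v) for v in vals])
            except ValueError as e:
                raise TractogramFormatError(f"{path}:{lineno}: {e}") from e
    if block:
        streamlines.append(np.array(block, dtype=np.float64))
    return streamlines


def _write_text(streamlines: Iterable[np.ndarray], path: str) -> None:
    with open(path, "w") as fh:
        for s in streamlines:
            for p in s:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            fh.write("\n")


def read_tractogram(path, format: str = "auto") -> Tractogram:
    """Read a TRK/TCK/text streamline file into RAS mm world coordinates.

    TRK voxel-order quirks are resolved via the header affine, so
    coordinates are RAS mm regardless of the on-disk voxel convention.
    Streamline ordering is preserved.
    """
    fmt = _infer_format(path, format)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "txt":
        streamlines = _read_text(path)
        meta = {"format": "txt"}
    else:
        try:
            tf = nib.streamlines.load(str(path))
        except Exception as e:  # corrupt header / truncated records
            raise TractogramFormatError(f"cannot parse {path!r} as {fmt}: {e}") from e
        # nibabel returns streamlines already transformed to RAS+ mm
        streamlines = [np.asarray(s, dtype=np.float64) for s in tf.streamlines]
        meta = {"format": fmt, "header": dict(tf.header)}
    if not streamlines:
        raise TractogramFormatError(f"{path!r} contains no streamlines")
    return Tractogram(streamlines=streamlines, source_meta=meta)


def write_tractogram(t: Tractogram, path, format: str = "auto") -> None:
    """Write a tractogram; round-trips points within float tolerance.

    TRK/TCK output goes through nibabel with an identity RAS-mm affine.
    """
    if len(t) == 0:
        raise ValueError("refusing to write an empty tractogram")
    fmt = _infer_format(path, format)
    if fmt == "txt":
        _write_text(t.streamlines, path)
        return
    sl = [np.asarray(s, dtype=np.float32) for s in t.streamlines]
    ntg = nib.streamlines.Tractogram(sl, affine_to_rasmm=np.eye(4))
    if fmt == "trk":
        header = nib.streamlines.TrkFile.create_empty_header()
        # give the header a sane voxel grid covering the data
        allp = np.vstack(sl)
        header["voxel_sizes"] = np.array([1.0, 1.0, 1.0], dtype=np.float32)
        header["dimensions"] = np.maximum(
            np.ceil(allp.max(axis=0) - np.minimum(allp.min(axis=0), 0)).astype(np.int16)
            + 1,
            1,
        )
        nib.streamlines.save(ntg, str(path), header=header)
    else:
        nib.streamlines.save(ntg, str(path))


def filter_by_length(t: Tractogram, min_length: float) -> Tractogram:
    """Keep streamlines with arc length >= ``min_length`` mm (labels aligned).

    The boundary case (length exactly equal to the threshold) is kept.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    keep = [i for i, s in enumerate(t.streamlines)
            if streamline_length(s) >= min_length]
    return t.subset(keep)


def write_predictions(names: Sequence[str], path) -> None:
    """Write per-streamline tract names as a two-column TSV with a header row."""
    df = pd.DataFrame(
        {"streamline_index": np.arange(len(names)), "tract_name": list(names)}
    )
    df.to_csv(path, sep="\t", index=False)


def read_predictions(path) -> list:
    """Re-read a prediction TSV; returns the tract-name sequence in file order."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["streamline_index", "tract_name"]:
        raise TractogramFormatError(f"{path!r} is not a prediction table")
    return df.sort_values("streamline_index")["tract_name"].tolist()


def write_label_map(lm: LabelMap, cluster_path, names_path) -> None:
    """Persist a LabelMap as two TSVs: (cluster_id, tract_id) and (tract_id, name)."""
    pd.DataFrame(
        sorted(lm.cluster_to_tract.items()), columns=["cluster_id", "tract_id"]
    ).to_csv(cluster_path, sep="\t", index=False)
    names = pd.DataFrame(sorted(lm.tract_names.items()), columns=["tract_id", "name"])
    names["is_outlier"] = (names["tract_id"] == lm.outlier_id).astype(int)
    names.to_csv(names_path, sep="\t", index=False)


def read_label_map(cluster_path, names_path) -> LabelMap:
    c = pd.read_csv(cluster_path, sep="\t")
    n = pd.read_csv(names_path, sep="\t")
    outliers = n.loc[n["is_outlier"] == 1, "tract_id"]
    if len(outliers) != 1:
        raise TractogramFormatError("label map must mark exactly one outlier tract")
    return LabelMap(
        cluster_to_tract=dict(zip(c["cluster_id"].astype(int), c["tract_id"].astype(int))),
        tract_names=dict(zip(n["tract_id"].astype(int), n["name"])),
        outlier_id=int(outliers.iloc[0]),
    )


def split_by_tract(t: Tractogram, out_dir, format: str = "trk",
                   tract_names: Optional[dict] = None) -> dict:
    """Write one file per tract id present in ``t.labels``; returns {id: path}."""
    if t.labels is None:
        raise ValueError("tractogram has no labels to split by")
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for tid in np.unique(t.labels):
        idx = np.flatnonzero(t.labels == tid)
        name = (tract_names or {}).get(int(tid), f"tract_{int(tid)}")
        path = os.path.join(out_dir, f"{name}.{format}")
        write_tractogram(t.subset(idx), path, format=format)
        paths[int(tid)] = path
    return paths
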