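"""File formats: correspondence CSV/JSON, PLY clouds, transform JSON,
intrinsics YAML, images and report JSON.

Every JSON artifact written by the CLI embeds the producing configuration
and seed under a ``"provenance"`` key so runs are reproducible from their
outputs alone.  Coordinates are world-frame, right-handed, in abstract
scene units.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .geometry import CameraIntrinsics
from .horn import CorrespondenceSet
from .transforms import SimilarityTransform

__all__ = [
    "read_correspondences_csv", "write_correspondences_csv",
    "read_correspondences_json", "write_correspondences_json",
    "read_ply", "write_ply",
    "read_transform_json", "write_transform_json",
    "read_intrinsics_yaml", "write_intrinsics_yaml",
    "read_image", "write_image",
    "write_report_json",
]

_CSV_HEADER = ["px", "py", "pz", "qx", "qy", "qz"]


def write_correspondences_csv(path, corr: CorrespondenceSet) -> None:
    data = np.hstack([corr.p, corr.q])
    np.savetxt(path, data, delimiter=",", header=",".join(_CSV_HEADER),
               comments="", fmt="%.17g")


def read_correspondences_csv(path) -> CorrespondenceSet:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if [h.strip() for h in header] != _CSV_HEADER:
        raise ValueError(f"{path}: line 1: expected header "
                         f"{','.join(_CSV_HEADER)}, got {','.join(header)}")
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got {data.shape[1]}")
    return CorrespondenceSet(data[:, :3], data[:, 3:])


def write_correspondences_json(path, corr: CorrespondenceSet) -> None:
    Path(path).write_text(json.dumps(
        {"p": corr.p.tolist(), "q": corr.q.tolist()}, indent=1))


def read_correspondences_json(path) -> CorrespondenceSet:
    d = json.loads(Path(path).read_text())
    for key in ("p", "q"):
        if key not in d:
            raise ValueError(f"{path}: missing array {key!r}")
    return CorrespondenceSet(np.asarray(d["p"]), np.asarray(d["q"]))


# -- PLY (ASCII, vertex x/y/z) -----------------------------------------

def write_ply(path, points: np.ndarray) -> None:
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n"
                 f"element vertex {len(points)}\n"
                 "property double x\nproperty double y\nproperty double z\n"
                 "end_header\n")
        for x, y, z in points:
            fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")


def read_ply(path) -> np.ndarray:
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path}: not a PLY file (magic {line!r})")
        n_vertex = None
        fmt = None
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: header never ends")
            line = line.strip()
            if line.startswith("format"):
                fmt = line.split()[1]
            elif line.startswith("element vertex"):
                n_vertex = int(line.split()[2])
            elif line == "end_header":
                break
        if fmt != "ascii":
            raise ValueError(f"{path}: only ASCII PLY is supported, got {fmt}")
        if n_vertex is None:
            raise ValueError(f"{path}: no vertex element declared")
        pts = np.loadtxt(fh, max_rows=n_vertex, ndmin=2)
    if pts.shape != (n_vertex, 3):
        raise ValueError(f"{path}: expected {n_vertex} x/y/z rows, "
                         f"got shape {pts.shape}")
    return pts


# -- transforms, intrinsics, reports -----------------------------------

def write_transform_json(path, transform: SimilarityTransform,
                         provenance: dict | None = None) -> None:
    doc = transform.to_dict()
    if provenance:
        doc["provenance"] = provenance
    Path(path).write_text(json.dumps(doc, indent=1))


def read_transform_json(path) -> SimilarityTransform:
    d = json.loads(Path(path).read_text())
    for key in ("quaternion", "scale", "translation"):
        if key not in d:
            raise ValueError(f"{path}: missing field {key!r}")
    return SimilarityTransform.from_dict(d)


def write_intrinsics_yaml(path, K: CameraIntrinsics) -> None:
    Path(path).write_text(yaml.safe_dump(K.to_dict()))


def read_intrinsics_yaml(path) -> CameraIntrinsics:
    d = yaml.safe_load(Path(path).read_text())
    missing = [k for k in ("fx", "fy", "width", "height") if k not in d]
    if missing:
        raise ValueError(f"{path}: missing intrinsics fields {missing}")
    return CameraIntrinsics.from_dict(d)


def write_image(path, img: np.ndarray) -> None:
    img = np.asarray(img)
    if img.dtype != np.uint8:
        img = np.clip(np.round(np.asarray(img, dtype=float) * 255), 0,
                      255).astype(np.uint8)
    iio.imwrite(path, img)


def read_image(path) -> np.ndarray:
    return iio.imread(path)


def write_report_json(path, report: dict, provenance: dict | None = None) -> None:
    doc = dict(report)
    if provenance:
        doc["provenance"] = provenance
    Path(path).write_text(json.dumps(doc, indent=1))
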