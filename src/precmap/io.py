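"""File formats: GIFTI surfaces and per-vertex maps, a binary matrix
container with a JSON sidecar for dense time series, tab-separated record
tables, YAML configuration, and run manifests.

Conventions: vertex indexing is 0-based everywhere, areas are mm², ages are
decimal weeks, floating maps roundtrip within 1e-12 (float64 containers) and
label/integer data exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from nibabel.gifti import GiftiDataArray, GiftiImage

from .mesh import SurfaceMesh
from .preprocess import BoldSeries

FORMAT_VERSION = "1"


class FormatError(RuntimeError):
    """Raised on truncated, malformed or version-mismatched artifact files."""


# -- GIFTI surfaces and maps ------------------------------------------------

def save_mesh_gifti(mesh: SurfaceMesh, path) -> Path:
    path = Path(path)
    img = GiftiImage(darrays=[
        GiftiDataArray(mesh.vertex_coords.astype(np.float32),
                       intent="NIFTI_INTENT_POINTSET"),
        GiftiDataArray(mesh.triangles.astype(np.int32),
                       intent="NIFTI_INTENT_TRIANGLE"),
    ])
    nib.save(img, str(path))
    return path


def load_mesh_gifti(path) -> SurfaceMesh:
    img = _load_gifti(path)
    points = tris = None
    for da in img.darrays:
        if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            points = np.asarray(da.data, dtype=float)
        elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            tris = np.asarray(da.data, dtype=np.int64)
    if points is None or tris is None:
        raise FormatError(f"{path}: missing pointset or triangle array")
    return SurfaceMesh(vertex_coords=points, triangles=tris)


def save_maps_gifti(maps: np.ndarray, path, names: list | None = None) -> Path:
    """Write an L×V (or length-V) stack of per-vertex maps, one darray each."""
    path = Path(path)
    # the GIFTI standard stores per-vertex floats as float32; exact float64
    # roundtrips go through the matrix container instead
    maps = np.atleast_2d(np.asarray(maps, dtype=np.float32))
    darrays = []
    for i, row in enumerate(maps):
        da = GiftiDataArray(row.astype(np.float32), intent="NIFTI_INTENT_NONE",
                            datatype="NIFTI_TYPE_FLOAT32")
        if names is not None:
            da.meta["Name"] = str(names[i])
        darrays.append(da)
    nib.save(GiftiImage(darrays=darrays), str(path))
    return path


def load_maps_gifti(path) -> tuple[np.ndarray, list]:
    img = _load_gifti(path)
    if not img.darrays:
        raise FormatError(f"{path}: no data arrays")
    maps = np.stack([np.asarray(da.data, dtype=float) for da in img.darrays])
    names = [da.meta.get("Name", f"map{i:02d}") for i, da in enumerate(img.darrays)]
    return maps, names


def save_labels_gifti(labels: np.ndarray, path, label_names: dict | None = None) -> Path:
    """Write an integer label map with a color table (label 0 = unassigned)."""
    path = Path(path)
    labels = np.asarray(labels, dtype=np.int32)
    img = GiftiImage(darrays=[
        GiftiDataArray(labels, intent="NIFTI_INTENT_LABEL",
                       datatype="NIFTI_TYPE_INT32")
    ])
    table = nib.gifti.GiftiLabelTable()
    rng = np.random.default_rng(0)
    names = label_names or {}
    for k in np.unique(labels):
        r, g, b = ((0.5, 0.5, 0.5) if k == 0 else tuple(rng.uniform(0, 1, 3)))
        lab = nib.gifti.GiftiLabel(key=int(k), red=float(r), green=float(g),
                                   blue=float(b), alpha=1.0)
        lab.label = str(names.get(int(k), f"label{int(k)}"))
        table.labels.append(lab)
    img.labeltable = table
    nib.save(img, str(path))
    return path


def load_labels_gifti(path) -> np.ndarray:
    img = _load_gifti(path)
    if not img.darrays:
        raise FormatError(f"{path}: no data arrays")
    return np.asarray(img.darrays[0].data, dtype=np.int32)


def _load_gifti(path) -> GiftiImage:
    try:
        return nib.load(str(path))
    except Exception as exc:  # truncated/invalid XML, wrong format, ...
        raise FormatError(f"{path}: not a readable GIFTI file ({exc})") from exc


# -- dense matrix container -------------------------------------------------

def save_series(series: BoldSeries, path) -> Path:
    """Write a BOLD series as float64 .npy plus a JSON sidecar with the
    dimensions, TR and session id."""
    path = Path(path)
    np.save(path, series.data.astype(np.float64))
    npy = path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")
    sidecar = {
        "format_version": FORMAT_VERSION,
        "n_frames": int(series.n_frames),
        "n_vertices": int(series.n_vertices),
        "tr_seconds": float(series.tr_seconds),
        "session_id": series.session_id,
    }
    npy.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return npy


def load_series(path) -> BoldSeries:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"{sidecar_path}: missing sidecar")
    meta = json.loads(sidecar_path.read_text())
    if meta.get("format_version") != FORMAT_VERSION:
        raise FormatError(
            f"{path}: format version {meta.get('format_version')!r} "
            f"!= {FORMAT_VERSION!r}"
        )
    try:
        data = np.load(path)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable matrix container ({exc})") from exc
    if data.shape != (meta["n_frames"], meta["n_vertices"]):
        raise FormatError(f"{path}: shape {data.shape} does not match sidecar")
    return BoldSeries(data, tr_seconds=meta["tr_seconds"],
                      session_id=meta["session_id"])


# -- tables, config, manifests ---------------------------------------------

def save_records(records: pd.DataFrame, path) -> Path:
    path = Path(path)
    records.to_csv(path, sep="\t", index=False)
    return path


def load_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "preterm" in df.columns:
        df["preterm"] = df["preterm"].astype(bool)
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: dict, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def save_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path


def load_manifest(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: corrupt manifest ({exc})") from exc
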