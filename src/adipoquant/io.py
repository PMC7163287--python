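"""NIfTI + JSON-sidecar input/output for echo series and parametric maps."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .recon import EchoSeries, ParametricMaps
from .signal_model import EchoTimes

MAP_NAMES = ("W", "F", "pdff", "r2star", "fieldmap", "valid")


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_echo_series(series: EchoSeries, nifti_path, sidecar_path) -> None:
    """Write the complex series as complex64 NIfTI plus a JSON sidecar."""
    img = nib.Nifti1Image(
        np.asarray(series.data, dtype=np.complex64), _affine(series.voxel_size)
    )
    nib.save(img, str(nifti_path))
    meta = {
        "echo_times_ms": [float(t) for t in series.tes.values_ms],
        "field_strength_T": float(series.field_strength),
        "voxel_size_mm": [float(v) for v in series.voxel_size],
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=2))


def load_echo_series(nifti_path, sidecar_path) -> EchoSeries:
    meta = json.loads(Path(sidecar_path).read_text())
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj)
    if not np.iscomplexobj(data):
        data = data.astype(complex)
    return EchoSeries(
        data=data,
        tes=EchoTimes(tuple(meta["echo_times_ms"])),
        voxel_size=tuple(meta["voxel_size_mm"]),
        field_strength=float(meta["field_strength_T"]),
    )


def save_maps(maps: ParametricMaps, out_dir, voxel_size=(2.58, 2.58, 5.0)) -> dict:
    """One NIfTI per map with a shared affine; returns the path manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(voxel_size)
    paths = {}
    for name in MAP_NAMES:
        arr = getattr(maps, name)
        dtype = np.uint8 if arr.dtype == bool else np.float32
        img = nib.Nifti1Image(arr.astype(dtype), aff)
        path = out_dir / f"{name}.nii.gz"
        nib.save(img, str(path))
        paths[name] = str(path)
    (out_dir / "meta.json").write_text(json.dumps(maps.meta, indent=2))
    return paths


def load_maps(map_dir) -> ParametricMaps:
    map_dir = Path(map_dir)
    arrays = {}
    for name in MAP_NAMES:
        img = nib.load(str(map_dir / f"{name}.nii.gz"))
        arr = np.asarray(img.dataobj)
        arrays[name] = arr.astype(bool) if name == "valid" else arr.astype(float)
    meta_path = map_dir / "meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ParametricMaps(meta=meta, **arrays)


def save_labels(seg, path, voxel_size=(2.58, 2.58, 5.0)) -> None:
    img = nib.Nifti1Image(seg.labels.astype(np.uint8), _affine(voxel_size))
    nib.save(img, str(path))
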