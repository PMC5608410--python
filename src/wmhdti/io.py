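"""File I/O: NIfTI volumes, FSL bvals/bvecs, TrackVis .trk, TSV tables.

All volumes are written with the generating affine preserved bit-exactly;
masks go out as uint8, parameter maps as float32.  Every generated dataset
can be accompanied by a YAML sidecar echoing the generation parameters.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
import nibabel as nib
import numpy as np
import yaml

from .tensor import DiffusionAcquisition, ScalarVolume
from .tracking import StreamlineSet

__all__ = [
    "save_nifti", "load_nifti", "save_mask", "load_mask",
    "save_bvals_bvecs", "load_bvals_bvecs",
    "save_acquisition", "load_acquisition",
    "save_trk", "load_trk",
    "save_streamlines_jsonl", "load_streamlines_jsonl",
    "write_yaml_sidecar",
]


def save_nifti(path, values: np.ndarray, affine: np.ndarray,
               dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(values).astype(dtype), np.asarray(affine))
    nib.save(img, str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_mask(path, mask: np.ndarray, affine: np.ndarray) -> None:
    save_nifti(path, np.asarray(mask).astype(np.uint8), affine, dtype=np.uint8)


def load_mask(path):
    data, affine = load_nifti(path)
    return data.astype(bool), affine


def save_bvals_bvecs(prefix, bvals: np.ndarray, bvecs: np.ndarray,
                     s_per_mm2: bool = True) -> None:
    """FSL-style `bvals` / `bvecs` text files (bvecs as 3 rows).

    Internal b-values are ms/um^2; on disk the FSL convention of s/mm^2 is
    used unless ``s_per_mm2`` is False.
    """
    prefix = Path(prefix)
    scale = 1000.0 if s_per_mm2 else 1.0
    np.savetxt(prefix.with_suffix(".bval"),
               np.atleast_2d(np.asarray(bvals) * scale), fmt="%.1f")
    np.savetxt(prefix.with_suffix(".bvec"),
               np.asarray(bvecs).T, fmt="%.8f")


def load_bvals_bvecs(prefix, s_per_mm2: bool = True):
    prefix = Path(prefix)
    bvals = np.loadtxt(prefix.with_suffix(".bval")).ravel()
    bvecs = np.loadtxt(prefix.with_suffix(".bvec"))
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if s_per_mm2:
        bvals = bvals / 1000.0
    return bvals, bvecs


def save_acquisition(prefix, acq: DiffusionAcquisition) -> None:
    """DWI as <prefix>.nii.gz plus <prefix>.bval / <prefix>.bvec."""
    prefix = Path(prefix)
    save_nifti(str(prefix) + ".nii.gz", acq.signal, acq.affine)
    save_bvals_bvecs(prefix, acq.bvals, acq.bvecs)


def load_acquisition(prefix) -> DiffusionAcquisition:
    prefix = Path(prefix)
    signal, affine = load_nifti(str(prefix) + ".nii.gz")
    bvals, bvecs = load_bvals_bvecs(prefix)
    voxel_size = tuple(np.abs(np.diag(affine)[:3]))
    return DiffusionAcquisition(
        signal=np.asarray(signal, dtype=float),
        bvals=bvals, bvecs=bvecs,
        voxel_size=voxel_size, affine=affine,
    )


def save_trk(path, streams: StreamlineSet,
             voxel_size=(2.0, 2.0, 2.0)) -> None:
    """Write streamlines in the TrackVis .trk format (world-mm points)."""
    tractogram = nib.streamlines.Tractogram(
        streams.streamlines, affine_to_rasmm=np.eye(4)
    )
    header = {
        "dimensions": np.asarray(streams.grid_shape, dtype=np.int16),
        "voxel_sizes": np.asarray(voxel_size, dtype=np.float32),
        "voxel_to_rasmm": np.asarray(streams.affine, dtype=np.float32),
        "voxel_order": "RAS",
    }
    nib.streamlines.save(tractogram, str(path),
                         header=header)


def load_trk(path) -> StreamlineSet:
    trk = nib.streamlines.load(str(path))
    affine = np.asarray(trk.header["voxel_to_rasmm"], dtype=float)
    shape = tuple(int(d) for d in trk.header["dimensions"])
    return StreamlineSet(
        [np.asarray(s, dtype=float) for s in trk.tractogram.streamlines],
        affine, shape,
    )


def save_streamlines_jsonl(path, streams: StreamlineSet) -> None:
    """Plain-text fallback: one JSON array of [x, y, z] points per line."""
    with open(path, "w") as fh:
        meta = {"affine": np.asarray(streams.affine).tolist(),
                "grid_shape": list(streams.grid_shape)}
        fh.write(json.dumps({"header": meta}) + "\n")
        for s in streams.streamlines:
            fh.write(json.dumps(np.asarray(s).round(6).tolist()) + "\n")


def load_streamlines_jsonl(path) -> StreamlineSet:
    with open(path) as fh:
        header = json.loads(fh.readline())["header"]
        lines = [np.asarray(json.loads(line), dtype=float)
                 for line in fh if line.strip()]
    return StreamlineSet(lines, np.asarray(header["affine"]),
                         tuple(header["grid_shape"]))


def _yamlable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _yamlable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    return obj


def write_yaml_sidecar(path, params) -> None:
    """Echo generation parameters (dataclass or dict) next to the data."""
    with open(path, "w") as fh:
        yaml.safe_dump(_yamlable(params), fh, sort_keys=False)
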