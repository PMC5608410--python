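"""Atlas-ROI tract segmentation and per-tract summary metrics.

Each tract is defined by an inclusion mask (the full atlas tract volume, an
"AND"-ROI) and an exclusion shell (the tract dilated by ~5 voxels minus the
tract itself, a "NOT"-ROI).  A whole-brain streamline is assigned to the
tract when at least one of its vertices falls inside the AND-ROI and none
fall inside the shell; the shell removes streamlines belonging to adjacent
bundles that merely graze the tract.  Tract-level MD and FA are means over
the set of unique voxels visited by the retained streamlines.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional

import numpy as np
from scipy import ndimage

from .tensor import ScalarVolume
from .tracking import StreamlineSet, world_to_voxel

__all__ = [
    "TractDefinition",
    "TractSummary",
    "TractNotReconstructedError",
    "build_and_roi",
    "build_not_shell",
    "make_tract_definition",
    "segment_tract",
    "tract_summary",
    "visited_voxels",
]


class TractNotReconstructedError(RuntimeError):
    """Raised when no streamline survives segmentation for a tract."""

    def __init__(self, name: str):
        super().__init__(f"tract not reconstructed: {name!r} "
                         "(no streamlines retained)")
        self.tract = name


@dataclasses.dataclass
class TractDefinition:
    name: str
    and_roi: np.ndarray        # bool, subject grid
    not_shell: np.ndarray      # bool, disjoint from and_roi
    dilation_radius: int = 5

    def __post_init__(self) -> None:
        if np.any(self.and_roi & self.not_shell):
            raise ValueError(
                f"tract {self.name!r}: AND-ROI and NOT-shell overlap"
            )


@dataclasses.dataclass
class TractSummary:
    name: str
    n_streamlines: int
    mean_md: float
    mean_fa: float
    n_voxels: int


def build_and_roi(
    atlas_label_mask: np.ndarray,
    transform: np.ndarray,
    output_shape: Optional[tuple] = None,
    name: str = "tract",
) -> np.ndarray:
    """Resample an atlas label into the subject grid by nearest neighbor.

    ``transform`` is the 4x4 voxel-to-voxel affine mapping atlas indices to
    subject indices (identity when the grids coincide).
    """
    atlas = np.asarray(atlas_label_mask).astype(bool)
    transform = np.asarray(transform, dtype=float)
    if output_shape is None:
        output_shape = atlas.shape
    inv = np.linalg.inv(transform)
    # scipy's affine_transform maps output coords through `matrix` to input
    out = ndimage.affine_transform(
        atlas.astype(np.uint8),
        matrix=inv[:3, :3],
        offset=inv[:3, 3],
        output_shape=output_shape,
        order=0,
        mode="constant",
        cval=0,
    ).astype(bool)
    if not out.any():
        raise ValueError(
            f"AND-ROI for tract {name!r} is empty after resampling to the "
            "subject grid"
        )
    return out


def build_not_shell(tract_mask: np.ndarray, radius: int = 5) -> np.ndarray:
    """Shell ROI: the tract dilated by ``radius`` voxels minus the tract.

    Dilation is ``radius`` iterations of 26-connected binary dilation, i.e. a
    Chebyshev ball of the given radius.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    mask = np.asarray(tract_mask).astype(bool)
    if not mask.any():
        return np.zeros_like(mask)
    dil = ndimage.binary_dilation(
        mask, structure=np.ones((3, 3, 3), dtype=bool), iterations=radius
    )
    return dil & ~mask


def make_tract_definition(
    name: str, tract_mask: np.ndarray, radius: int = 5
) -> TractDefinition:
    """Convenience: AND-ROI = the mask itself, shell built around it."""
    return TractDefinition(
        name=name,
        and_roi=np.asarray(tract_mask).astype(bool),
        not_shell=build_not_shell(tract_mask, radius),
        dilation_radius=radius,
    )


def _vertex_indices(streams: StreamlineSet):
    """Per-streamline rounded voxel indices (clipped) and in-bounds flags."""
    shape = np.array(streams.grid_shape)
    for s in streams.streamlines:
        vox = world_to_voxel(streams.affine, s)
        idx = np.round(vox).astype(int)
        inb = np.all((idx >= 0) & (idx < shape), axis=1)
        yield np.clip(idx, 0, shape - 1), inb


def segment_tract(streams: StreamlineSet, tdef: TractDefinition) -> StreamlineSet:
    """Retain streamlines hitting the AND-ROI and avoiding the NOT-shell."""
    kept = []
    for s, (idx, inb) in zip(streams.streamlines, _vertex_indices(streams)):
        in_and = tdef.and_roi[idx[:, 0], idx[:, 1], idx[:, 2]] & inb
        in_not = tdef.not_shell[idx[:, 0], idx[:, 1], idx[:, 2]] & inb
        if in_and.any() and not in_not.any():
            kept.append(s)
    return StreamlineSet(kept, streams.affine, streams.grid_shape)


def visited_voxels(streams: StreamlineSet) -> np.ndarray:
    """Boolean volume of voxels visited by any streamline vertex."""
    vol = np.zeros(streams.grid_shape, dtype=bool)
    for idx, inb in _vertex_indices(streams):
        good = idx[inb]
        vol[good[:, 0], good[:, 1], good[:, 2]] = True
    return vol


def tract_summary(
    md: ScalarVolume,
    fa: ScalarVolume,
    segmented: StreamlineSet,
    name: str,
) -> TractSummary:
    """Mean MD/FA over the unique voxels visited by the segmented bundle."""
    if len(segmented) == 0:
        raise TractNotReconstructedError(name)
    vis = visited_voxels(segmented)
    vis &= md.valid_mask
    n_vox = int(vis.sum())
    if n_vox == 0:
        raise TractNotReconstructedError(name)
    return TractSummary(
        name=name,
        n_streamlines=len(segmented),
        mean_md=float(md.values[vis].mean()),
        mean_fa=float(fa.values[vis].mean()),
        n_voxels=n_vox,
    )


def qc_report(
    definitions: Dict[str, TractDefinition],
    segmented: Dict[str, StreamlineSet],
) -> Dict[str, dict]:
    """Per-tract streamline counts and visitation sizes (no auto-editing)."""
    report = {}
    for name, tdef in definitions.items():
        seg = segmented.get(name)
        report[name] = {
            "n_streamlines": 0 if seg is None else len(seg),
            "and_roi_voxels": int(tdef.and_roi.sum()),
            "shell_voxels": int(tdef.not_shell.sum()),
            "visited_voxels": (
                0 if seg is None or len(seg) == 0
                else int(visited_voxels(seg).sum())
            ),
        }
    return report
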