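"""Deterministic whole-brain streamline tractography.

Fixed-step Euler integration along the principal eigenvector field, seeded
at the center of every voxel whose FA reaches the threshold, propagated in
both directions from each seed.  Propagation stops when the current voxel's
FA falls below the threshold, when the turn between consecutive steps
exceeds the angle threshold, when the streamline leaves the volume, or when
it reaches the maximum length.  The default direction lookup is the FACT
convention — the principal eigenvector of the voxel containing the current
point — with trilinear interpolation of the six tensor components available
as an option.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional

import numpy as np

from .tensor import EigenField, ScalarVolume, TensorField, tensor_from_components

__all__ = ["TrackingParams", "StreamlineSet", "track_whole_brain"]


@dataclasses.dataclass
class TrackingParams:
    """Tracking thresholds and step geometry (lengths in mm)."""

    fa_threshold: float = 0.2
    angle_threshold: float = 30.0       # degrees per step
    step_size: float = 1.0
    min_length: float = 10.0
    max_length: float = 250.0
    seeds_per_voxel: int = 1
    interpolation: str = "nearest"      # "nearest" (FACT) | "trilinear"

    def __post_init__(self) -> None:
        if not 0.0 < self.fa_threshold < 1.0:
            raise ValueError("fa_threshold must be in (0, 1)")
        if not 0.0 < self.angle_threshold < 90.0:
            raise ValueError("angle_threshold must be in (0, 90) degrees")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.interpolation not in ("nearest", "trilinear"):
            raise ValueError("interpolation must be 'nearest' or 'trilinear'")


@dataclasses.dataclass
class StreamlineSet:
    """Streamlines as (k, 3) world-mm point arrays plus the grid geometry."""

    streamlines: List[np.ndarray]
    affine: np.ndarray
    grid_shape: tuple

    def __len__(self) -> int:
        return len(self.streamlines)

    def lengths(self) -> np.ndarray:
        return np.array([
            np.linalg.norm(np.diff(s, axis=0), axis=1).sum()
            for s in self.streamlines
        ])


def world_to_voxel(affine: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """World mm -> continuous voxel coordinates (0-based)."""
    inv = np.linalg.inv(affine)
    pts = np.atleast_2d(pts)
    return pts @ inv[:3, :3].T + inv[:3, 3]


def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    ijk = np.atleast_2d(ijk).astype(float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def _nearest_index(vox: np.ndarray, shape) -> tuple[np.ndarray, np.ndarray]:
    """Round continuous voxel coords; also report in-bounds status."""
    idx = np.round(vox).astype(int)
    ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=-1)
    idx_clipped = np.clip(idx, 0, np.array(shape) - 1)
    return idx_clipped, ok


def _trilinear_tensor(tensor6: np.ndarray, vox: np.ndarray) -> np.ndarray:
    """Trilinearly interpolated (n, 6) tensor components at voxel coords."""
    shape = np.array(tensor6.shape[:3])
    p = np.clip(vox, 0.0, shape - 1.000001)
    i0 = np.floor(p).astype(int)
    f = p - i0
    out = np.zeros((vox.shape[0], 6))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[:, 0] if dx else 1 - f[:, 0])
                    * (f[:, 1] if dy else 1 - f[:, 1])
                    * (f[:, 2] if dz else 1 - f[:, 2])
                )
                ii = np.minimum(i0 + [dx, dy, dz], shape - 1)
                out += w[:, None] * tensor6[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


class _DirectionField:
    """Principal-direction lookup at arbitrary world points."""

    def __init__(self, ef: EigenField, tf: Optional[TensorField], mode: str):
        self.ef = ef
        self.tf = tf
        self.mode = mode
        self.shape = ef.eigenvalues.shape[:3]
        self.affine = ef.affine if ef.affine is not None else np.eye(4)

    def __call__(self, pts_world: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Directions (n,3) and validity flags at world points."""
        vox = world_to_voxel(self.affine, pts_world)
        idx, inb = _nearest_index(vox, self.shape)
        if self.mode == "nearest" or self.tf is None:
            d = self.ef.principal_direction[idx[:, 0], idx[:, 1], idx[:, 2]]
        else:
            comp = _trilinear_tensor(self.tf.tensor, vox)
            w, v = np.linalg.eigh(tensor_from_components(comp))
            d = v[:, :, 2]
        norms = np.linalg.norm(d, axis=1)
        ok = inb & (norms > 0)
        d = np.where(norms[:, None] > 0, d / np.maximum(norms, 1e-30)[:, None], 0.0)
        return d, ok


def _half_tracks(
    field: _DirectionField,
    fa_vals: np.ndarray,
    seeds: np.ndarray,
    init_dirs: np.ndarray,
    params: TrackingParams,
    max_steps: int,
) -> list[list[np.ndarray]]:
    """Propagate all seeds simultaneously in one direction.

    Returns, per seed, the list of points *after* the seed point.
    """
    n = seeds.shape[0]
    shape = field.shape
    cos_thr = np.cos(np.deg2rad(params.angle_threshold))
    pos = seeds.copy()
    dirs = init_dirs.copy()
    active = np.ones(n, dtype=bool)
    tracks: list[list[np.ndarray]] = [[] for _ in range(n)]
    for _ in range(max_steps):
        if not active.any():
            break
        ia = np.flatnonzero(active)
        cand = pos[ia] + params.step_size * dirs[ia]
        vox = world_to_voxel(field.affine, cand)
        idx, inb = _nearest_index(vox, shape)
        fa_ok = fa_vals[idx[:, 0], idx[:, 1], idx[:, 2]] >= params.fa_threshold
        keep = inb & fa_ok
        stopped = ia[~keep]
        active[stopped] = False
        moved = ia[keep]
        if moved.size == 0:
            continue
        cand = cand[keep]
        pos[moved] = cand
        for j, p in zip(moved, cand):
            tracks[j].append(p)
        # next direction at the new point, sign-aligned with travel direction
        new_d, ok = field(cand)
        dots = np.einsum("ij,ij->i", new_d, dirs[moved])
        new_d = np.where(dots[:, None] < 0, -new_d, new_d)
        dots = np.abs(dots)
        turn_ok = dots >= cos_thr - 1e-12
        good = ok & turn_ok
        active[moved[~good]] = False
        dirs[moved[good]] = new_d[good]
    return tracks


def track_whole_brain(
    ef: EigenField,
    fa: ScalarVolume,
    params: TrackingParams | None = None,
    tf: Optional[TensorField] = None,
    rng: Optional[np.random.Generator] = None,
) -> StreamlineSet:
    """Deterministic tractography over the whole FA-suprathreshold volume.

    Seeds are placed at the center of every voxel with FA >= ``fa_threshold``
    (additional seeds per voxel are uniformly jittered inside the voxel and
    require ``rng``).  Each seed is propagated in both directions along the
    principal eigenvector and the two half-tracks are concatenated; results
    shorter than ``min_length`` are discarded.  ``tf`` is only needed for
    ``interpolation="trilinear"``.
    """
    if params is None:
        params = TrackingParams()
    if ef.eigenvalues.shape[:3] != fa.values.shape:
        raise ValueError("EigenField and FA map must share the same grid")
    affine = ef.affine if ef.affine is not None else np.eye(4)
    fa_vals = np.where(fa.valid_mask, fa.values, 0.0)

    seed_idx = np.argwhere(fa_vals >= params.fa_threshold)
    if seed_idx.size == 0:
        return StreamlineSet([], affine, fa_vals.shape)
    seeds = voxel_to_world(affine, seed_idx)
    if params.seeds_per_voxel > 1:
        if rng is None:
            rng = np.random.default_rng(0)
        extra = []
        half = np.abs(np.diag(affine)[:3]) / 2.0
        for _ in range(params.seeds_per_voxel - 1):
            jitter = rng.uniform(-half, half, size=seeds.shape)
            extra.append(voxel_to_world(affine, seed_idx) + jitter)
        seeds = np.concatenate([seeds] + extra, axis=0)

    field = _DirectionField(ef, tf, params.interpolation)
    d0, ok = field(seeds)
    seeds = seeds[ok]
    d0 = d0[ok]
    max_steps = int(np.ceil(params.max_length / 2.0 / params.step_size))

    fwd = _half_tracks(field, fa_vals, seeds, d0, params, max_steps)
    bwd = _half_tracks(field, fa_vals, seeds, -d0, params, max_steps)

    streamlines: List[np.ndarray] = []
    for i in range(seeds.shape[0]):
        pts = list(reversed(bwd[i])) + [seeds[i]] + fwd[i]
        if len(pts) < 2:
            continue
        arr = np.asarray(pts)
        length = np.linalg.norm(np.diff(arr, axis=0), axis=1).sum()
        if length >= params.min_length:
            streamlines.append(arr)
    return StreamlineSet(streamlines, affine, fa_vals.shape)
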