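"""Image-level diffusion phantoms: tensor-field tract bundles, lesions, DWI.

A phantom is a regular voxel grid carrying a ground-truth diffusion tensor in
every brain voxel: an isotropic background, one or more anisotropic tract
bundles (straight cylinders or circular arcs) whose tensors are oriented
along the local bundle tangent, and optional lesions — voxels whose
eigenvalues are swapped for a higher-MD / lower-FA set, emulating white
matter hyperintensities.  Lesion voxels are drawn preferentially near a
"ventricular" slab at the grid center with probability ∝ exp(-d/tau) in the
distance d to that slab, mimicking the periventricular predilection of real
lesions without any anatomy.

The companion DWI simulator produces magnitude signals under the
mono-exponential tensor model with Rician noise,
S = |S0 exp(-b g^T D g) + complex N(0, sigma^2)|, at the default acquisition
of one b=0 volume plus 64 diffusion directions at b = 1 ms/um^2 and 2 mm
isotropic voxels.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.ndimage import distance_transform_edt

from .tensor import (
    DiffusionAcquisition,
    TensorField,
    components_from_tensor,
    md_fa_from_eigenvalues,
)

__all__ = [
    "TractGeometry",
    "PhantomSpec",
    "Phantom",
    "make_phantom",
    "simulate_dwi",
    "fibonacci_directions",
    "default_gradient_scheme",
]


@dataclasses.dataclass
class TractGeometry:
    """Geometry of one synthetic bundle.

    ``shape`` is ``"straight"`` (a cylinder along ``axis`` through ``offset``)
    or ``"arc"`` (a quarter-circle of radius ``arc_radius_mm`` in the plane
    spanned by ``axis`` and the next axis, centered at ``offset``).  All
    coordinates are world mm; ``cross_radius_mm`` is the bundle half-width.
    """

    name: str
    shape: str = "straight"
    axis: int = 0
    offset: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    cross_radius_mm: float = 6.0
    length_mm: Optional[float] = None          # straight bundles; None = full span
    arc_radius_mm: float = 24.0


@dataclasses.dataclass
class PhantomSpec:
    """Everything needed to build one phantom.

    Eigenvalues are in um^2/ms.  ``lesion_load_target`` is the lesioned
    fraction of the brain mask; placement is biased toward the central
    "ventricular" slab with decay length ``lesion_site_tau_mm``.
    ``lesion_within`` optionally restricts lesions to one named bundle.
    """

    grid_shape: Tuple[int, int, int] = (40, 40, 40)
    voxel_size: float = 2.0
    tract_geometries: Optional[List[TractGeometry]] = None
    lesion_load_target: float = 0.0
    lesion_site_tau_mm: float = 10.0
    lesion_within: Optional[str] = None
    nawm_eigenvalues: Tuple[float, float, float] = (1.5, 0.4, 0.3)
    background_eigenvalue: float = 0.7
    lesion_eigenvalues: Tuple[float, float, float] = (1.6, 0.9, 0.7)
    s0: float = 1000.0
    snr_b0: Optional[float] = 30.0             # None = noise-free
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lesion_load_target < 1.0:
            raise ValueError("lesion_load_target must be in [0, 1)")
        md_n, fa_n = md_fa_from_eigenvalues(np.array(self.nawm_eigenvalues))
        md_l, fa_l = md_fa_from_eigenvalues(np.array(self.lesion_eigenvalues))
        if not (md_l > md_n and fa_l < fa_n):
            raise ValueError(
                "lesion_eigenvalues must yield higher MD and lower FA than "
                "nawm_eigenvalues"
            )
        if self.tract_geometries is None:
            self.tract_geometries = default_tract_geometries(
                self.grid_shape, self.voxel_size
            )


def default_tract_geometries(grid_shape, voxel_size) -> List[TractGeometry]:
    """Two parallel-ish straight bundles: an x-aligned 'slf' analog near the
    center slab and a z-aligned 'cst' analog off to one side."""
    ext = tuple(n * voxel_size for n in grid_shape)
    return [
        TractGeometry(
            name="bundle_a", shape="straight", axis=0,
            offset=(0.0, 0.5 * ext[1], 0.40 * ext[2]),
            cross_radius_mm=6.0,
        ),
        TractGeometry(
            name="bundle_b", shape="straight", axis=2,
            offset=(0.30 * ext[0], 0.25 * ext[1], 0.0),
            cross_radius_mm=6.0,
        ),
    ]


@dataclasses.dataclass
class Phantom:
    """Ground truth produced by :func:`make_phantom`."""

    truth: TensorField
    eigenvalue_field: np.ndarray        # (X,Y,Z,3) truth eigenvalues
    tract_masks: Dict[str, np.ndarray]
    lesion_mask: np.ndarray
    brain_mask: np.ndarray
    ventricle_mask: np.ndarray
    spec: PhantomSpec


def _voxel_centers(grid_shape, voxel_size):
    ax = [ (np.arange(n) + 0.5) * voxel_size for n in grid_shape ]
    return np.meshgrid(*ax, indexing="ij")


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Orthonormal frame whose first column is ``direction``."""
    d = direction / np.linalg.norm(direction)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(d, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(d, e2)
    return np.stack([d, e2, e3], axis=1)


def _tensor_from_axis(direction, eigenvalues) -> np.ndarray:
    R = _rotation_to(np.asarray(direction, dtype=float))
    return R @ np.diag(eigenvalues) @ R.T


def _rasterize_tract(geom: TractGeometry, grid_shape, voxel_size):
    """Binary mask plus per-voxel tangent direction for one bundle."""
    X, Y, Z = _voxel_centers(grid_shape, voxel_size)
    ext = tuple(n * voxel_size for n in grid_shape)
    coords = [X, Y, Z]
    if geom.shape == "straight":
        a = geom.axis
        others = [i for i in range(3) if i != a]
        d2 = sum((coords[i] - geom.offset[i]) ** 2 for i in others)
        mask = d2 <= geom.cross_radius_mm ** 2
        if geom.length_mm is not None:
            lo = geom.offset[a]
            mask &= (coords[a] >= lo) & (coords[a] <= lo + geom.length_mm)
            if lo < 0 or lo + geom.length_mm > ext[a]:
                raise ValueError(
                    f"tract '{geom.name}' extends outside the grid along "
                    f"axis {a}"
                )
        for i in others:
            if (geom.offset[i] - geom.cross_radius_mm < 0
                    or geom.offset[i] + geom.cross_radius_mm > ext[i]):
                raise ValueError(
                    f"tract '{geom.name}' cross-section exceeds the grid "
                    f"along axis {i}"
                )
        tangent = np.zeros(grid_shape + (3,))
        tangent[..., a] = 1.0
        return mask, tangent
    if geom.shape == "arc":
        a = geom.axis
        b = (a + 1) % 3
        c = 3 - a - b
        u = coords[a] - geom.offset[a]
        v = coords[b] - geom.offset[b]
        w = coords[c] - geom.offset[c]
        r = np.hypot(u, v)
        in_plane = np.abs(w) <= geom.cross_radius_mm
        quarter = (u >= 0) & (v >= 0)
        mask = (np.abs(r - geom.arc_radius_mm) <= geom.cross_radius_mm) \
            & in_plane & quarter
        hi = geom.arc_radius_mm + geom.cross_radius_mm
        for i, off in ((a, geom.offset[a]), (b, geom.offset[b])):
            if off + hi > ext[i] or off < 0:
                raise ValueError(
                    f"tract '{geom.name}' arc exceeds the grid along axis {i}"
                )
        tangent = np.zeros(grid_shape + (3,))
        with np.errstate(invalid="ignore", divide="ignore"):
            tu = np.where(r > 0, -v / np.maximum(r, 1e-12), 1.0)
            tv = np.where(r > 0, u / np.maximum(r, 1e-12), 0.0)
        tangent[..., a] = tu
        tangent[..., b] = tv
        return mask, tangent
    raise ValueError(f"unknown tract shape {geom.shape!r}")


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build the ground-truth tensor field, tract/lesion/brain masks.

    Lesion voxels are sampled without replacement with probability
    ∝ exp(-d/tau), d the Euclidean distance (mm) to the central ventricular
    slab, until the requested fraction of the brain mask is lesioned (the
    voxel count is rounded, so the achieved fraction is within one voxel of
    the target).  Lesion tensors keep the local fiber orientation but carry
    ``lesion_eigenvalues``.
    """
    rng = np.random.default_rng(spec.seed)
    gs = tuple(spec.grid_shape)
    vs = float(spec.voxel_size)

    brain = np.ones(gs, dtype=bool)
    brain[0, :, :] = brain[-1, :, :] = False
    brain[:, 0, :] = brain[:, -1, :] = False
    brain[:, :, 0] = brain[:, :, -1] = False

    # "ventricular" region: a small central slab
    vent = np.zeros(gs, dtype=bool)
    cx, cy, cz = (n // 2 for n in gs)
    vent[max(cx - 2, 0):cx + 2, max(cy - 2, 0):cy + 2, :] = True
    vent &= brain

    evals = np.zeros(gs + (3,), dtype=float)
    evals[brain] = spec.background_eigenvalue
    tangents = np.zeros(gs + (3,), dtype=float)
    tangents[..., 0] = 1.0

    tract_masks: Dict[str, np.ndarray] = {}
    for geom in spec.tract_geometries:
        mask, tangent = _rasterize_tract(geom, gs, vs)
        mask &= brain
        tract_masks[geom.name] = mask
        evals[mask] = spec.nawm_eigenvalues
        tangents[mask] = tangent[mask]

    # lesions
    lesion = np.zeros(gs, dtype=bool)
    n_target = int(round(spec.lesion_load_target * brain.sum()))
    if n_target > 0:
        if spec.lesion_within is not None:
            candidates = tract_masks[spec.lesion_within] & brain
        else:
            candidates = brain
        dist = distance_transform_edt(~vent, sampling=vs)
        idx = np.flatnonzero(candidates)
        if n_target > idx.size:
            raise ValueError(
                "lesion_load_target exceeds the available candidate volume"
            )
        w = np.exp(-dist.ravel()[idx] / spec.lesion_site_tau_mm)
        chosen = rng.choice(idx, size=n_target, replace=False, p=w / w.sum())
        lesion.ravel()[chosen] = True
        evals[lesion] = spec.lesion_eigenvalues

    # assemble tensors: orient along local tangent
    flat_dirs = tangents.reshape(-1, 3)
    flat_evals = evals.reshape(-1, 3)
    tensor6 = np.zeros((flat_dirs.shape[0], 6), dtype=float)
    in_brain = brain.ravel()
    # group voxels by direction to vectorize the rotation products
    dirs_in = flat_dirs[in_brain]
    evals_in = flat_evals[in_brain]
    uniq, inv = np.unique(dirs_in.round(9), axis=0, return_inverse=True)
    t6_in = np.empty((dirs_in.shape[0], 6))
    for k, d in enumerate(uniq):
        sel = inv == k
        R = _rotation_to(d)
        lam = evals_in[sel]                       # (n,3)
        D = np.einsum("ij,nj,kj->nik", R, lam, R)
        t6_in[sel] = components_from_tensor(D)
    tensor6[in_brain] = t6_in

    affine = np.diag([vs, vs, vs, 1.0])
    truth = TensorField(
        s0=np.where(brain, spec.s0, 0.0),
        tensor=tensor6.reshape(gs + (6,)),
        valid_mask=brain,
        affine=affine,
        voxel_size=(vs, vs, vs),
    )
    return Phantom(
        truth=truth,
        eigenvalue_field=evals,
        tract_masks=tract_masks,
        lesion_mask=lesion,
        brain_mask=brain,
        ventricle_mask=vent,
        spec=spec,
    )


def fibonacci_directions(n: int) -> np.ndarray:
    """n roughly uniform unit vectors on the sphere (golden-spiral points)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5.0 ** 0.5) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def default_gradient_scheme(n_dirs: int = 64):
    """One b=0 volume plus ``n_dirs`` directions at b = 1 ms/um^2."""
    bvals = np.concatenate([[0.0], np.ones(n_dirs)])
    bvecs = np.concatenate([[[0.0, 0.0, 0.0]], fibonacci_directions(n_dirs)])
    return bvals, bvecs


def simulate_dwi(
    truth: TensorField,
    spec: PhantomSpec,
    bvals: Optional[np.ndarray] = None,
    bvecs: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> DiffusionAcquisition:
    """Simulate magnitude DWI from a truth tensor field.

    Signals follow S = S0 exp(-b g^T D g); when ``spec.snr_b0`` is finite,
    Rician noise is applied channel-wise as |S + n1 + i n2| with
    n1, n2 ~ N(0, sigma^2) and sigma = mean brain S0 / snr_b0.
    """
    if bvals is None or bvecs is None:
        bvals, bvecs = default_gradient_scheme()
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float).copy()
    if np.any(bvals < 0):
        raise ValueError("negative b-values are not allowed")
    norms = np.linalg.norm(bvecs, axis=1)
    dw = bvals > 0
    bad = dw & (np.abs(norms - 1.0) > 1e-6)
    if np.any(bad):
        warnings.warn(
            f"{bad.sum()} gradient direction(s) were not unit-norm; "
            "normalizing", stacklevel=2,
        )
        bvecs[bad] = bvecs[bad] / norms[bad, None]

    # quadratic forms g^T D g for every voxel and direction
    dxx, dyy, dzz, dxy, dxz, dyz = (truth.tensor[..., i] for i in range(6))
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    quad = (
        dxx[..., None] * gx ** 2
        + dyy[..., None] * gy ** 2
        + dzz[..., None] * gz ** 2
        + 2 * dxy[..., None] * gx * gy
        + 2 * dxz[..., None] * gx * gz
        + 2 * dyz[..., None] * gy * gz
    )
    signal = truth.s0[..., None] * np.exp(-bvals * quad)

    snr = spec.snr_b0
    if snr is not None and np.isfinite(snr):
        if rng is None:
            rng = np.random.default_rng(spec.seed + 1)
        s0_brain = truth.s0[truth.valid_mask]
        sigma = (s0_brain.mean() if s0_brain.size else spec.s0) / snr
        n1 = rng.normal(0.0, sigma, size=signal.shape)
        n2 = rng.normal(0.0, sigma, size=signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2 ** 2)

    return DiffusionAcquisition(
        signal=signal,
        bvals=bvals,
        bvecs=bvecs,
        voxel_size=truth.voxel_size,
        affine=truth.affine,
    )
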