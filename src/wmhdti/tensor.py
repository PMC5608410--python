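"""Per-voxel diffusion tensor estimation and scalar maps.

The diffusion tensor D (3x3 symmetric, units um^2/ms) is estimated from the
log-linearized signal model

    ln S(b, g) = ln S0 - b * g^T D g

by a two-pass weighted linear least-squares fit: an ordinary least-squares
pass on log-signals followed by a weighted pass whose weights are the squared
predicted signals from the first pass.  The second pass corrects for the
heteroscedasticity introduced by the log transform (the variance of ln S is
approximately sigma^2 / S^2 for additive noise of variance sigma^2).

b-values are carried in ms/um^2 so that 1000 s/mm^2 is stored as 1.0 and
diffusivities come out directly in um^2/ms.
"""

from __future__ import annotations

import dataclasses
from typing import Tuple

import numpy as np

__all__ = [
    "DiffusionAcquisition",
    "TensorField",
    "EigenField",
    "ScalarVolume",
    "design_matrix",
    "fit_wlls",
    "eigendecompose",
    "scalar_maps",
    "tensor_from_components",
    "components_from_tensor",
]

# ordering of the 6 unique tensor components everywhere in this package
TENSOR_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclasses.dataclass
class DiffusionAcquisition:
    """A 4-D diffusion-weighted dataset plus its encoding scheme.

    Parameters
    ----------
    signal : ndarray, shape (X, Y, Z, M)
        Non-negative magnitude signal, one volume per measurement.
    bvals : ndarray, shape (M,)
        b-values in ms/um^2 (1000 s/mm^2 == 1.0).
    bvecs : ndarray, shape (M, 3)
        Unit gradient directions; arbitrary for b = 0 rows.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    affine : ndarray, shape (4, 4)
        Voxel-to-world (mm) transform.
    """

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    voxel_size: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, measurement)")
        m = self.signal.shape[-1]
        if self.bvals.shape != (m,) or self.bvecs.shape != (m, 3):
            raise ValueError("bvals/bvecs inconsistent with signal shape")
        if m < 7:
            raise ValueError("need at least 7 measurements to fit a tensor")
        if not np.any(self.bvals == 0):
            raise ValueError("need at least one b=0 measurement")
        if np.any(self.bvals < 0):
            raise ValueError("negative b-values are not allowed")
        if self.affine is None:
            aff = np.eye(4)
            aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
            self.affine = aff

    @property
    def n_measurements(self) -> int:
        return self.signal.shape[-1]


@dataclasses.dataclass
class TensorField:
    """Per-voxel tensor fit: S0 amplitude and the 6 unique components."""

    s0: np.ndarray                # (X, Y, Z)
    tensor: np.ndarray            # (X, Y, Z, 6) ordered as TENSOR_COMPONENTS
    valid_mask: np.ndarray        # (X, Y, Z) bool
    affine: np.ndarray | None = None
    voxel_size: Tuple[float, float, float] = (2.0, 2.0, 2.0)


@dataclasses.dataclass
class EigenField:
    """Sorted eigenvalues (descending) and the principal eigenvector."""

    eigenvalues: np.ndarray          # (X, Y, Z, 3), lambda1 >= lambda2 >= lambda3
    principal_direction: np.ndarray  # (X, Y, Z, 3), unit norm on valid voxels
    valid_mask: np.ndarray
    affine: np.ndarray | None = None
    voxel_size: Tuple[float, float, float] = (2.0, 2.0, 2.0)


@dataclasses.dataclass
class ScalarVolume:
    """A 3-D scalar parameter map (MD in um^2/ms, or unitless FA)."""

    values: np.ndarray
    kind: str                     # "MD" | "FA"
    valid_mask: np.ndarray
    affine: np.ndarray | None = None
    voxel_size: Tuple[float, float, float] = (2.0, 2.0, 2.0)


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Build the M x 7 log-linear DTI design matrix.

    Row i is ``[1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz,
    -2b gy gz]`` for the parameter vector
    ``[ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]``.
    """
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if bvals.shape[0] != bvecs.shape[0]:
        raise ValueError("bvals and bvecs must have the same length")
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    b = bvals
    cols = [
        np.ones_like(b),
        -b * gx * gx,
        -b * gy * gy,
        -b * gz * gz,
        -2.0 * b * gx * gy,
        -2.0 * b * gx * gz,
        -2.0 * b * gy * gz,
    ]
    return np.stack(cols, axis=1)


def tensor_from_components(comp: np.ndarray) -> np.ndarray:
    """(..., 6) component vector -> (..., 3, 3) symmetric matrix."""
    comp = np.asarray(comp, dtype=float)
    out = np.empty(comp.shape[:-1] + (3, 3), dtype=float)
    dxx, dyy, dzz, dxy, dxz, dyz = (comp[..., i] for i in range(6))
    out[..., 0, 0] = dxx
    out[..., 1, 1] = dyy
    out[..., 2, 2] = dzz
    out[..., 0, 1] = out[..., 1, 0] = dxy
    out[..., 0, 2] = out[..., 2, 0] = dxz
    out[..., 1, 2] = out[..., 2, 1] = dyz
    return out


def components_from_tensor(mat: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric matrix -> (..., 6) component vector."""
    mat = np.asarray(mat, dtype=float)
    return np.stack(
        [mat[..., 0, 0], mat[..., 1, 1], mat[..., 2, 2],
         mat[..., 0, 1], mat[..., 0, 2], mat[..., 1, 2]],
        axis=-1,
    )


def fit_wlls(
    acq: DiffusionAcquisition,
    mask: np.ndarray | None = None,
    n_passes: int = 2,
) -> TensorField:
    """Fit the diffusion tensor by heteroscedasticity-corrected linear LS.

    Pass 1 is ordinary least squares on log-signals; each further pass
    re-solves with per-measurement weights equal to the squared signals
    predicted by the previous pass.  ``n_passes=1`` gives plain log-linear
    OLS; the default of 2 is the usual WLLS estimator.

    Voxels whose signal is non-positive in more than half of the
    measurements, or whose solution is non-finite, are excluded from
    ``valid_mask`` (never raised on).
    """
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    X = design_matrix(acq.bvals, acq.bvecs)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError(
            "rank-deficient diffusion encoding: the b-value/direction scheme "
            "does not determine all 7 tensor parameters"
        )

    shape3 = acq.signal.shape[:3]
    if mask is None:
        mask = np.ones(shape3, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    sig = acq.signal[mask]                       # (V, M)
    m = sig.shape[1]
    # clamp non-positive signals to a tiny positive floor before the log
    floor = np.finfo(float).tiny ** 0.5
    scale = np.maximum(sig.max(initial=0.0), 1.0)
    clamped = sig <= 0
    sig_safe = np.where(clamped, floor * scale, sig)
    usable = clamped.sum(axis=1) <= m // 2       # >50% clamped -> invalid
    y = np.log(sig_safe)                         # (V, M)

    beta = np.linalg.lstsq(X, y.T, rcond=None)[0].T   # (V, 7) OLS pass
    for _ in range(n_passes - 1):
        w = np.exp(2.0 * (beta @ X.T))           # squared predicted signals
        w = np.where(np.isfinite(w), w, 0.0)
        gram = np.einsum("vm,mi,mj->vij", w, X, X)
        rhs = np.einsum("vm,mi->vi", w * y, X)
        ok = np.isfinite(gram).all(axis=(1, 2))
        # solve voxel-wise normal equations; fall back to previous beta on
        # numerically singular voxels
        new_beta = beta.copy()
        if np.any(ok):
            try:
                new_beta[ok] = np.linalg.solve(
                    gram[ok], rhs[ok][..., None]
                )[..., 0]
            except np.linalg.LinAlgError:
                for v in np.flatnonzero(ok):
                    try:
                        new_beta[v] = np.linalg.solve(gram[v], rhs[v])
                    except np.linalg.LinAlgError:
                        pass
        beta = new_beta

    finite = np.isfinite(beta).all(axis=1)
    good = usable & finite

    s0 = np.zeros(shape3, dtype=float)
    tensor = np.zeros(shape3 + (6,), dtype=float)
    valid = np.zeros(shape3, dtype=bool)
    s0_flat = np.exp(beta[:, 0])
    s0_vals = np.where(good, s0_flat, 0.0)
    tensor_vals = np.where(good[:, None], beta[:, 1:], 0.0)
    s0[mask] = s0_vals
    tensor[mask] = tensor_vals
    tmp = np.zeros(shape3, dtype=bool)
    tmp[mask] = good
    valid = tmp
    return TensorField(
        s0=s0, tensor=tensor, valid_mask=valid,
        affine=acq.affine, voxel_size=acq.voxel_size,
    )


def eigendecompose(tf: TensorField) -> EigenField:
    """Eigenvalues (descending) and principal direction of each tensor.

    The principal eigenvector's sign is unified so that its first nonzero
    component is non-negative.
    """
    mats = tensor_from_components(tf.tensor)         # (X,Y,Z,3,3)
    shape3 = tf.tensor.shape[:3]
    evals = np.zeros(shape3 + (3,), dtype=float)
    pdir = np.zeros(shape3 + (3,), dtype=float)
    valid = tf.valid_mask
    if np.any(valid):
        w, v = np.linalg.eigh(mats[valid])           # ascending
        w = w[:, ::-1]
        e1 = v[:, :, 2]                              # eigvec of largest
        # sign unification: first component with |x| > tol must be >= 0
        tol = 1e-12
        sign = np.ones(len(e1))
        for k in range(3):
            undecided = np.abs(e1[:, :k]).max(axis=1, initial=0.0) <= tol
            flip = undecided & (e1[:, k] < -tol)
            sign[flip] = -1.0
        e1 = e1 * sign[:, None]
        evals[valid] = w
        pdir[valid] = e1
    return EigenField(
        eigenvalues=evals, principal_direction=pdir, valid_mask=valid,
        affine=tf.affine, voxel_size=tf.voxel_size,
    )


def md_fa_from_eigenvalues(evals: np.ndarray, clamp_negative: bool = True):
    """Closed-form MD and FA from (..., 3) eigenvalue arrays.

    MD = (l1+l2+l3)/3.  FA = sqrt(3/2 * sum (li - MD)^2 / sum li^2), defined
    as 0 when all eigenvalues are 0.  Negative eigenvalues (a noise artifact)
    are clamped to 0 first so FA stays within [0, 1].
    """
    lam = np.asarray(evals, dtype=float)
    if clamp_negative:
        lam = np.clip(lam, 0.0, None)
    md = lam.mean(axis=-1)
    num = ((lam - md[..., None]) ** 2).sum(axis=-1)
    den = (lam ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return md, np.clip(fa, 0.0, 1.0)


def scalar_maps(ef: EigenField) -> Tuple[ScalarVolume, ScalarVolume]:
    """MD and FA maps from an eigenvalue field."""
    md, fa = md_fa_from_eigenvalues(ef.eigenvalues)
    md = np.where(ef.valid_mask, md, 0.0)
    fa = np.where(ef.valid_mask, fa, 0.0)
    mk = dict(valid_mask=ef.valid_mask, affine=ef.affine, voxel_size=ef.voxel_size)
    return (
        ScalarVolume(values=md, kind="MD", **mk),
        ScalarVolume(values=fa, kind="FA", **mk),
    )
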