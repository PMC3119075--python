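"""Spatial normalization chain: bias correction, rigid co-registration,
12-parameter affine normalization, transform application and smoothing.

All transforms are stored as 4x4 homogeneous matrices acting on world (mm)
coordinates, in the fixed <- moving direction: ``w_fixed = T @ w_moving``.
Registration maximizes normalized cross-correlation (both images are of the
same modality) by derivative-free optimization, with a light Gaussian
pre-smoothing used for parameter estimation only.  Resampling of index maps
defaults to nearest-neighbour so that map values are never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize


class RegistrationError(RuntimeError):
    """Optimizer failed to converge within the allotted restarts."""


class DegenerateFitError(ValueError):
    """Too little data to estimate the requested model."""


def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass(frozen=True)
class Transform:
    """A rigid-6 or affine-12 world-coordinate transform (fixed <- moving)."""

    kind: str                     # "rigid-6" or "affine-12"
    matrix: np.ndarray            # 4x4 homogeneous, mm

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", M)
        if M.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if abs(np.linalg.det(M[:3, :3])) < 1e-12:
            raise ValueError("transform is not invertible")
        if self.kind == "rigid-6":
            R = M[:3, :3]
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
                raise ValueError("rigid transform must have an orthonormal, "
                                 "det=+1 rotation block")

    @classmethod
    def identity(cls, kind: str = "rigid-6") -> "Transform":
        return cls(kind=kind, matrix=np.eye(4))

    @classmethod
    def rigid(cls, translation: Sequence[float] = (0, 0, 0),
              rotation_deg: Sequence[float] = (0, 0, 0)) -> "Transform":
        M = np.eye(4)
        M[:3, :3] = _rotation_matrix(*np.deg2rad(rotation_deg))
        M[:3, 3] = translation
        return cls(kind="rigid-6", matrix=M)

    @classmethod
    def affine12(cls, translation: Sequence[float] = (0, 0, 0),
                 rotation_deg: Sequence[float] = (0, 0, 0),
                 scale: Sequence[float] = (1, 1, 1),
                 shear: Sequence[float] = (0, 0, 0)) -> "Transform":
        R = _rotation_matrix(*np.deg2rad(rotation_deg))
        S = np.diag(scale)
        H = np.eye(3)
        H[0, 1], H[0, 2], H[1, 2] = shear
        M = np.eye(4)
        M[:3, :3] = R @ S @ H
        M[:3, 3] = translation
        return cls(kind="affine-12", matrix=M)

    def compose(self, other: "Transform") -> "Transform":
        """self o other: apply ``other`` first, then ``self``."""
        kind = "rigid-6" if self.kind == other.kind == "rigid-6" else "affine-12"
        return Transform(kind=kind, matrix=self.matrix @ other.matrix)

    def inverse(self) -> "Transform":
        return Transform(kind=self.kind, matrix=np.linalg.inv(self.matrix))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# dtiplast transform, kind={self.kind}, "
                     "4x4 world (mm) matrix, fixed<-moving\n")
            np.savetxt(fh, self.matrix, fmt="%.12g")

    @classmethod
    def load(cls, path: str | Path) -> "Transform":
        kind = "affine-12"
        with open(path) as fh:
            header = fh.readline()
            if "kind=" in header:
                kind = header.split("kind=")[1].split(",")[0].strip()
            M = np.loadtxt(fh)
        return cls(kind=kind, matrix=M)


def compose_chain(transforms: "Transform | Iterable[Transform]") -> Transform:
    if isinstance(transforms, Transform):
        return transforms
    chain = list(transforms)
    if not chain:
        return Transform.identity()
    out = chain[0]
    for t in chain[1:]:
        out = out.compose(t)
    return out


def apply_transform(data: np.ndarray, moving_affine: np.ndarray,
                    transforms: Transform | Iterable[Transform],
                    fixed_affine: np.ndarray,
                    fixed_shape: tuple[int, int, int],
                    interpolation: str = "nearest",
                    cval: float = np.nan) -> np.ndarray:
    """Resample ``data`` (moving) into the fixed grid through a transform chain.

    ``interpolation`` is ``"nearest"`` (default: index maps and label
    volumes are never interpolated) or ``"trilinear"``.  Voxels mapping
    outside the moving field of view are set to ``cval`` (NaN by default
    for float data, 0 for integer data).
    """
    T = compose_chain(transforms)
    order = {"nearest": 0, "trilinear": 1}[interpolation]
    M = np.linalg.inv(moving_affine) @ np.linalg.inv(T.matrix) @ np.asarray(fixed_affine)
    data = np.asarray(data)
    if not np.issubdtype(data.dtype, np.floating):
        cv = 0 if np.isnan(cval) else cval
        return ndimage.affine_transform(data, M[:3, :3], offset=M[:3, 3],
                                        output_shape=tuple(fixed_shape),
                                        order=0, cval=cv, mode="constant")
    return ndimage.affine_transform(data, M[:3, :3], offset=M[:3, 3],
                                    output_shape=tuple(fixed_shape),
                                    order=order, cval=cval, mode="constant",
                                    prefilter=False)


# ---------------------------------------------------------------------------
# similarity metric and registration

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation over jointly finite voxels."""
    valid = np.isfinite(a) & np.isfinite(b)
    if valid.sum() < 10:
        return -1.0
    x = a[valid] - a[valid].mean()
    y = b[valid] - b[valid].mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return 0.0
    return float(x @ y / (nx * ny))


def _smooth_for_estimation(data: np.ndarray, voxel_size: Sequence[float],
                           fwhm: float) -> np.ndarray:
    if fwhm <= 0:
        return data
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / np.asarray(voxel_size, float)
    return ndimage.gaussian_filter(np.nan_to_num(data), sigma=sigma)


def _params_to_transform(params: np.ndarray, kind: str) -> Transform:
    t, r = params[0:3], np.rad2deg(params[3:6])
    if kind == "rigid-6":
        return Transform.rigid(translation=t, rotation_deg=r)
    scale = 1.0 + params[6:9]
    shear = params[9:12]
    return Transform.affine12(translation=t, rotation_deg=r,
                              scale=scale, shear=shear)


def register(moving: np.ndarray, fixed: np.ndarray,
             moving_affine: np.ndarray, fixed_affine: np.ndarray,
             kind: str = "rigid-6", metric: str = "ncc",
             voxel_size: Sequence[float] | None = None,
             est_smooth_fwhm: float = 0.2,
             init: Transform | None = None,
             coarse_grid_voxels: Sequence[float] = (-1.0, 0.0, 1.0),
             xtol: float = 1e-5, maxiter: int = 4000,
             regularization: float = 1e-4) -> Transform:
    """Estimate the fixed<-moving transform maximizing image similarity.

    Powell's method over the parameter vector, multi-started from the
    identity (or ``init``) plus a coarse in-plane translation grid.  A
    Gaussian pre-smoothing (default 0.2 mm FWHM) is applied to both images
    for parameter estimation only; the returned transform is meant to be
    applied to the unsmoothed maps.  For ``kind="affine-12"`` a rigid
    pre-fit initializes the affine search.

    Parameters are bounded to anatomically plausible ranges (translations
    within a quarter FOV of the init, rotations <=20 degrees, scales within
    +/-25%, shears <=0.25) and a small quadratic penalty anchors directions
    the image content does not constrain to the identity, in the manner of
    regularized affine normalization.
    """
    if metric != "ncc":
        raise ValueError("only the normalized cross-correlation metric is implemented")
    if voxel_size is None:
        voxel_size = np.abs(np.diag(np.asarray(fixed_affine)[:3, :3]))
    fx = _smooth_for_estimation(np.asarray(fixed, float), voxel_size, est_smooth_fwhm)
    mv = _smooth_for_estimation(np.asarray(moving, float), voxel_size, est_smooth_fwhm)

    if kind == "affine-12" and init is None:
        init = register(moving, fixed, moving_affine, fixed_affine,
                        kind="rigid-6", voxel_size=voxel_size,
                        est_smooth_fwhm=est_smooth_fwhm,
                        coarse_grid_voxels=coarse_grid_voxels,
                        xtol=xtol, maxiter=maxiter)

    n_params = 6 if kind == "rigid-6" else 12

    # cubic B-spline resampling for the metric (prefilter once): trilinear
    # interpolation biases the NCC peak by a noticeable fraction of a voxel
    mv_pre = ndimage.spline_filter(mv, order=3)
    fixed_affine = np.asarray(fixed_affine)
    inv_moving = np.linalg.inv(moving_affine)

    fov = np.abs(np.asarray(voxel_size)) * np.asarray(fx.shape)
    t_bound = float(fov.max()) / 4.0
    scales = np.r_[np.full(3, t_bound), np.full(3, 0.35),
                   np.full(6, 0.25)][:n_params]
    bounds = [(-s, s) for s in scales]

    def cost(params: np.ndarray) -> float:
        T = _params_to_transform(params, kind)
        if init is not None:
            T = T.compose(init)
        M = inv_moving @ np.linalg.inv(T.matrix) @ fixed_affine
        # zero fill outside the moving FOV: background is air, and a NaN
        # mask would make the metric blind to overlap loss (a uniform slab
        # could slide along its invariant axis at constant NCC)
        res = ndimage.affine_transform(mv_pre, M[:3, :3], offset=M[:3, 3],
                                       output_shape=fx.shape, order=3,
                                       cval=0.0, mode="constant",
                                       prefilter=False)
        penalty = regularization * float(np.sum((params / scales) ** 2))
        return -_ncc(fx, res) + penalty

    inplane = float(np.min(np.asarray(voxel_size)[:2]))
    starts = [np.zeros(n_params)]
    if init is None:
        for dx in coarse_grid_voxels:
            for dy in coarse_grid_voxels:
                if dx == 0 and dy == 0:
                    continue
                s = np.zeros(n_params)
                s[0], s[1] = dx * inplane, dy * inplane
                starts.append(s)

    best, best_cost, any_success = None, np.inf, False
    for k, s in enumerate(starts):
        res = minimize(cost, s, method="Powell", bounds=bounds,
                       options={"xtol": xtol, "ftol": 1e-12, "maxiter": maxiter})
        any_success = any_success or bool(res.success)
        if res.fun < best_cost:
            best, best_cost = res.x, float(res.fun)
        # lazy multi-start: the translation grid is only consulted when the
        # identity start did not already lock on
        if k == 0 and best_cost < -0.995:
            break
    if best is None or (not any_success and best_cost > -0.2):
        raise RegistrationError(
            f"registration did not converge: best NCC {-best_cost:.4f} "
            f"with parameters {best}")

    T = _params_to_transform(best, kind)
    if init is not None:
        T = T.compose(init)
    return T


# ---------------------------------------------------------------------------
# bias correction

def _poly_design(shape: tuple[int, int, int], order: int = 2) -> np.ndarray:
    """Tri-polynomial basis x^i y^j z^k (i,j,k <= order) on [-1,1]^3."""
    axes = [np.linspace(-1, 1, n) if n > 1 else np.zeros(n) for n in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    cols = []
    for i in range(order + 1):
        for j in range(order + 1):
            for k in range(order + 1):
                cols.append((X ** i) * (Y ** j) * (Z ** k))
    return np.stack([c.ravel() for c in cols], axis=1)


def bias_correct(volume: np.ndarray, mask: np.ndarray,
                 order: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Estimate and divide out a smooth multiplicative intensity field.

    A tri-quadratic polynomial is least-squares fitted to the in-mask
    intensities; the corrected volume is renormalized so its in-mask mean is
    unchanged.  Raises :class:`DegenerateFitError` when the mask has fewer
    voxels than the polynomial has coefficients.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateFitError("empty mask")
    P = _poly_design(volume.shape, order=order)
    n_terms = P.shape[1]
    idx = mask.ravel()
    if idx.sum() < n_terms:
        raise DegenerateFitError(
            f"mask has {int(idx.sum())} voxels but the bias model has "
            f"{n_terms} coefficients")
    beta, *_ = np.linalg.lstsq(P[idx], volume.ravel()[idx], rcond=None)
    fld = (P @ beta).reshape(volume.shape)
    fld = fld / fld[mask].mean()
    fld = np.clip(fld, 1e-3, None)
    corrected = volume / fld
    corrected *= volume[mask].mean() / corrected[mask].mean()
    return corrected, fld


# ---------------------------------------------------------------------------
# smoothing and normalization QA

def gaussian_smooth(data: np.ndarray, voxel_size: Sequence[float],
                    fwhm: float = 0.3) -> np.ndarray:
    """NaN-aware separable Gaussian smoothing with the kernel given in mm.

    Weights over non-finite neighbours are renormalized, so a constant map
    stays constant and the value range never widens; ``fwhm=0`` is the
    identity.  NaN voxels stay NaN.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    data = np.asarray(data, dtype=float)
    if fwhm == 0:
        return data.copy()
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / np.asarray(voxel_size, float)
    valid = np.isfinite(data)
    num = ndimage.gaussian_filter(np.where(valid, data, 0.0), sigma=sigma)
    den = ndimage.gaussian_filter(valid.astype(float), sigma=sigma)
    out = np.full_like(data, np.nan)
    ok = valid & (den > 1e-12)
    out[ok] = num[ok] / den[ok]
    return out


def normalization_qa(maps: Sequence[np.ndarray],
                     mask: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxelwise mean, SD and SD/mean over a cohort of normalized maps."""
    stack = np.stack([np.asarray(m, float) for m in maps])
    if stack.shape[0] < 2:
        raise ValueError("normalization QA needs at least 2 maps")
    mean = np.nanmean(stack, axis=0)
    sd = np.nanstd(stack, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(np.abs(mean) > 1e-12, sd / mean, np.nan)
    if mask is not None:
        for arr in (mean, sd, cv):
            arr[~mask] = np.nan
    return mean, sd, cv


def qa_sd_ratio(maps_a: Sequence[np.ndarray], maps_b: Sequence[np.ndarray],
                mask: np.ndarray, percentile: float = 95.0) -> float:
    """Ratio of in-mask SD percentiles between two normalization pipelines.

    Values < 1 mean pipeline A (e.g. full affine normalization) leaves less
    residual anatomical variability than pipeline B (e.g. rigid only).
    """
    _, sd_a, _ = normalization_qa(maps_a, mask)
    _, sd_b, _ = normalization_qa(maps_b, mask)
    pa = np.nanpercentile(sd_a[mask], percentile)
    pb = np.nanpercentile(sd_b[mask], percentile)
    return float(pa / pb)
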