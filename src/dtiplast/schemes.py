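"""Diffusion gradient schemes: b-values and unit gradient directions.

A scheme is the list of (b, g) pairs of one DTI acquisition.  The default
scheme mirrors a rodent protocol of 15 noncollinear directions on a single
b = 1000 s/mm^2 shell plus one unweighted (b0) image.  Because no published
direction table is available, the default directions are generated by
electrostatic repulsion of antipodal point pairs on the unit sphere with a
fixed seed, which gives a reproducible, well-conditioned table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize


class SchemeError(ValueError):
    """Invalid or non-identifiable acquisition scheme."""


def _quadratic_form_rows(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows -b*(gx^2, gy^2, gz^2, 2gxgy, 2gxgz, 2gygz) of the tensor system."""
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    cols = np.stack([gx * gx, gy * gy, gz * gz,
                     2 * gx * gy, 2 * gx * gz, 2 * gy * gz], axis=1)
    return -bvals[:, None] * cols


@dataclass(frozen=True)
class AcquisitionScheme:
    """b-values (s/mm^2) and unit gradient directions of one acquisition.

    Identifiability requires at least six noncollinear diffusion-weighted
    directions plus at least one b0 image; this is enforced at construction.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if bvals.ndim != 1 or bvecs.shape != (bvals.size, 3):
            raise SchemeError(
                f"shape mismatch: {bvals.shape} b-values vs {bvecs.shape} directions")
        if np.any(bvals < 0):
            raise SchemeError("negative b-values")
        dwi = bvals > 0
        if not np.any(bvals == 0):
            raise SchemeError("scheme has no b0 image")
        norms = np.linalg.norm(bvecs[dwi], axis=1)
        if dwi.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise SchemeError("diffusion-weighted directions must be unit vectors")
        if dwi.sum() < 6:
            raise SchemeError(f"only {int(dwi.sum())} b>0 directions; >=6 required")
        # Noncollinearity: the 6 quadratic-form columns must span R^6.
        rank = np.linalg.matrix_rank(_quadratic_form_rows(bvals[dwi], bvecs[dwi]))
        if rank < 6:
            raise SchemeError(
                f"gradient directions are rank-deficient (rank {rank} of 6); "
                "the tensor is not identifiable")

    @property
    def n(self) -> int:
        return int(self.bvals.size)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0

    # FSL-dialect text files: bval one row, bvec three rows (x, y, z),
    # directions expressed in the image coordinate frame.
    def to_files(self, bval_path: str | Path, bvec_path: str | Path) -> None:
        np.savetxt(bval_path, self.bvals[None, :], fmt="%.6g")
        np.savetxt(bvec_path, self.bvecs.T, fmt="%.8f")

    @classmethod
    def from_files(cls, bval_path: str | Path, bvec_path: str | Path) -> "AcquisitionScheme":
        bvals = np.loadtxt(bval_path).reshape(-1)
        bvecs = np.loadtxt(bvec_path)
        if bvecs.shape[0] == 3:
            bvecs = bvecs.T
        return cls(bvals=bvals, bvecs=bvecs)


def electrostatic_directions(n: int, seed: int = 1234) -> np.ndarray:
    """Spread ``n`` antipodally symmetric unit directions on the sphere.

    Minimizes the Coulomb energy of the 2n point set {+g_i, -g_i} over
    spherical angles with a deterministic random initialization, the standard
    construction for DTI sampling tables when none is prescribed.
    """
    rng = np.random.default_rng(seed)
    x0 = rng.standard_normal((n, 3))
    x0 /= np.linalg.norm(x0, axis=1, keepdims=True)
    ang0 = np.stack([np.arccos(np.clip(x0[:, 2], -1, 1)),
                     np.arctan2(x0[:, 1], x0[:, 0])], axis=1).ravel()

    def to_xyz(angles: np.ndarray) -> np.ndarray:
        theta, phi = angles.reshape(-1, 2).T
        st = np.sin(theta)
        return np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=1)

    def energy(angles: np.ndarray) -> float:
        g = to_xyz(angles)
        diff = g[:, None, :] - g[None, :, :]
        summ = g[:, None, :] + g[None, :, :]
        iu = np.triu_indices(n, k=1)
        d1 = np.linalg.norm(diff[iu], axis=1)
        d2 = np.linalg.norm(summ[iu], axis=1)
        return float(np.sum(1.0 / d1) + np.sum(1.0 / d2))

    res = minimize(energy, ang0, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14})
    g = to_xyz(res.x)
    # Canonical orientation: positive z hemisphere, sorted for determinism.
    g[g[:, 2] < 0] *= -1
    order = np.lexsort((g[:, 1], g[:, 0], g[:, 2]))
    return g[order]


def default_scheme(n_directions: int = 15, bvalue: float = 1000.0,
                   seed: int = 1234) -> AcquisitionScheme:
    """One b0 followed by ``n_directions`` noncollinear b=``bvalue`` volumes."""
    dirs = electrostatic_directions(n_directions, seed=seed)
    bvals = np.concatenate([[0.0], np.full(n_directions, float(bvalue))])
    bvecs = np.vstack([np.zeros(3), dirs])
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs)
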