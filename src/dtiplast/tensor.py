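"""Voxelwise diffusion tensor fitting and derived index maps.

The signal model is the single-tensor Stejskal-Tanner equation
``S_i = S0 * exp(-b_i g_i^T D g_i)``; taking logs turns the fit into a
linear least-squares problem per voxel.  From the eigenvalues of D the four
indices that the downstream statistics analyze are derived: fractional
anisotropy (FA), mean diffusivity (reported as ADC), axial diffusivity
(AD = lambda1) and radial diffusivity (RD = (lambda2 + lambda3)/2).

Note on naming: throughout this package "ADC" denotes the tensor-derived
mean diffusivity (lambda1 + lambda2 + lambda3)/3, the quantity the
voxel-based statistics operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .schemes import AcquisitionScheme, SchemeError, _quadratic_form_rows

#: order of the six unique tensor elements everywhere in the package
ELEMENT_ORDER = ("xx", "yy", "zz", "xy", "xz", "yz")

#: canonical index-map names
INDEX_NAMES = ("FA", "ADC", "AD", "RD")


class FitError(ValueError):
    """Unrecoverable tensor-fit failure."""


def design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """(n, 7) matrix mapping (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) to ln S.

    Column 0 is the intercept (ln S0); columns 1-6 are
    ``-b * (gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz)``.
    Raises :class:`~dtiplast.schemes.SchemeError` if the system is
    rank-deficient.
    """
    X = np.hstack([np.ones((scheme.n, 1)),
                   _quadratic_form_rows(scheme.bvals, scheme.bvecs)])
    rank = np.linalg.matrix_rank(X)
    if rank < 7:
        raise SchemeError(
            f"design matrix rank {rank} < 7: scheme cannot identify the tensor "
            "(directions coplanar or too few)")
    return X


def tensors_to_matrices(d6: np.ndarray) -> np.ndarray:
    """(..., 6) unique elements -> (..., 3, 3) symmetric matrices."""
    d6 = np.asarray(d6)
    D = np.empty(d6.shape[:-1] + (3, 3), dtype=d6.dtype)
    D[..., 0, 0] = d6[..., 0]
    D[..., 1, 1] = d6[..., 1]
    D[..., 2, 2] = d6[..., 2]
    D[..., 0, 1] = D[..., 1, 0] = d6[..., 3]
    D[..., 0, 2] = D[..., 2, 0] = d6[..., 4]
    D[..., 1, 2] = D[..., 2, 1] = d6[..., 5]
    return D


def matrices_to_tensors(D: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric matrices -> (..., 6) unique elements."""
    D = np.asarray(D)
    return np.stack([D[..., 0, 0], D[..., 1, 1], D[..., 2, 2],
                     D[..., 0, 1], D[..., 0, 2], D[..., 1, 2]], axis=-1)


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor plus S0 on a regular grid.

    ``d6`` holds the unique elements in :data:`ELEMENT_ORDER` (mm^2/s).
    """

    d6: np.ndarray                       # (X, Y, Z, 6)
    s0: np.ndarray                       # (X, Y, Z)
    voxel_size: tuple[float, float, float]
    affine: np.ndarray                   # 4x4 NIfTI-style voxel->world (mm)
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.d6.shape[:3]

    def matrices(self) -> np.ndarray:
        return tensors_to_matrices(self.d6)

    def copy(self) -> "TensorField":
        return TensorField(self.d6.copy(), np.array(self.s0, copy=True),
                           tuple(self.voxel_size), self.affine.copy(),
                           dict(self.provenance))


@dataclass
class FitQC:
    """Bookkeeping of the voxelwise fit: clamp and invalidation incidents."""

    n_voxels: int = 0
    n_invalid: int = 0          # all-nonpositive signal series, dropped from mask
    n_clamped_signals: int = 0  # nonpositive samples floored before the log
    n_negative_eigenvalues: int = 0
    method: str = ""

    def as_text(self) -> str:
        return ("tensor fit QC\n"
                f"method\t{self.method}\n"
                f"voxels_fit\t{self.n_voxels}\n"
                f"voxels_invalid\t{self.n_invalid}\n"
                f"signals_clamped\t{self.n_clamped_signals}\n"
                f"eigenvalues_clamped\t{self.n_negative_eigenvalues}\n")


def _floor_nonpositive(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Clamp nonpositive samples to half the voxel's smallest positive signal.

    Returns (clamped signals, validity per voxel, number of clamped samples).
    Voxels whose whole series is nonpositive are marked invalid.
    """
    pos = Y > 0
    valid = pos.any(axis=-1)
    n_clamped = int(np.count_nonzero(~pos[valid]))
    Ymasked = np.where(pos, Y, np.inf)
    floor = 0.5 * Ymasked.min(axis=-1)
    floor = np.where(valid, floor, 1.0)
    Yc = np.where(pos, Y, floor[..., None])
    return Yc, valid, n_clamped


def fit_tensor(dwi, mask: np.ndarray | None = None,
               scheme: AcquisitionScheme | None = None,
               method: Literal["ols", "wls"] = "wls") -> tuple[TensorField, np.ndarray, FitQC]:
    """Fit the tensor voxelwise by (weighted) linear least squares on log-signals.

    Parameters
    ----------
    dwi
        A :class:`~dtiplast.simulate.DWIVolume` (or any object with ``data``,
        ``scheme``, ``voxel_size`` and ``affine`` attributes).
    mask
        Boolean brain mask; voxels outside it are left as zero tensors.
    method
        ``"ols"`` for ordinary least squares on log-signals, ``"wls"`` for
        weighted least squares with weights equal to the squared fitted
        signals from an OLS first pass (the default).

    Returns
    -------
    (field, mask_out, qc)
        ``mask_out`` is ``mask`` minus voxels whose signal series was entirely
        nonpositive; such voxels are counted in ``qc``.
    """
    scheme = scheme if scheme is not None else dwi.scheme
    data = np.asarray(dwi.data, dtype=float)
    if data.shape[-1] != scheme.n:
        raise FitError(f"DWI has {data.shape[-1]} volumes but scheme has {scheme.n}")
    shape = data.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    X = design_matrix(scheme)

    Y = data[mask]                                   # (V, n)
    Yc, valid, n_clamped = _floor_nonpositive(Y)
    logY = np.log(Yc)

    pinv = np.linalg.pinv(X)
    beta = logY @ pinv.T                             # (V, 7) OLS
    if method == "wls":
        W = np.exp(2.0 * (beta @ X.T))               # squared fitted signals
        # batched weighted normal equations: (X^T W X) beta = X^T W y
        A = np.einsum("ni,vn,nj->vij", X, W, X, optimize=True)
        b = np.einsum("ni,vn,vn->vi", X, W, logY, optimize=True)
        beta = np.linalg.solve(A, b[..., None])[..., 0]
    elif method != "ols":
        raise ValueError(f"unknown fit method {method!r}")

    beta[~valid] = 0.0
    d6 = np.zeros(shape + (6,))
    s0 = np.zeros(shape)
    d6[mask] = beta[:, 1:]
    s0[mask] = np.where(valid, np.exp(beta[:, 0]), 0.0)

    mask_out = mask.copy()
    idx = np.argwhere(mask)
    mask_out[tuple(idx[~valid].T)] = False

    qc = FitQC(n_voxels=int(valid.sum()), n_invalid=int((~valid).sum()),
               n_clamped_signals=n_clamped, method=method)
    field = TensorField(d6=d6, s0=s0, voxel_size=tuple(dwi.voxel_size),
                        affine=np.asarray(dwi.affine, dtype=float),
                        provenance={"method": method})
    return field, mask_out, qc


def eigendecompose(field: TensorField | np.ndarray,
                   mask: np.ndarray | None = None,
                   qc: FitQC | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sorted (descending) eigenvalues and eigenvectors of the tensor field.

    Negative eigenvalues are clamped to zero (the incident count goes to
    ``qc``); voxels with non-finite tensor elements are invalidated in the
    returned mask.
    """
    d6 = field.d6 if isinstance(field, TensorField) else np.asarray(field)
    shape = d6.shape[:-1]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask_out = mask.copy()
    finite = np.isfinite(d6).all(axis=-1)
    mask_out &= finite

    evals = np.zeros(shape + (3,))
    evecs = np.zeros(shape + (3, 3))
    D = tensors_to_matrices(d6[mask_out])
    w, v = np.linalg.eigh(D)                         # ascending
    w = w[..., ::-1]
    v = v[..., ::-1]
    n_neg = int(np.count_nonzero(w < 0))
    w = np.clip(w, 0.0, None)
    evals[mask_out] = w
    evecs[mask_out] = v
    if qc is not None:
        qc.n_negative_eigenvalues += n_neg
    return evals, evecs, mask_out


@dataclass
class IndexMaps:
    """FA / ADC(MD) / AD / RD maps with shared geometry and mask.

    All maps are NaN outside the mask.  ``maps`` gives dict-style access
    under the canonical names in :data:`INDEX_NAMES`.
    """

    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    @property
    def adc(self) -> np.ndarray:
        """Alias: ADC is reported as the tensor mean diffusivity."""
        return self.md

    @property
    def maps(self) -> dict[str, np.ndarray]:
        return {"FA": self.fa, "ADC": self.md, "AD": self.ad, "RD": self.rd}


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lambda - mean|| / ||lambda||, with FA(0 tensor) = 0."""
    evals = np.asarray(evals, dtype=float)
    md = evals.mean(axis=-1, keepdims=True)
    num = np.sqrt(((evals - md) ** 2).sum(axis=-1))
    den = np.sqrt((evals ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)


def compute_indices(evals: np.ndarray, mask: np.ndarray,
                    voxel_size: tuple[float, float, float],
                    affine: np.ndarray) -> IndexMaps:
    """Derive FA, ADC(MD), AD and RD from sorted nonnegative eigenvalues."""
    evals = np.asarray(evals, dtype=float)
    if np.any(np.diff(evals[mask], axis=-1) > 1e-30):
        raise ValueError("eigenvalues must be sorted descending")
    md = evals.mean(axis=-1)
    ad = evals[..., 0]
    rd = 0.5 * (evals[..., 1] + evals[..., 2])
    fa = fa_from_eigenvalues(evals)
    out = {}
    for name, arr in (("fa", fa), ("md", md), ("ad", ad), ("rd", rd)):
        m = np.full(mask.shape, np.nan)
        m[mask] = arr[mask]
        out[name] = m
    return IndexMaps(mask=mask.copy(), voxel_size=tuple(voxel_size),
                     affine=np.asarray(affine, dtype=float), **out)


def index_maps_from_dwi(dwi, mask: np.ndarray | None = None,
                        method: Literal["ols", "wls"] = "wls"
                        ) -> tuple[IndexMaps, FitQC]:
    """Convenience chain: fit tensor, decompose, derive the four index maps."""
    field, mask_out, qc = fit_tensor(dwi, mask=mask, method=method)
    evals, _, mask_out = eigendecompose(field, mask_out, qc=qc)
    return compute_indices(evals, mask_out, field.voxel_size, field.affine), qc


def index_maps_from_field(field: TensorField, mask: np.ndarray) -> IndexMaps:
    """Ground-truth index maps straight from a (phantom) tensor field."""
    evals, _, mask_out = eigendecompose(field, mask)
    return compute_indices(evals, mask_out, field.voxel_size, field.affine)
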