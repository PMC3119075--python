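"""Motion screening of slice/direction images and repeat averaging.

Respiration during an EPI readout corrupts only the slices sampled at that
moment, smearing brain signal along the phase-encoding axis.  The screen
measures the mean-signal profile along that axis and flags a slice when the
signal found at profile positions outside the brain exceeds a fraction tau
of the in-brain mean (after subtracting the background noise floor).
Surviving repeats are then averaged per slice and direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .simulate import DWIVolume, PHASE_AXIS

DEFAULT_TAU = 0.05
#: minimum in-plane distance (voxels) from the mask for "far" background voxels
FAR_BACKGROUND_DISTANCE = 10.0


@dataclass(frozen=True)
class SliceDecision:
    repeat: int
    direction: int
    slice: int
    statistic: float        # out-of-brain signal ratio, >= 0 after flooring
    decision: str           # "keep" or "reject"


def data_brain_mask(repeats: list[DWIVolume],
                    threshold_fraction: float = 0.25) -> np.ndarray:
    """Brain mask from the subject's own data: thresholded mean b0.

    Screening must use the subject's brain borders, not a template's: a
    rigidly displaced head would otherwise put genuine brain signal
    "outside the brain" and be mistaken for a ghost.
    """
    b0 = np.mean([r.data[..., r.scheme.b0_mask].mean(axis=-1) for r in repeats],
                 axis=0)
    mask = b0 > threshold_fraction * np.nanmax(b0)
    return ndimage.binary_fill_holes(mask)


def phase_profile(slice_image: np.ndarray, phase_axis: int = PHASE_AXIS) -> np.ndarray:
    """Mean-signal profile along the phase-encoding axis of one 2D slice."""
    img = np.asarray(slice_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("phase_profile expects a 2D slice image")
    if img.size == 0:
        raise ValueError("empty slice image")
    other_axis = 1 - phase_axis
    return img.mean(axis=other_axis)


def _background_floor(slice_image: np.ndarray, mask_slice: np.ndarray) -> float:
    """Noise floor: median of out-of-mask voxels far from the brain.

    Distance is the in-plane Euclidean distance to the mask.  On small
    matrices where no voxel is that far, the 25th percentile of all
    out-of-mask voxels is used instead: a ghost elevates a minority of the
    background, so a low quantile stays anchored to the noise floor where a
    median over a small far region would not.
    """
    dist = ndimage.distance_transform_edt(~mask_slice)
    far = dist > FAR_BACKGROUND_DISTANCE
    if far.any():
        return float(np.median(slice_image[far]))
    outside = dist > 0
    if not outside.any():
        return 0.0
    return float(np.percentile(slice_image[outside], 25.0))


def screen_slice(slice_image: np.ndarray, mask_slice: np.ndarray,
                 tau: float = DEFAULT_TAU, phase_axis: int = PHASE_AXIS,
                 repeat: int = 0, direction: int = 0,
                 slice_index: int = 0) -> SliceDecision:
    """Keep/reject one (repeat, direction, slice) image by out-of-brain signal.

    statistic = (mean profile value at phase positions with no brain voxels
    minus the background floor) / (mean in-mask signal); reject iff the
    statistic exceeds ``tau``.
    """
    img = np.asarray(slice_image, dtype=float)
    mask_slice = np.asarray(mask_slice, dtype=bool)
    if not mask_slice.any():
        warnings.warn(f"slice {slice_index}: empty brain mask, keeping by default",
                      stacklevel=2)
        return SliceDecision(repeat, direction, slice_index, 0.0, "keep")

    profile = phase_profile(img, phase_axis)
    mask_positions = mask_slice.any(axis=1 - phase_axis)
    out_positions = ~mask_positions
    if not out_positions.any():
        return SliceDecision(repeat, direction, slice_index, 0.0, "keep")

    floor = _background_floor(img, mask_slice)
    in_mean = float(img[mask_slice].mean())
    stat = (float(profile[out_positions].mean()) - floor) / max(in_mean, 1e-30)
    stat = max(stat, 0.0)
    decision = "reject" if stat > tau else "keep"
    return SliceDecision(repeat, direction, slice_index, stat, decision)


def screen_repeats(repeats: list[DWIVolume], mask: np.ndarray,
                   tau: float = DEFAULT_TAU,
                   phase_axis: int = PHASE_AXIS) -> pd.DataFrame:
    """Screen every (repeat, direction, slice) image; tidy decisions table."""
    rows = []
    for rep, dwi in enumerate(repeats):
        nz, nd = dwi.data.shape[2], dwi.data.shape[3]
        for d in range(nd):
            for z in range(nz):
                dec = screen_slice(dwi.data[:, :, z, d], mask[:, :, z],
                                   tau=tau, phase_axis=phase_axis,
                                   repeat=rep, direction=d, slice_index=z)
                rows.append(dec.__dict__)
    return pd.DataFrame(rows)


class RepeatCoverageError(RuntimeError):
    """Some (slice, direction) cell lost all repeats to screening."""


def combine_repeats(repeats: list[DWIVolume],
                    decisions: pd.DataFrame | None = None
                    ) -> tuple[DWIVolume, np.ndarray]:
    """Voxelwise mean over surviving repeats, per (slice, direction) cell.

    Returns the combined volume and the per-(slice, direction) survivor
    count.  Raises :class:`RepeatCoverageError`, listing the cells, if any
    cell has no survivors.
    """
    if not repeats:
        raise ValueError("no repeats to combine")
    shape = repeats[0].data.shape
    for r in repeats[1:]:
        if r.data.shape != shape:
            raise ValueError("repeats have mismatched shapes")
    nz, nd = shape[2], shape[3]
    keep = np.ones((len(repeats), nz, nd), dtype=bool)
    if decisions is not None and len(decisions):
        rej = decisions[decisions["decision"] == "reject"]
        for _, row in rej.iterrows():
            keep[int(row["repeat"]), int(row["slice"]), int(row["direction"])] = False

    counts = keep.sum(axis=0)                       # (nz, nd)
    dead = np.argwhere(counts == 0)
    if dead.size:
        cells = ", ".join(f"(slice {z}, direction {d})" for z, d in dead[:10])
        raise RepeatCoverageError(
            f"{len(dead)} (slice, direction) cells have no surviving repeat: {cells}")

    stack = np.stack([r.data for r in repeats])     # (R, X, Y, Z, n)
    w = keep[:, None, None, :, :].astype(float)
    combined = (stack * w).sum(axis=0) / counts[None, None, :, :]
    out = DWIVolume(data=combined, scheme=repeats[0].scheme,
                    voxel_size=tuple(repeats[0].voxel_size),
                    affine=repeats[0].affine.copy())
    return out, counts
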