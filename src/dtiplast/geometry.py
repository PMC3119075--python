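"""Shared voxel/world geometry helpers.

Conventions used throughout the package: voxel indices are 0-based,
world coordinates are in mm via a NIfTI-style affine, and the default
affine places the world origin at the volume centre (so rotations in
registration are about the centre of the field of view).
"""

from __future__ import annotations

import numpy as np


def default_affine(shape: tuple[int, int, int],
                   voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Axis-aligned voxel->world affine with the origin at the volume centre."""
    shape = np.asarray(shape, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    A = np.eye(4)
    A[:3, :3] = np.diag(vs)
    A[:3, 3] = -(shape - 1) / 2.0 * vs
    return A


def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def world_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    xyz = np.asarray(xyz, dtype=float)
    return xyz @ inv[:3, :3].T + inv[:3, 3]
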