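"""Forward simulation of diffusion-weighted cohorts.

Signals follow the single-tensor forward model S_i = S0 exp(-b g^T D g);
noise is Rician (magnitude of a complex Gaussian perturbation), matching
magnitude EPI data, with Gaussian noise available for analytic tests.
Motion artifacts are injected as half-FOV phase-encode ghosts on single
(slice, direction) images, the classic N/2 EPI ghost, which places brain
signal outside the brain mask exactly as the motion screen expects.

A cohort is a two-scan, three-repeat design over subjects with group and
age labels; the second scan of subjects matched by an effect spec is
simulated from the effect-injected tensor field.  Every random draw is
derived from the design's master seed via named seed sequences, so a
cohort regenerates byte-identically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .phantom import (EffectSpec, PhantomSpec, ROILabelMap, apply_effects,
                      bias_field, build_phantom)
from .schemes import AcquisitionScheme, default_scheme
from .tensor import TensorField, tensors_to_matrices

log = logging.getLogger(__name__)

#: phase-encoding axis of the simulated EPI readout (0-based array axis)
PHASE_AXIS = 1

# Default complex-noise sigma as a fraction of S0 (b0 SNR 60 per repeat,
# ~100 after three-repeat averaging): the high-field, surface-coil regime,
# chosen at design time so that the small synthetic cohorts (8 subjects per
# group) retain the per-voxel sensitivity the full-size in-vivo design owes
# to its larger samples.
DEFAULT_NOISE_SIGMA_FRACTION = 1.0 / 60.0


@dataclass
class DWIVolume:
    """4D diffusion-weighted data with its scheme and voxel geometry."""

    data: np.ndarray                     # (X, Y, Z, n)
    scheme: AcquisitionScheme
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def copy(self) -> "DWIVolume":
        return DWIVolume(self.data.copy(), self.scheme,
                         tuple(self.voxel_size), self.affine.copy())


def forward_signals(fld: TensorField, scheme: AcquisitionScheme) -> np.ndarray:
    """Noise-free signals S0 exp(-b g^T D g), shape (X, Y, Z, n)."""
    D = tensors_to_matrices(fld.d6)
    g = scheme.bvecs
    q = np.einsum("...ab,na,nb->...n", D, g, g, optimize=True)
    return np.asarray(fld.s0)[..., None] * np.exp(-scheme.bvals * q)


def simulate_dwi(fld: TensorField, scheme: AcquisitionScheme | None = None,
                 noise_sigma: float = 0.0,
                 rng: np.random.Generator | int | None = None,
                 noise_model: str = "rician",
                 bias: np.ndarray | None = None) -> DWIVolume:
    """Simulate one DTI acquisition of a tensor field.

    ``noise_sigma`` is the complex Gaussian component standard deviation in
    signal (S0) units; 0 returns the exact forward-model signals.  ``bias``
    optionally multiplies the signals with a smooth receive field.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    scheme = scheme if scheme is not None else default_scheme()
    S = forward_signals(fld, scheme)
    if bias is not None:
        S = S * np.asarray(bias)[..., None]
    if noise_sigma > 0:
        rng = np.random.default_rng(rng)
        if noise_model == "rician":
            re = S + rng.normal(0.0, noise_sigma, S.shape)
            im = rng.normal(0.0, noise_sigma, S.shape)
            S = np.hypot(re, im)
        elif noise_model == "gaussian":
            S = S + rng.normal(0.0, noise_sigma, S.shape)
        else:
            raise ValueError(f"unknown noise model {noise_model!r}")
    return DWIVolume(data=S, scheme=scheme, voxel_size=fld.voxel_size,
                     affine=fld.affine.copy())


def corrupt_slice(dwi: DWIVolume, slice_index: int, direction_index: int,
                  ghost_fraction: float, mask: np.ndarray,
                  phase_axis: int = PHASE_AXIS) -> DWIVolume:
    """Add a half-FOV phase-encode ghost to one (slice, direction) image.

    The in-mask signal of the slice is replicated, displaced by half the
    field of view along the phase-encoding axis and added back scaled by
    ``ghost_fraction``, so that brain-shaped signal appears outside the
    brain.  All other slices and directions are bit-identical.
    """
    if ghost_fraction < 0:
        raise ValueError("ghost_fraction must be >= 0")
    out = dwi.copy()
    if ghost_fraction == 0.0:
        return out
    sl_img = dwi.data[:, :, slice_index, direction_index]
    sl_mask = mask[:, :, slice_index]
    if not sl_mask.any():
        warnings.warn(f"ghosting requested on slice {slice_index} with empty "
                      "brain mask; no-op", stacklevel=2)
        log.warning("corrupt_slice: empty mask in slice %d, skipping", slice_index)
        return out
    ghost = np.where(sl_mask, sl_img, 0.0)
    shift = sl_img.shape[phase_axis] // 2
    ghost = np.roll(ghost, shift, axis=phase_axis)
    out.data[:, :, slice_index, direction_index] = sl_img + ghost_fraction * ghost
    return out


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class Subject:
    id: str
    group: str                           # L / S / NL
    age: int                             # months


@dataclass(frozen=True)
class GhostEvent:
    """One scheduled motion artifact."""

    subject: str
    scan: int                            # 1 or 2
    repeat: int                          # 0-based
    direction: int
    slice: int
    ghost_fraction: float = 0.10


@dataclass(frozen=True)
class CohortDesign:
    """Subjects x two scans x repeats, with the master seed recorded."""

    subjects: tuple[Subject, ...]
    n_repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids")
        if not self.subjects:
            raise ValueError("empty design")

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.subjects])

    @classmethod
    def balanced(cls, n_per_group: int = 8, age: int = 4,
                 groups: Sequence[str] = ("L", "S", "NL"), n_repeats: int = 3,
                 seed: int = 0) -> "CohortDesign":
        subs = tuple(Subject(id=f"{g}{i:02d}", group=g, age=age)
                     for g in groups for i in range(n_per_group))
        return cls(subjects=subs, n_repeats=n_repeats, seed=seed)

    @classmethod
    def age_series(cls, n_per_age: int = 8, ages: Sequence[int] = (1, 4, 12),
                   group: str = "L", n_repeats: int = 3, seed: int = 0) -> "CohortDesign":
        subs = tuple(Subject(id=f"{group}{a}m{i:02d}", group=group, age=a)
                     for a in ages for i in range(n_per_age))
        return cls(subjects=subs, n_repeats=n_repeats, seed=seed)

    @classmethod
    def study_design(cls, seed: int = 0) -> "CohortDesign":
        """The full in-vivo study layout: L at three ages, S and NL at 4 months."""
        subs = []
        for a, n in ((1, 26), (4, 22), (12, 20)):
            subs += [Subject(id=f"L{a}m{i:02d}", group="L", age=a) for i in range(n)]
        subs += [Subject(id=f"S4m{i:02d}", group="S", age=4) for i in range(10)]
        subs += [Subject(id=f"NL4m{i:02d}", group="NL", age=4) for i in range(14)]
        return cls(subjects=tuple(subs), n_repeats=3, seed=seed)


def _rng_for(design: CohortDesign, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([design.seed & 0x7FFFFFFF, *key]))


def subject_perturbations(design: CohortDesign, spec: PhantomSpec,
                          max_translation_voxels: float = 2.0,
                          max_rotation_deg: float = 5.0,
                          scan_jitter_voxels: float = 0.2,
                          scan_jitter_deg: float = 0.5) -> dict[tuple[str, int], dict]:
    """Small rigid head poses per (subject, scan).

    One pose is drawn per subject and a smaller jitter per scan, so both the
    scan-to-scan co-registration and the across-subject normalization stages
    have work to do.  Returns {(subject id, scan): {"translation_mm", "rotation_deg"}}.
    """
    vs = np.asarray(spec.voxel_size)
    out: dict[tuple[str, int], dict] = {}
    for si, sub in enumerate(design.subjects):
        rng = _rng_for(design, 101, si)
        base_t = rng.uniform(-max_translation_voxels, max_translation_voxels, 3) * vs
        base_t[2] *= 0.25          # through-plane motion stays well under a slice
        base_r = rng.uniform(-max_rotation_deg, max_rotation_deg, 3)
        base_r[:2] *= 0.2          # mostly in-plane rotation for thin slabs
        for scan in (1, 2):
            jit_t = rng.uniform(-scan_jitter_voxels, scan_jitter_voxels, 3) * vs
            jit_r = rng.uniform(-scan_jitter_deg, scan_jitter_deg, 3) * np.array([0.2, 0.2, 1.0])
            out[(sub.id, scan)] = {
                "translation_mm": (base_t + jit_t).tolist(),
                "rotation_deg": (base_r + jit_r).tolist(),
            }
    return out


def _perturbed_field(fld: TensorField, pose: dict) -> TensorField:
    """Resample the scalar channels of a field into a rigidly moved frame.

    The subject's acquisition samples the template content at world points
    T(w): equivalently the template volumes are pulled back through T.
    Tensor elements are resampled channelwise (rotation effects on tensor
    orientation are negligible at <=5 degrees and irrelevant to the scalar
    indices under study).
    """
    from .spatial import Transform, apply_transform   # local import, avoids cycle

    T = Transform.rigid(translation=pose["translation_mm"],
                        rotation_deg=pose["rotation_deg"])
    out = fld.copy()
    for c in range(6):
        out.d6[..., c] = apply_transform(
            fld.d6[..., c], fld.affine, T, fld.affine, fld.shape,
            interpolation="trilinear", cval=0.0)
    out.s0 = apply_transform(np.asarray(fld.s0, dtype=float), fld.affine, T,
                             fld.affine, fld.shape, interpolation="trilinear",
                             cval=0.0)
    return out


def random_ghost_schedule(design: CohortDesign, spec: PhantomSpec,
                          n_events: int, ghost_fraction: float = 0.10,
                          scheme_n: int = 16) -> list[GhostEvent]:
    """Draw a reproducible artifact schedule over the whole cohort."""
    rng = _rng_for(design, 202)
    events = []
    for _ in range(n_events):
        sub = design.subjects[rng.integers(len(design.subjects))]
        events.append(GhostEvent(
            subject=sub.id, scan=int(rng.integers(1, 3)),
            repeat=int(rng.integers(design.n_repeats)),
            direction=int(rng.integers(scheme_n)),
            slice=int(rng.integers(spec.shape[2])),
            ghost_fraction=ghost_fraction))
    return events


def simulate_subject_scan(design: CohortDesign, spec: PhantomSpec,
                          base_field: TensorField, rois: ROILabelMap,
                          effects: Sequence[EffectSpec], subject_index: int,
                          scan: int, scheme: AcquisitionScheme,
                          noise_sigma: float, mask: np.ndarray,
                          pose: dict | None = None,
                          ghosts: Sequence[GhostEvent] = (),
                          noise_model: str = "rician") -> list[DWIVolume]:
    """All repeats of one (subject, scan), reproducible from the master seed."""
    sub = design.subjects[subject_index]
    fld = base_field
    if scan == 2:
        fld = apply_effects(base_field, rois, effects, sub.group, sub.age)
    if pose is not None:
        fld = _perturbed_field(fld, pose)
    bias = bias_field(spec) if spec.bias_amplitude > 0 else None
    repeats = []
    for rep in range(design.n_repeats):
        rng = _rng_for(design, 303, subject_index, scan, rep)
        dwi = simulate_dwi(fld, scheme, noise_sigma=noise_sigma, rng=rng,
                           noise_model=noise_model, bias=bias)
        for ev in ghosts:
            if (ev.subject, ev.scan, ev.repeat) == (sub.id, scan, rep):
                dwi = corrupt_slice(dwi, ev.slice, ev.direction,
                                    ev.ghost_fraction, mask)
        repeats.append(dwi)
    return repeats


def simulate_cohort(design: CohortDesign, spec: PhantomSpec,
                    effects: Sequence[EffectSpec], out_dir: str | Path,
                    scheme: AcquisitionScheme | None = None,
                    noise_sigma: float | None = None,
                    ghost_events: Sequence[GhostEvent] = (),
                    perturb: bool = True,
                    noise_model: str = "rician") -> dict:
    """Write a complete two-scan cohort to disk and return its manifest.

    Layout: per subject/scan one 4D NIfTI per repeat plus FSL-dialect
    bval/bvec files; cohort-level ROI label map, brain mask, ground-truth
    index maps, a tab-delimited design table and a YAML manifest recording
    seeds, poses, injected effects and scheduled artifacts.
    """
    from . import io as dio   # local import keeps nibabel out of hot paths

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scheme = scheme if scheme is not None else default_scheme()
    if noise_sigma is None:
        noise_sigma = spec.s0 * DEFAULT_NOISE_SIGMA_FRACTION

    base_field, rois, mask = build_phantom(spec)
    poses = subject_perturbations(design, spec) if perturb else {}

    dio.save_nifti(out_dir / "roi_labels.nii", rois.data.astype(np.int16), spec.affine)
    dio.save_nifti(out_dir / "brain_mask.nii", mask.astype(np.uint8), spec.affine)
    scheme.to_files(out_dir / "dwi.bval", out_dir / "dwi.bvec")

    # normalization targets: the phantom ground truth serves as the b0/FA
    # template (the in-vivo study used one atlas-registered reference animal)
    from .tensor import index_maps_from_field
    truth = index_maps_from_field(base_field, mask)
    dio.save_nifti(out_dir / "template_fa.nii",
                   np.nan_to_num(truth.fa).astype(np.float32), spec.affine)
    dio.save_nifti(out_dir / "template_b0.nii",
                   np.asarray(base_field.s0, dtype=np.float32), spec.affine)

    rows = []
    for si, sub in enumerate(design.subjects):
        for scan in (1, 2):
            pose = poses.get((sub.id, scan))
            repeats = simulate_subject_scan(
                design, spec, base_field, rois, effects, si, scan, scheme,
                noise_sigma, mask, pose=pose, ghosts=ghost_events,
                noise_model=noise_model)
            scan_dir = out_dir / f"sub-{sub.id}" / f"scan-{scan}"
            scan_dir.mkdir(parents=True, exist_ok=True)
            for rep, dwi in enumerate(repeats):
                path = scan_dir / f"rep-{rep}_dwi.nii"
                dio.save_nifti(path, dwi.data.astype(np.float32), spec.affine)
                rows.append({"subject_id": sub.id, "group": sub.group,
                             "age_months": sub.age, "scan_time": scan,
                             "repeat": rep,
                             "path": str(path.relative_to(out_dir))})

    import pandas as pd
    design_table = pd.DataFrame(rows)
    dio.write_table(design_table, out_dir / "design.tsv")

    manifest = {
        "seed": int(design.seed),
        "n_repeats": int(design.n_repeats),
        "noise_sigma": float(noise_sigma),
        "noise_model": noise_model,
        "phantom": {
            "shape": list(spec.shape),
            "voxel_size_mm": list(spec.voxel_size),
            "s0": float(spec.s0),
            "bias_amplitude": float(spec.bias_amplitude),
            "rois": {r.name: {"label": int(r.label),
                              "eigenvalues_mm2_s": list(map(float, r.eigenvalues))}
                     for r in spec.rois},
        },
        "effects": [{"roi": e.roi, "index": e.index, "percent": float(e.percent),
                     "groups": list(e.groups), "ages": list(e.ages),
                     "attenuation": {int(k): float(v) for k, v in e.attenuation.items()}}
                    for e in effects],
        "poses": {f"{sid}/scan-{scan}": p for (sid, scan), p in poses.items()},
        "ghost_events": [{"subject": ev.subject, "scan": ev.scan,
                          "repeat": ev.repeat, "direction": ev.direction,
                          "slice": ev.slice, "ghost_fraction": ev.ghost_fraction}
                         for ev in ghost_events],
        "files": {"labels": "roi_labels.nii", "mask": "brain_mask.nii",
                  "bval": "dwi.bval", "bvec": "dwi.bvec", "design": "design.tsv"},
    }
    dio.write_manifest(manifest, out_dir / "manifest.yaml")
    return manifest
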