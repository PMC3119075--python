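"""Reproducible study recipes: the simulation experiments that characterize
the pipeline (FDR calibration, effect localization, age dependence, motion
screening and registration recovery).

Each function fixes the study conditions -- grid, group sizes, noise level,
effect magnitudes -- and derives every random stream from a single base
seed, so a study is one function call.  FDR-calibration cohorts are
analyzed without map smoothing so that the voxelwise ground-truth effect
set stays exactly the injected region; the localization and age studies
use the full default chain including 0.3-mm smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import (EffectSpec, ROIDef, default_effects,
                      default_phantom_spec, build_phantom)
from .pipeline import AnalysisSettings, generate_cohort_maps, interaction_analysis
from .qc import screen_slice
from .simulate import CohortDesign, corrupt_slice, simulate_dwi
from .spatial import Transform, register
from .stats import age_analysis, anova_map, fdr_correct
from .geometry import default_affine

GRID = (16, 16, 4)
N_PER_GROUP = 8
Q_LEVEL = 0.05
#: noise level of the FDR calibration studies (sigma = S0/40)
FDR_STUDY_NOISE_FRACTION = 1.0 / 40.0

#: expected localization pattern: ROI -> (index, driving group)
EXPECTED_EFFECTS = {"DG": ("ADC", "L"), "PC": ("ADC", "L"),
                    "CG": ("FA", "L"), "CC": ("FA", "L"),
                    "SC": ("ADC", "S")}
CONTROL_ROI = "EC"


def _cohort_seed(base_seed: int, i: int) -> int:
    return int((base_seed * 100_003 + 7919 * i) % (2 ** 31 - 1))


# ---------------------------------------------------------------------------
# FDR calibration

def null_fdr_study(n_cohorts: int = 200, base_seed: int = 1,
                   q_level: float = Q_LEVEL) -> dict:
    """Family-wise error of the corrected interaction test under the null.

    Simulates complete-null cohorts (3 groups x 8 subjects x 2 scans, no
    injected effects), runs the voxelwise interaction ANOVA on ADC and
    counts cohorts in which BH-FDR at ``q_level`` declares any voxel.
    """
    spec = default_phantom_spec(GRID)
    hits = 0
    for i in range(n_cohorts):
        design = CohortDesign.balanced(n_per_group=N_PER_GROUP,
                                       seed=_cohort_seed(base_seed, i))
        cohort = generate_cohort_maps(design, spec=spec, effects=[],
                                      noise_sigma=spec.s0 * FDR_STUDY_NOISE_FRACTION,
                                      smooth_fwhm=0.0, indices=("ADC",))
        res = anova_map(cohort.maps, design.groups, cohort.mask)["ADC"]
        _, sig = fdr_correct(res.effects["interaction"].p, q=q_level,
                             mask=res.mask)
        hits += bool(sig.any())
    return {"n_cohorts": n_cohorts,
            "any_discovery_proportion": hits / n_cohorts,
            "q_level": q_level}


def sparse_fdr_study(n_cohorts: int = 200, base_seed: int = 1,
                     q_level: float = Q_LEVEL, percent: float = -5.0) -> dict:
    """Mean false-discovery proportion with 5% of voxels truly affected.

    One ROI covering ~5% of the in-mask voxels receives a ``percent`` ADC
    change for group L at the second scan; per cohort the FDP of the
    corrected interaction test against the known affected voxel set is
    computed and averaged.
    """
    roi = ROIDef(label=1, name="DG", lo=(6, 6, 0), hi=(9, 9, 3),
                 eigenvalues=(0.78e-3, 0.70e-3, 0.62e-3), axis=(0, 0, 1))
    spec = default_phantom_spec(GRID)
    spec = type(spec)(shape=spec.shape, voxel_size=spec.voxel_size,
                      rois=(roi,), s0=spec.s0)
    effects = [EffectSpec(roi="DG", index="ADC", percent=percent, groups=("L",))]
    _, rois, mask = build_phantom(spec)
    truth = rois.mask_of("DG") & mask

    fdps, n_disc = [], []
    for i in range(n_cohorts):
        design = CohortDesign.balanced(n_per_group=N_PER_GROUP,
                                       seed=_cohort_seed(base_seed, i))
        cohort = generate_cohort_maps(design, spec=spec, effects=effects,
                                      noise_sigma=spec.s0 * FDR_STUDY_NOISE_FRACTION,
                                      smooth_fwhm=0.0, indices=("ADC",))
        res = anova_map(cohort.maps, design.groups, cohort.mask)["ADC"]
        _, sig = fdr_correct(res.effects["interaction"].p, q=q_level,
                             mask=res.mask)
        disc = int(sig.sum())
        false = int((sig & ~truth).sum())
        fdps.append(false / max(1, disc))
        n_disc.append(disc)
    return {"n_cohorts": n_cohorts,
            "mean_fdp": float(np.mean(fdps)),
            "mean_discoveries": float(np.mean(n_disc)),
            "true_voxels": int(truth.sum()),
            "mask_voxels": int(mask.sum()),
            "q_level": q_level}


# ---------------------------------------------------------------------------
# localization and age dependence

def localization_study(seed: int = 0,
                       settings: AnalysisSettings | None = None) -> dict:
    """One default-effect cohort through the full chain; who was found where.

    Returns the cluster table plus, per expected region, whether a
    surviving interaction cluster with the correct index and driving group
    was found, and how many clusters touch the no-effect control region.
    """
    design = CohortDesign.balanced(n_per_group=N_PER_GROUP, seed=seed)
    cohort = generate_cohort_maps(design, spec=default_phantom_spec(GRID),
                                  effects=default_effects(),
                                  smooth_fwhm=0.3, indices=("ADC", "FA"))
    analysis = interaction_analysis(cohort, settings=settings)
    clusters = analysis["clusters"]
    detected = {}
    for roi, (index, driver) in EXPECTED_EFFECTS.items():
        rows = clusters[(clusters["index"] == index)
                        & (clusters["main_roi"] == roi)]
        detected[roi] = bool((rows["driving_group"] == driver).any())
    control_hits = int(clusters["roi_overlap"].fillna("")
                       .str.contains(f"{CONTROL_ROI}:").sum())
    return {"clusters": clusters, "detected": detected,
            "control_hits": control_hits,
            "all_correct": all(detected.values()) and control_hits == 0}


def age_study(seed: int = 0) -> tuple[dict, pd.DataFrame]:
    """Learning-group cohorts at 1/4/12 months through the age x time analysis.

    Under the default attenuation profile the DG ADC decrease is age-stable
    while the CG/CC FA changes shrink with age.
    """
    design = CohortDesign.age_series(n_per_age=N_PER_GROUP, seed=seed)
    cohort = generate_cohort_maps(design, spec=default_phantom_spec(GRID),
                                  effects=default_effects(),
                                  smooth_fwhm=0.3, indices=("ADC", "FA"))
    results, regional = age_analysis(cohort.maps, design.ages, cohort.mask,
                                     roi_labels=cohort.rois.data,
                                     roi_names=cohort.rois.names)
    return results, regional


# ---------------------------------------------------------------------------
# motion screening

def motion_qc_study(n_corrupt: int = 200, n_clean: int = 200,
                    ghost_fraction: float = 0.10, seed: int = 0,
                    tau: float = 0.05) -> dict:
    """Sensitivity/specificity of the slice screen on known artifacts.

    Slices are drawn from noisy acquisitions of a 32 x 32 x 4 phantom;
    corrupted slices receive a half-FOV ghost of the given amplitude.
    """
    spec = default_phantom_spec((32, 32, 4))
    field, _, mask = build_phantom(spec)
    rng = np.random.default_rng(seed)
    sigma = spec.s0 / 40.0

    def draw_slices(n: int, corrupt: bool) -> list[bool]:
        # several distinct (slice, direction) cells per simulated acquisition
        out: list[bool] = []
        while len(out) < n:
            dwi = simulate_dwi(field, noise_sigma=sigma, rng=rng)
            n_cells = dwi.data.shape[2] * dwi.data.shape[3]
            cells = rng.choice(n_cells, size=min(8, n - len(out)), replace=False)
            for cell in cells:
                z, d = int(cell % dwi.data.shape[2]), int(cell // dwi.data.shape[2])
                img = dwi
                if corrupt:
                    img = corrupt_slice(dwi, z, d, ghost_fraction, mask)
                dec = screen_slice(img.data[:, :, z, d], mask[:, :, z], tau=tau,
                                   slice_index=z, direction=d)
                out.append(dec.decision == "reject")
        return out

    rejected_corrupt = draw_slices(n_corrupt, corrupt=True)
    rejected_clean = draw_slices(n_clean, corrupt=False)
    return {"sensitivity": float(np.mean(rejected_corrupt)),
            "specificity": float(1.0 - np.mean(rejected_clean)),
            "tau": tau, "ghost_fraction": ghost_fraction,
            "n_corrupt": n_corrupt, "n_clean": n_clean}


# ---------------------------------------------------------------------------
# registration recovery

def _blob_image(shape, affine, rng, n_blobs: int = 12,
                voxel_size=(0.2, 0.2, 1.2)):
    """Smooth analytic test pattern: Gaussian blobs inside an ellipsoid.

    Blob widths are at least ~1.5 voxels per axis so the pattern is fully
    resolved at the (anisotropic) sampling grid; structure below the slice
    spacing would alias and bias the similarity optimum.
    """
    vs = np.asarray(voxel_size, dtype=float)
    half = vs * (np.asarray(shape) - 1) / 2
    centers = rng.uniform(-0.55, 0.55, (n_blobs, 3)) * half
    widths = rng.uniform(1.5, 4.0, (n_blobs, 3)) * vs
    amps = rng.uniform(0.5, 1.0, n_blobs)

    def f(world: np.ndarray) -> np.ndarray:
        # world: (..., 3) in mm
        u = world / half
        env = np.exp(-(np.linalg.norm(u, axis=-1) / 0.8) ** 4)
        out = np.zeros(world.shape[:-1])
        for c, w, a in zip(centers, widths, amps):
            out += a * np.exp(-(((world - c) / w) ** 2).sum(axis=-1) / 2)
        return out * env

    return f


def registration_study(n_trials: int = 50, seed: int = 0,
                       shape=(32, 32, 8),
                       voxel_size=(0.2, 0.2, 1.2),
                       max_translation_voxels: float = 2.0,
                       max_rotation_deg: float = 5.0,
                       tolerance_voxels: float = 0.1) -> dict:
    """Apply-then-recover test of rigid registration.

    Random rigid perturbations (translations up to 2 voxels per axis,
    rotations up to 5 degrees) are applied analytically to a smooth blob
    pattern; success means the mean in-mask displacement error of the
    recovered transform is at most 0.1 voxel on every axis.
    """
    rng = np.random.default_rng(seed)
    affine = default_affine(shape, voxel_size)
    vs = np.asarray(voxel_size)
    ii = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    world = ii @ affine[:3, :3].T + affine[:3, 3]
    half = vs * (np.asarray(shape) - 1) / 2
    in_mask = (np.linalg.norm(world / half, axis=-1) < 0.7)

    errors, successes = [], 0
    for _ in range(n_trials):
        f = _blob_image(shape, affine, rng, voxel_size=voxel_size)
        fixed = f(world)
        t = rng.uniform(-max_translation_voxels, max_translation_voxels, 3) * vs
        r = rng.uniform(-max_rotation_deg, max_rotation_deg, 3) * np.array([0.3, 0.3, 1.0])
        T_true = Transform.rigid(translation=t, rotation_deg=r)
        moving = f((world @ T_true.matrix[:3, :3].T) + T_true.matrix[:3, 3])
        T_rec = register(moving, fixed, affine, affine, kind="rigid-6",
                         voxel_size=voxel_size)
        # correspondence error between true and recovered mappings, in mm
        pts = world[in_mask]
        inv_true = np.linalg.inv(T_true.matrix)
        inv_rec = np.linalg.inv(T_rec.matrix)
        m_true = pts @ inv_true[:3, :3].T + inv_true[:3, 3]
        m_rec = pts @ inv_rec[:3, :3].T + inv_rec[:3, 3]
        err = np.abs(m_rec - m_true).mean(axis=0) / vs      # voxels per axis
        errors.append(err)
        successes += bool(np.all(err <= tolerance_voxels))
    errors = np.array(errors)
    return {"success_rate": successes / n_trials,
            "n_trials": n_trials,
            "mean_error_voxels": errors.mean(axis=0).tolist(),
            "max_error_voxels": errors.max(axis=0).tolist(),
            "tolerance_voxels": tolerance_voxels}
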