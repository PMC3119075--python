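"""High-level orchestration: cohorts in, statistics out.

These functions wire the stages together for the two study analyses
(group x time at a fixed age; age x time within the learning group) and
are what the command-line interface and the reproduction scripts call.
The fast in-memory path generates, fits and analyzes a cohort without
touching disk; the disk-based path mirrors it for simulated cohorts
written by :func:`dtiplast.simulate.simulate_cohort`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .phantom import (EffectSpec, PhantomSpec, ROILabelMap, build_phantom,
                      default_effects, default_phantom_spec)
from .qc import combine_repeats, data_brain_mask, screen_repeats
from .schemes import AcquisitionScheme, default_scheme
from .simulate import (DEFAULT_NOISE_SIGMA_FRACTION, CohortDesign, GhostEvent,
                       simulate_subject_scan, subject_perturbations)
from .spatial import apply_transform, gaussian_smooth, register
from .stats import anova_map, extract_clusters, fdr_correct, posthoc_regional
from .tensor import index_maps_from_dwi, index_maps_from_field


@dataclass
class CohortMaps:
    """Per-index stacks of subject index maps: (N subjects, 2 scans, X, Y, Z)."""

    maps: dict[str, np.ndarray]
    mask: np.ndarray
    rois: ROILabelMap
    design: CohortDesign
    spec: PhantomSpec


def generate_cohort_maps(design: CohortDesign,
                         spec: PhantomSpec | None = None,
                         effects: Sequence[EffectSpec] | None = None,
                         scheme: AcquisitionScheme | None = None,
                         noise_sigma: float | None = None,
                         smooth_fwhm: float = 0.3,
                         qc: bool = False,
                         ghost_events: Sequence[GhostEvent] = (),
                         perturb: bool = False,
                         fit_method: str = "wls",
                         noise_model: str = "rician",
                         indices: Sequence[str] = ("ADC", "FA")) -> CohortMaps:
    """Simulate a cohort and carry every scan to smoothed index maps.

    With ``perturb=False`` subjects are generated directly in template
    space, which isolates the statistical stages from registration; with
    ``perturb=True`` each scan receives a small rigid head pose and the
    maps are normalized back to the template through the registration
    chain before statistics.
    """
    spec = spec if spec is not None else default_phantom_spec()
    effects = list(default_effects()) if effects is None else list(effects)
    scheme = scheme if scheme is not None else default_scheme()
    if noise_sigma is None:
        noise_sigma = spec.s0 * DEFAULT_NOISE_SIGMA_FRACTION

    base_field, rois, mask = build_phantom(spec)
    template = index_maps_from_field(base_field, mask)
    poses = subject_perturbations(design, spec) if perturb else {}

    n = len(design.subjects)
    stacks = {i: np.empty((n, 2) + spec.shape) for i in indices}
    common_mask = mask.copy()
    for si in range(n):
        sub = design.subjects[si]
        for scan in (1, 2):
            reps = simulate_subject_scan(design, spec, base_field, rois,
                                         effects, si, scan, scheme,
                                         noise_sigma, mask,
                                         pose=poses.get((sub.id, scan)),
                                         ghosts=ghost_events,
                                         noise_model=noise_model)
            screen_mask = data_brain_mask(reps) if perturb else mask
            decisions = screen_repeats(reps, screen_mask) if qc else None
            combined, _ = combine_repeats(reps, decisions)
            fit_mask = mask if not perturb else _approx_moved_mask(combined)
            imaps, _ = index_maps_from_dwi(combined, mask=fit_mask,
                                           method=fit_method)
            if perturb:
                imaps = normalize_subject_maps(imaps, template)
            for idx in indices:
                m = imaps.maps[idx]
                if smooth_fwhm > 0:
                    m = gaussian_smooth(m, spec.voxel_size, fwhm=smooth_fwhm)
                stacks[idx][si, scan - 1] = m
            common_mask &= imaps.mask if not perturb else common_mask
    for idx in indices:
        common_mask &= np.isfinite(stacks[idx]).all(axis=(0, 1))
    return CohortMaps(maps=stacks, mask=common_mask, rois=rois,
                      design=design, spec=spec)


def _approx_moved_mask(dwi) -> np.ndarray:
    """Liberal mask for fitting a rigidly moved subject: strong b0 signal."""
    b0 = dwi.data[..., dwi.scheme.b0_mask].mean(axis=-1)
    return b0 > 0.25 * np.nanmax(b0)


def normalize_subject_maps(imaps, template):
    """Register a subject's maps into template space (rigid b0 step folded
    into one FA-driven transform here: the synthetic subjects differ only
    rigidly, so the affine stage is estimated directly on FA), then resample
    every index map with nearest-neighbour interpolation."""
    from .tensor import IndexMaps

    T = register(imaps.fa, template.fa, imaps.affine, template.affine,
                 kind="rigid-6", voxel_size=imaps.voxel_size)
    out = {}
    for key, arr in (("fa", imaps.fa), ("md", imaps.md),
                     ("ad", imaps.ad), ("rd", imaps.rd)):
        out[key] = apply_transform(arr, imaps.affine, T, template.affine,
                                   template.mask.shape, interpolation="nearest")
    new_mask = apply_transform(imaps.mask.astype(np.uint8), imaps.affine, T,
                               template.affine, template.mask.shape,
                               interpolation="nearest").astype(bool)
    return IndexMaps(mask=new_mask & template.mask,
                     voxel_size=template.voxel_size,
                     affine=template.affine, **out)


# ---------------------------------------------------------------------------
# statistics driver

@dataclass
class AnalysisSettings:
    q_level: float = 0.05
    connectivity: int = 26
    min_cluster_size: int = 5
    indices: tuple[str, ...] = ("ADC", "FA")


def interaction_analysis(cohort: CohortMaps,
                         settings: AnalysisSettings | None = None,
                         between: str = "group") -> dict:
    """Voxelwise group x time ANOVA per index, FDR, clusters and post-hocs.

    FDR is applied separately per index map and per effect (the per-map
    family definition); clusters are extracted from the corrected
    interaction map and annotated with the ROI labels and the group
    driving the interaction.
    """
    settings = settings or AnalysisSettings()
    labels = (cohort.design.groups if between == "group"
              else cohort.design.ages.astype(str))
    results = anova_map(cohort.maps, labels, cohort.mask,
                        indices=settings.indices, between_factor=between)
    cluster_rows = []
    posthocs = {}
    for index, res in results.items():
        for eff in res.effects.values():
            eff.q, eff.sig = fdr_correct(eff.p, q=settings.q_level, mask=res.mask)
        inter = res.effects["interaction"]
        table, clab = extract_clusters(inter.sig,
                                       connectivity=settings.connectivity,
                                       min_size=settings.min_cluster_size,
                                       stat_map=inter.F,
                                       roi_labels=cohort.rois.data,
                                       roi_names=cohort.rois.names)
        for _, row in table.iterrows():
            cmask = clab == row["cluster_id"]
            ph = posthoc_regional(cmask, cohort.maps[index], labels,
                                  region_name=f"{index}:{row['main_roi']}")
            drive = ph.table.set_index("group").loc[ph.driving_group]
            cluster_rows.append({"index": index, **row.to_dict(),
                                 "driving_group": ph.driving_group,
                                 "driving_pct_change": drive["pct_change"],
                                 "driving_p": drive["p"]})
            posthocs[(index, int(row["cluster_id"]))] = ph
        res.cluster_labels = clab    # type: ignore[attr-defined]
    columns = ["index", "cluster_id", "size", "peak_F", "centroid_x",
               "centroid_y", "centroid_z", "main_roi", "roi_overlap",
               "driving_group", "driving_pct_change", "driving_p"]
    return {"stats": results,
            "clusters": pd.DataFrame(cluster_rows, columns=columns),
            "posthocs": posthocs,
            "settings": settings}
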