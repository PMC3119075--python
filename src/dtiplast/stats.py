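"""Voxel-wise mixed-design (split-plot) ANOVA, FDR correction, cluster
extraction and regional post-hoc quantification.

The design has one between-subject factor (group or age) and one repeated
factor (scan time, exactly two levels).  Each effect is tested against its
own error stratum: the group effect against subject-within-group
variability of the subject means, and the time and interaction effects
against the time-by-subject residual of the difference scores.  With two
time points the within-subject stratum reduces exactly to an analysis of
the per-subject difference d = y2 - y1: the interaction F equals the
one-way ANOVA F of d across groups, and the time main effect tests the
(unweighted, Type III) grand mean of d against zero, so unbalanced group
sizes do not bias the inference towards the larger groups.

Voxelwise maps are computed by broadcasting the same closed-form
projections over all in-mask voxels at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EFFECT_NAMES = ("group", "time", "interaction")

#: relative floor below which an error mean square counts as zero variance
_ZERO_VAR_REL = 1e-12


class DesignError(ValueError):
    """Statistical design violates the split-plot preconditions."""


def _group_codes(groups: Sequence) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    counts = np.bincount(codes)
    if labels.size < 2:
        raise DesignError("need at least 2 groups")
    if counts.min() < 2:
        bad = labels[counts < 2]
        raise DesignError(f"groups with a single subject: {list(bad)}")
    return labels, codes, counts


def _oneway_f(x: np.ndarray, codes: np.ndarray, counts: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA over the last-but-one axis; x is (N, V)."""
    a = counts.size
    N = x.shape[0]
    G = np.zeros((a, N))
    G[codes, np.arange(N)] = 1.0
    gsum = G @ x                                 # (a, V)
    gmean = gsum / counts[:, None]
    grand = x.mean(axis=0)
    ss_between = (counts[:, None] * (gmean - grand) ** 2).sum(axis=0)
    ss_within = ((x - gmean[codes]) ** 2).sum(axis=0)
    return ss_between, ss_within, gmean


def _safe_f_p(ss_h: np.ndarray, df_h: int, ss_e: np.ndarray, df_e: int,
              scale: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """F and p with the degenerate zero-variance policy (p=1, flagged)."""
    ms_e = ss_e / df_e
    zero = ms_e <= _ZERO_VAR_REL * np.maximum(scale, 1e-300)
    ms_e_safe = np.where(zero, 1.0, ms_e)
    F = np.where(zero, 0.0, (ss_h / df_h) / ms_e_safe)
    p = np.where(zero, 1.0, sps.f.sf(F, df_h, df_e))
    return F, p, zero


def splitplot_anova(y1: np.ndarray, y2: np.ndarray, groups: Sequence
                    ) -> dict:
    """Split-plot ANOVA of N subjects x 2 times, vectorized over voxels.

    ``y1``/``y2`` are (N,) or (N, V).  Returns a dict with per-effect F, p
    and degrees of freedom, the five-component (sequential) sum-of-squares
    decomposition, and a ``zero_variance`` flag per voxel.
    """
    y1 = np.atleast_2d(np.asarray(y1, float).T).T
    y2 = np.atleast_2d(np.asarray(y2, float).T).T
    if y1.shape != y2.shape:
        raise DesignError("both scans must have the same subjects")
    N = y1.shape[0]
    labels, codes, counts = _group_codes(groups)
    if len(groups) != N:
        raise DesignError("group labels do not match the number of subjects")
    a = labels.size

    s = 0.5 * (y1 + y2)                   # subject means (between stratum)
    d = y2 - y1                           # difference scores (within stratum)

    ssb_s, ssw_s, _ = _oneway_f(s, codes, counts)
    ssb_d, ssw_d, gmean_d = _oneway_f(d, codes, counts)

    grand = 0.5 * (y1 + y2).mean(axis=0)
    ss_total = ((y1 - grand) ** 2 + (y2 - grand) ** 2).sum(axis=0)
    scale = ss_total / (2 * N)

    # between stratum
    F_g, p_g, zero_g = _safe_f_p(2 * ssb_s, a - 1, 2 * ssw_s, N - a, scale)
    # within stratum: interaction = one-way on d
    F_i, p_i, zero_i = _safe_f_p(ssb_d, a - 1, ssw_d, N - a, scale)
    # time main effect: Type III (unweighted mean of the group means of d)
    mu = gmean_d.mean(axis=0)
    c = float((1.0 / counts).sum()) / a ** 2
    F_t, p_t, zero_t = _safe_f_p(mu ** 2 / c, 1, ssw_d, N - a, scale)

    ss = {
        "group": 2 * ssb_s,
        "subject(group)": 2 * ssw_s,
        "time": N * d.mean(axis=0) ** 2 / 2,
        "interaction": ssb_d / 2,
        "time x subject(group)": ssw_d / 2,
        "total": ss_total,
    }
    return {
        "labels": labels,
        "F": {"group": F_g, "time": F_t, "interaction": F_i},
        "p": {"group": p_g, "time": p_t, "interaction": p_i},
        "df": {"group": (a - 1, N - a), "time": (1, N - a),
               "interaction": (a - 1, N - a)},
        "ss": ss,
        "zero_variance": zero_g | zero_i | zero_t,
    }


def mixed_anova(values: np.ndarray, groups: Sequence) -> dict:
    """Single-voxel convenience wrapper: ``values`` is (N, 2)."""
    values = np.asarray(values, float)
    if values.ndim != 2 or values.shape[1] != 2:
        raise DesignError("values must be (N subjects, 2 times)")
    res = splitplot_anova(values[:, 0], values[:, 1], groups)
    out = dict(res)
    out["F"] = {e: float(res["F"][e][0]) for e in res["F"]}
    out["p"] = {e: float(res["p"][e][0]) for e in res["p"]}
    out["ss"] = {k: float(np.asarray(v).ravel()[0]) for k, v in res["ss"].items()}
    out["zero_variance"] = bool(res["zero_variance"][0])
    return out


# ---------------------------------------------------------------------------
# voxelwise maps

@dataclass
class EffectResult:
    """One effect's voxelwise statistics (NaN outside the mask)."""

    F: np.ndarray
    p: np.ndarray
    df: tuple[int, int]
    q: np.ndarray | None = None
    sig: np.ndarray | None = None


@dataclass
class StatResult:
    """Voxelwise split-plot ANOVA maps for one index."""

    effects: dict[str, EffectResult]
    mask: np.ndarray
    between_factor: str
    group_labels: np.ndarray
    n_voxels: int
    zero_variance: np.ndarray = field(default=None)


def anova_map(maps: Mapping[str, np.ndarray], groups: Sequence,
              mask: np.ndarray, indices: Sequence[str] | None = None,
              between_factor: str = "group") -> dict[str, StatResult]:
    """Split-plot ANOVA at every in-mask voxel for each selected index map.

    ``maps`` holds per-index arrays of shape (N subjects, 2 times, X, Y, Z).
    Returns {index: StatResult} with F/p maps per effect (between factor,
    time, interaction); q/sig are filled in later by FDR correction.
    """
    mask = np.asarray(mask, dtype=bool)
    selected = list(maps) if indices is None else [i for i in maps if i in set(indices)]
    out: dict[str, StatResult] = {}
    for name in selected:
        arr = np.asarray(maps[name], dtype=float)
        if arr.shape[1] != 2:
            raise DesignError(f"{name}: expected two scan times, got {arr.shape[1]}")
        if arr.shape[2:] != mask.shape:
            raise DesignError(f"{name}: map shape {arr.shape[2:]} != mask {mask.shape}")
        finite = np.isfinite(arr).all(axis=(0, 1))
        vmask = mask & finite
        y1 = arr[:, 0][:, vmask]
        y2 = arr[:, 1][:, vmask]
        res = splitplot_anova(y1, y2, groups)
        effects = {}
        for eff in EFFECT_NAMES:
            Fmap = np.full(mask.shape, np.nan)
            pmap = np.full(mask.shape, np.nan)
            Fmap[vmask] = res["F"][eff]
            pmap[vmask] = res["p"][eff]
            effects[eff] = EffectResult(F=Fmap, p=pmap, df=res["df"][eff])
        zv = np.zeros(mask.shape, dtype=bool)
        zv[vmask] = res["zero_variance"]
        out[name] = StatResult(effects=effects, mask=vmask,
                               between_factor=between_factor,
                               group_labels=res["labels"],
                               n_voxels=int(vmask.sum()), zero_variance=zv)
    return out


# ---------------------------------------------------------------------------
# FDR

def fdr_correct(p: np.ndarray, q: float = 0.05,
                mask: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over in-mask voxels.

    Returns (q-value map, boolean significance mask); q-values are the
    monotone step-up adjusted p-values.  Voxels outside the mask get NaN / False.
    """
    p = np.asarray(p, dtype=float)
    if mask is None:
        mask = np.isfinite(p)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(p)
    if not mask.any():
        raise ValueError("empty mask: no p-values to correct")
    pv = p[mask]
    if np.any((pv <= 0) | (pv > 1)):
        raise ValueError("p-values must be in (0, 1]")
    reject, q_adj, _, _ = multipletests(pv, alpha=q, method="fdr_bh")
    qmap = np.full(p.shape, np.nan)
    sig = np.zeros(p.shape, dtype=bool)
    qmap[mask] = q_adj
    sig[mask] = reject
    return qmap, sig


# ---------------------------------------------------------------------------
# clusters

def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6, 18 or 26")


def extract_clusters(sig: np.ndarray, connectivity: int = 26,
                     min_size: int = 5,
                     stat_map: np.ndarray | None = None,
                     roi_labels: np.ndarray | None = None,
                     roi_names: Mapping[int, str] | None = None
                     ) -> tuple[pd.DataFrame, np.ndarray]:
    """Connected components of a significance mask, annotated with ROIs.

    Components smaller than ``min_size`` are dropped (but reflected in the
    ``n_dropped`` attribute of the returned table).  Returns the cluster
    table and the cluster-id volume (0 = no cluster).
    """
    sig = np.asarray(sig, dtype=bool)
    lab, n = ndimage.label(sig, structure=_structure(connectivity))
    rows, dropped = [], 0
    out_lab = np.zeros_like(lab)
    next_id = 0
    for cid in range(1, n + 1):
        vox = lab == cid
        size = int(vox.sum())
        if size < min_size:
            dropped += 1
            continue
        next_id += 1
        out_lab[vox] = next_id
        centroid = np.array(np.nonzero(vox)).mean(axis=1)
        peak_F = peak_p = np.nan
        if stat_map is not None:
            vals = np.asarray(stat_map)[vox]
            peak_F = float(np.nanmax(vals))
        overlaps = {}
        if roi_labels is not None:
            ids, cts = np.unique(np.asarray(roi_labels)[vox], return_counts=True)
            for i, c in zip(ids, cts):
                if i == 0:
                    continue
                nm = roi_names.get(int(i), str(int(i))) if roi_names else str(int(i))
                overlaps[nm] = c / size
        main_roi = max(overlaps, key=overlaps.get) if overlaps else ""
        rows.append({"cluster_id": next_id, "size": size, "peak_F": peak_F,
                     "centroid_x": centroid[0], "centroid_y": centroid[1],
                     "centroid_z": centroid[2], "main_roi": main_roi,
                     "roi_overlap": ";".join(f"{k}:{v:.2f}" for k, v in
                                             sorted(overlaps.items(),
                                                    key=lambda kv: -kv[1]))})
    table = pd.DataFrame(rows, columns=["cluster_id", "size", "peak_F",
                                        "centroid_x", "centroid_y", "centroid_z",
                                        "main_roi", "roi_overlap"])
    table.attrs["n_dropped"] = dropped
    return table, out_lab


# ---------------------------------------------------------------------------
# regional post-hoc

@dataclass
class RegionalSummary:
    """Per-(group, time) means and per-group changes within one region."""

    region: str
    table: pd.DataFrame          # group, n, mean1, se1, mean2, se2, pct_change, t, p
    driving_group: str


def posthoc_regional(region_mask: np.ndarray, maps: np.ndarray,
                     groups: Sequence, region_name: str = "") -> RegionalSummary:
    """Post-hoc quantification of a cluster or ROI.

    ``maps`` is (N subjects, 2 times, X, Y, Z).  Per subject the regional
    mean is taken; per group the across-subject mean +/- SE at each time,
    the percent change 100*(m2-m1)/m1 and a paired t-test are reported.
    The group driving the interaction is the one with the largest
    standardized change |mean(d)| / SE(d).
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError(f"region {region_name!r} is empty")
    arr = np.asarray(maps, dtype=float)
    sub1 = np.nanmean(arr[:, 0][:, region_mask], axis=1)
    sub2 = np.nanmean(arr[:, 1][:, region_mask], axis=1)
    labels = np.asarray(groups)
    rows = []
    best, best_t = "", -np.inf
    for g in np.unique(labels):
        m = labels == g
        x1, x2 = sub1[m], sub2[m]
        d = x2 - x1
        n = int(m.sum())
        se_d = d.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        t_std = abs(d.mean() / se_d) if se_d and se_d > 0 else 0.0
        tt = sps.ttest_rel(x2, x1) if n > 1 else None
        pct = 100.0 * (x2.mean() - x1.mean()) / x1.mean() if x1.mean() != 0 else np.nan
        rows.append({"group": g, "n": n,
                     "mean1": x1.mean(), "se1": x1.std(ddof=1) / np.sqrt(n),
                     "mean2": x2.mean(), "se2": x2.std(ddof=1) / np.sqrt(n),
                     "pct_change": pct,
                     "t": tt.statistic if tt else np.nan,
                     "p": tt.pvalue if tt else np.nan})
        if t_std > best_t:
            best, best_t = str(g), t_std
    return RegionalSummary(region=region_name, table=pd.DataFrame(rows),
                           driving_group=best)


# ---------------------------------------------------------------------------
# age analysis and volumes

def age_analysis(maps: Mapping[str, np.ndarray], ages: Sequence[int],
                 mask: np.ndarray, roi_labels: np.ndarray | None = None,
                 roi_names: Mapping[int, str] | None = None,
                 indices: Sequence[str] | None = None
                 ) -> tuple[dict[str, StatResult], pd.DataFrame]:
    """Age x time split-plot analysis of the learning group.

    Same engine as the group analysis with age as the between factor.
    Returns the StatResults plus a per-(ROI, index, age) regional change
    table with 95% confidence intervals of the mean percent change.
    """
    present = set(int(a) for a in ages)
    if len(present) < 2:
        raise DesignError(f"need >=2 age subgroups, got {sorted(present)}")
    results = anova_map(maps, [str(a) for a in ages], mask,
                        indices=indices, between_factor="age")
    rows = []
    if roi_labels is not None and roi_names is not None:
        ages_arr = np.asarray(ages)
        for label, name in roi_names.items():
            rmask = (np.asarray(roi_labels) == label) & mask
            if not rmask.any():
                continue
            for index, arr in maps.items():
                if indices is not None and index not in indices:
                    continue
                arr = np.asarray(arr, float)
                sub1 = np.nanmean(arr[:, 0][:, rmask], axis=1)
                sub2 = np.nanmean(arr[:, 1][:, rmask], axis=1)
                pct = 100.0 * (sub2 - sub1) / sub1
                for a in sorted(present):
                    x = pct[ages_arr == a]
                    se = x.std(ddof=1) / np.sqrt(x.size)
                    ci = sps.t.ppf(0.975, x.size - 1) * se
                    rows.append({"roi": name, "index": index, "age_months": a,
                                 "n": x.size, "pct_change": x.mean(),
                                 "se": se, "ci95_lo": x.mean() - ci,
                                 "ci95_hi": x.mean() + ci})
    return results, pd.DataFrame(rows)


def roi_volume_change(labels_t1: Sequence[np.ndarray],
                      labels_t2: Sequence[np.ndarray], label: int,
                      voxel_volume: float) -> dict:
    """Percent volume change of one label across subjects, with a paired test.

    Volume = voxel count x voxel volume per subject and time point.
    """
    v1 = np.array([float((np.asarray(l) == label).sum()) * voxel_volume
                   for l in labels_t1])
    v2 = np.array([float((np.asarray(l) == label).sum()) * voxel_volume
                   for l in labels_t2])
    if np.any(v1 == 0):
        raise ValueError(f"label {label} empty in some subject at time 1")
    pct = 100.0 * (v2 - v1) / v1
    tt = sps.ttest_rel(v2, v1) if len(v1) > 1 else None
    return {"pct_change_mean": float(pct.mean()),
            "pct_change": pct,
            "t": float(tt.statistic) if tt else np.nan,
            "p": float(tt.pvalue) if tt else np.nan}
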