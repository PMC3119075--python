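"""Ground-truth tensor phantoms with region-specific effects.

The phantom stands in for an atlas-registered rat brain: an elliptical
"brain" mask on a small coronal grid, a handful of labelled regions of
interest (dentate gyrus DG, cingulate region CG, piriform cortex PC,
S1/S2 cortex SC, corpus callosum CC, plus a no-effect control region EC
and surrounding background grey matter), and a baseline diffusion tensor
per region.  Effects are injected as signed percent changes of either ADC
(all eigenvalues scaled together, leaving FA untouched) or FA (eigenvalue
spread rescaled about a fixed mean diffusivity).

Baseline eigenvalues are defaults typical of in-vivo rat brain at 7 T:
cortical grey matter is nearly isotropic with MD ~0.7e-3 mm^2/s, the
corpus callosum is strongly anisotropic, and the cingulate region is
modelled as the adjacent cingulum fiber bundle so that its FA is high
enough for fractional FA changes to be meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import default_affine
from .tensor import TensorField, matrices_to_tensors, tensors_to_matrices

GROUPS = ("L", "S", "NL")       # learning, swimming-only, nonlearning
AGES = (1, 4, 12)               # months


class PhantomError(ValueError):
    """Invalid phantom specification."""


class EffectError(ValueError):
    """Requested effect cannot be realized (e.g. FA out of feasible range)."""


def _basis_from_axis(axis: Sequence[float]) -> np.ndarray:
    """Deterministic orthonormal basis whose first column is ``axis``."""
    e1 = np.asarray(axis, dtype=float)
    n = np.linalg.norm(e1)
    if n == 0:
        raise PhantomError("principal direction must be nonzero")
    e1 = e1 / n
    helper = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e2 = np.cross(helper, e1)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=1)


@dataclass(frozen=True)
class ROIDef:
    """Axis-aligned voxel box carrying one baseline tensor."""

    label: int
    name: str
    lo: tuple[int, int, int]            # inclusive voxel corner
    hi: tuple[int, int, int]            # exclusive voxel corner
    eigenvalues: tuple[float, float, float]   # mm^2/s, sorted descending
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(ev < 0):
            raise PhantomError(f"ROI {self.name}: eigenvalues must be >= 0")
        if np.any(np.diff(ev) > 0):
            raise PhantomError(f"ROI {self.name}: eigenvalues must be sorted descending")
        if any(h <= l for l, h in zip(self.lo, self.hi)):
            raise PhantomError(f"ROI {self.name}: empty voxel extent")

    def tensor(self) -> np.ndarray:
        V = _basis_from_axis(self.axis)
        return V @ np.diag(self.eigenvalues) @ V.T


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, regions and baseline tensors of one synthetic brain."""

    shape: tuple[int, int, int] = (16, 16, 4)
    voxel_size: tuple[float, float, float] = (0.2, 0.2, 1.2)
    rois: tuple[ROIDef, ...] = ()
    background_eigenvalues: tuple[float, float, float] = (0.74e-3, 0.70e-3, 0.66e-3)
    background_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    background_label: int = 99
    mask_radius_fraction: float = 0.41   # in-plane ellipse, fraction of matrix
    s0: float = 1000.0
    bias_amplitude: float = 0.0          # max fractional deviation of the bias field

    def __post_init__(self) -> None:
        if not (0.0 <= self.bias_amplitude < 0.5):
            raise PhantomError("bias amplitude must be in [0, 0.5)")
        labels = [r.label for r in self.rois]
        if len(set(labels)) != len(labels):
            raise PhantomError(f"duplicate ROI labels: {sorted(labels)}")
        if self.background_label in labels:
            raise PhantomError("background label collides with an ROI label")
        # reject overlapping boxes up front, naming the offenders
        for i, a in enumerate(self.rois):
            for b in self.rois[i + 1:]:
                if all(a.lo[d] < b.hi[d] and b.lo[d] < a.hi[d] for d in range(3)):
                    raise PhantomError(
                        f"ROIs overlap: {a.name} (label {a.label}) and "
                        f"{b.name} (label {b.label})")

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.shape, self.voxel_size)

    def roi_by_name(self, name: str) -> ROIDef:
        for r in self.rois:
            if r.name == name:
                return r
        raise PhantomError(f"no ROI named {name!r}")


@dataclass
class ROILabelMap:
    """Integer label volume plus label<->name lookup."""

    data: np.ndarray
    names: dict[int, str]

    def mask_of(self, name: str) -> np.ndarray:
        for label, nm in self.names.items():
            if nm == name:
                return self.data == label
        raise KeyError(f"no ROI named {name!r}")


def brain_mask(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.shape
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    rx, ry = spec.mask_radius_fraction * nx, spec.mask_radius_fraction * ny
    inplane = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0
    return np.repeat(inplane[:, :, None], nz, axis=2)


def build_phantom(spec: PhantomSpec) -> tuple[TensorField, ROILabelMap, np.ndarray]:
    """Materialize a spec: tensor field, ROI label map and brain mask.

    Every in-mask voxel carries the baseline tensor of its region (the
    background region for unlabelled in-mask voxels); voxels outside the
    mask carry a zero tensor and zero S0, i.e. no signal.
    """
    mask = brain_mask(spec)
    labels = np.zeros(spec.shape, dtype=np.int16)
    d6 = np.zeros(spec.shape + (6,))
    names: dict[int, str] = {}

    bg = ROIDef(label=spec.background_label, name="background-GM",
                lo=(0, 0, 0), hi=spec.shape,
                eigenvalues=spec.background_eigenvalues,
                axis=spec.background_axis)
    d6[mask] = matrices_to_tensors(bg.tensor())
    labels[mask] = bg.label
    names[bg.label] = bg.name

    for roi in spec.rois:
        sl = tuple(slice(l, h) for l, h in zip(roi.lo, roi.hi))
        box = np.zeros(spec.shape, dtype=bool)
        box[sl] = True
        box &= mask
        labels[box] = roi.label
        d6[box] = matrices_to_tensors(roi.tensor())
        names[roi.label] = roi.name

    s0 = np.where(mask, spec.s0, 0.0)
    field = TensorField(d6=d6, s0=s0, voxel_size=spec.voxel_size,
                        affine=spec.affine, provenance={"phantom": True})
    return field, ROILabelMap(data=labels, names=names), mask


def bias_field(spec: PhantomSpec) -> np.ndarray:
    """Smooth multiplicative receive-coil field, max deviation = amplitude.

    Emulates a surface-coil intensity gradient from the brain surface (top
    of the slice) towards deeper structures, plus a mild quadratic term.
    """
    nx, ny, nz = spec.shape
    x = np.linspace(-1, 1, nx)[:, None, None]
    y = np.linspace(-1, 1, ny)[None, :, None]
    raw = 0.7 * (y + 1) / 2 + 0.3 * ((x + 1) / 2) ** 2
    raw = raw / raw.max()
    return np.broadcast_to(1.0 - spec.bias_amplitude * raw, (nx, ny, nz)).copy()


# ---------------------------------------------------------------------------
# effects

@dataclass(frozen=True)
class EffectSpec:
    """A region-, group- and age-specific percent change of ADC or FA.

    ``percent`` is the signed relative change applied at the second scan for
    subjects in ``groups``; per-age multipliers in ``attenuation`` rescale it
    (1.0 = full effect).
    """

    roi: str
    index: str                           # "ADC" or "FA"
    percent: float
    groups: tuple[str, ...] = ("L",)
    ages: tuple[int, ...] = AGES
    attenuation: Mapping[int, float] = field(default_factory=lambda: {a: 1.0 for a in AGES})

    def __post_init__(self) -> None:
        if self.index not in ("ADC", "FA"):
            raise EffectError(f"effect index must be ADC or FA, got {self.index!r}")
        if not (-50.0 < self.percent < 50.0):
            raise EffectError("percent change must be in (-50, 50)")
        if any(v < 0 for v in self.attenuation.values()):
            raise EffectError("attenuation factors must be >= 0")

    def effective_percent(self, group: str, age: int) -> float:
        """Percent change applying to one subject, 0 if the effect is inactive."""
        if group not in self.groups or age not in self.ages:
            return 0.0
        return self.percent * float(self.attenuation.get(age, 1.0))


def _fa_spread_scale(evals: np.ndarray, target_fa: np.ndarray) -> np.ndarray:
    """Scale ``s`` such that eigenvalues m + s*(lambda-m) attain ``target_fa``.

    Solves FA(s) = sqrt(3/2) * s r / sqrt(3 m^2 + s^2 r^2) for s, which keeps
    the mean diffusivity m exactly fixed by construction.
    """
    m = evals.mean(axis=-1)
    dev = evals - m[..., None]
    r2 = (dev ** 2).sum(axis=-1)
    denom = 1.5 - target_fa ** 2
    s2 = 3.0 * m ** 2 * target_fa ** 2 / (r2 * denom)
    return np.sqrt(s2)


def inject_effect(fld: TensorField, rois: ROILabelMap, effect: EffectSpec,
                  percent: float | None = None) -> TensorField:
    """Return a copy of the field with the effect applied inside its ROI.

    ADC effects scale all eigenvalues by (1 + pct/100), which leaves FA
    invariant; FA effects rescale the eigenvalue spread about the (exactly
    preserved) mean diffusivity.  Voxels outside the ROI are bit-identical.
    """
    pct = effect.percent if percent is None else percent
    if pct == 0.0:
        return fld.copy()
    roi = rois.mask_of(effect.roi)
    out = fld.copy()
    factor = 1.0 + pct / 100.0

    if effect.index == "ADC":
        out.d6[roi] = fld.d6[roi] * factor
        return out

    # FA: eigen-decompose ROI voxels and rescale the spread about the mean
    D = tensors_to_matrices(fld.d6[roi])
    w, V = np.linalg.eigh(D)
    m = w.mean(axis=-1)
    dev = w - m[..., None]
    r2 = (dev ** 2).sum(axis=-1)
    norm2 = (w ** 2).sum(axis=-1)
    fa0 = np.where(norm2 > 0, np.sqrt(1.5 * r2 / np.where(norm2 > 0, norm2, 1.0)), 0.0)
    if np.any(r2 <= 0) or np.any(m <= 0):
        raise EffectError(
            f"FA change on ROI {effect.roi!r}: baseline FA is 0 somewhere, "
            "a relative FA change is undefined there")
    fa1 = fa0 * factor
    dev_min = dev.min(axis=-1)
    s_max = m / (-dev_min)
    r = np.sqrt(r2)
    fa_max = np.sqrt(1.5) * s_max * r / np.sqrt(3 * m ** 2 + s_max ** 2 * r2)
    if np.any(fa1 >= np.sqrt(1.5)) or np.any(fa1 > fa_max + 1e-12):
        raise EffectError(
            f"FA change of {pct:+.3g}% on ROI {effect.roi!r} is infeasible: "
            f"feasible relative change is ({-100.0:.3g}%, "
            f"{float(100 * (fa_max.min() / fa0.max() - 1)):+.3g}%] "
            "(eigenvalues would become negative)")
    s = _fa_spread_scale(w, fa1)
    w_new = m[..., None] + s[..., None] * dev
    D_new = V @ (w_new[..., None] * np.swapaxes(V, -1, -2))
    out.d6[roi] = matrices_to_tensors(D_new)
    return out


# ---------------------------------------------------------------------------
# default study phantom and effect set

# canonical ROI boxes on a 16 x 16 x 4 grid (scaled for other shapes); the
# structures span the whole slab, so boxes cover the full slice extent.
# Regions analyzed on the same index map (ADC: DG/PC/SC; FA: CG/CC) are laid
# out with >=4-voxel gaps so their clusters stay distinct under 26-connectivity
# even with smoothing spillover.  CG is modelled as the cingulum fiber bundle
# (the white matter adjacent to the cingulate cortex) so that its FA is high
# enough for a fractional FA change to be a well-posed target.
_CANONICAL_BOXES = {
    # name: (label, lo, hi, eigenvalues (mm^2/s), axis)
    "DG": (1, (6, 2, 0), (9, 5, 4), (0.78e-3, 0.70e-3, 0.62e-3), (0, 0, 1)),
    "CG": (2, (10, 3, 0), (13, 6, 4), (1.30e-3, 0.35e-3, 0.30e-3), (0, 1, 0)),
    "PC": (3, (2, 9, 0), (5, 12, 4), (0.76e-3, 0.70e-3, 0.64e-3), (1, 0, 0)),
    "SC": (4, (11, 9, 0), (14, 12, 4), (0.77e-3, 0.69e-3, 0.64e-3), (1, 0, 0)),
    "CC": (5, (2, 4, 0), (5, 7, 4), (1.40e-3, 0.30e-3, 0.30e-3), (1, 0, 0)),
    "EC": (6, (6, 10, 0), (9, 13, 4), (0.75e-3, 0.70e-3, 0.65e-3), (1, 0, 0)),
}


def default_phantom_spec(shape: tuple[int, int, int] = (16, 16, 4),
                         **overrides) -> PhantomSpec:
    """The study phantom: five effect regions plus a no-effect control (EC).

    ROI boxes are defined on a canonical 16 x 16 x 4 grid and scaled
    proportionally to other shapes.
    """
    sx, sy, sz = shape[0] / 16.0, shape[1] / 16.0, shape[2] / 4.0
    rois = []
    for name, (label, lo, hi, ev, axis) in _CANONICAL_BOXES.items():
        lo_s = (round(lo[0] * sx), round(lo[1] * sy), round(lo[2] * sz))
        hi_s = (round(hi[0] * sx), round(hi[1] * sy), round(hi[2] * sz))
        rois.append(ROIDef(label=label, name=name, lo=lo_s, hi=hi_s,
                           eigenvalues=ev, axis=axis))
    return PhantomSpec(shape=shape, rois=tuple(rois), **overrides)


def default_effects() -> list[EffectSpec]:
    """The study effect pattern.

    Learning-group (L) effects: ADC decreases in DG and PC, FA decrease in
    CG, FA increase in CC; swimming-group (S) effect: strong ADC decrease in
    SC.  The DG effect is age-stable; CG and CC effects weaken with age.
    """
    aging = {1: 1.3, 4: 1.0, 12: 0.5}
    flat = {1: 1.0, 4: 1.0, 12: 1.0}
    return [
        EffectSpec(roi="DG", index="ADC", percent=-2.5, groups=("L",), attenuation=flat),
        EffectSpec(roi="PC", index="ADC", percent=-2.5, groups=("L",), attenuation=flat),
        EffectSpec(roi="CG", index="FA", percent=-2.5, groups=("L",), attenuation=aging),
        EffectSpec(roi="CC", index="FA", percent=+3.0, groups=("L",), attenuation=aging),
        EffectSpec(roi="SC", index="ADC", percent=-6.0, groups=("S",), attenuation=flat),
    ]


def apply_effects(fld: TensorField, rois: ROILabelMap,
                  effects: Sequence[EffectSpec], group: str, age: int) -> TensorField:
    """Field seen at the second scan by one subject: all applicable effects."""
    out = fld
    for eff in effects:
        pct = eff.effective_percent(group, age)
        if pct != 0.0:
            out = inject_effect(out, rois, eff, percent=pct)
    if out is fld:
        out = fld.copy()
    return out
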