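"""Segmentation evaluation metrics, millimetre-aware.

Six metrics per region of interest: Dice overlap D, the 95th-percentile
Hausdorff distance HD95 (mm), volume similarity VS, compactness score CS,
precision P and recall R.

* D = 2|Y ∩ Yt| / (|Y| + |Yt|)
* HD95: surface voxels are extracted by XOR with a connectivity-1 erosion;
  the two directed surface-to-surface distance arrays (voxel-center
  distances, anisotropy-aware) are pooled and their 95th percentile taken —
  the convention of the MedPy library.
* VS = 1 - ||Yt| - |Y|| / (|Yt| + |Y|); depends on volumes only.
* Compactness C = area^1.5 / volume with the surface area obtained by
  exposed-face counting (each exposed voxel face contributes its mm^2 area),
  and CS = 1 - 2|C - C_GT| / (C + C_GT), equal to 1 iff the two compactness
  values coincide.
* P = |Y ∩ Yt| / |Y|, R = |Y ∩ Yt| / |Yt|.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ShapeError
from .grids import CONTRA, IPSI, LabelMap

METRIC_NAMES = ("dice", "hd95", "vs", "cs", "precision", "recall")
ROI_NAMES = {IPSI: "ipsi", CONTRA: "contra"}


def _as_bool(a):
    return np.asarray(a).astype(bool)


def _check(y, yt):
    y, yt = _as_bool(y), _as_bool(yt)
    if y.shape != yt.shape:
        raise ShapeError(f"mask shapes differ: {y.shape} vs {yt.shape}")
    return y, yt


def dice(y, yt) -> float:
    y, yt = _check(y, yt)
    if not yt.any():
        raise DegenerateInputError("empty ground truth")
    inter = np.logical_and(y, yt).sum()
    return 2.0 * inter / (y.sum() + yt.sum())


def _surface(mask: np.ndarray) -> np.ndarray:
    footprint = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=footprint, iterations=1)
    return mask ^ eroded


def _directed_surface_distances(a: np.ndarray, b: np.ndarray, spacing) -> np.ndarray:
    """Distances from each surface voxel of ``a`` to the nearest surface
    voxel of ``b``, in mm."""
    sb = _surface(b)
    dt = ndimage.distance_transform_edt(~sb, sampling=spacing)
    return dt[_surface(a)]


def hd95(y, yt, spacing) -> float:
    """95th percentile of the pooled bidirectional surface distances (mm)."""
    y, yt = _check(y, yt)
    if not y.any() or not yt.any():
        raise DegenerateInputError("hd95 requires both masks nonempty")
    d1 = _directed_surface_distances(y, yt, spacing)
    d2 = _directed_surface_distances(yt, y, spacing)
    return float(np.percentile(np.hstack((d1, d2)), 95))


def volume_similarity(y, yt) -> float:
    y, yt = _check(y, yt)
    ny, nt = int(y.sum()), int(yt.sum())
    if ny + nt == 0:
        raise DegenerateInputError("both masks empty")
    return 1.0 - abs(nt - ny) / (nt + ny)


def surface_area(mask, spacing) -> float:
    """Total exposed-face area in mm^2 (each voxel face between in and out,
    including volume borders, contributes its face area)."""
    mask = _as_bool(mask)
    dx, dy, dz = spacing
    face_areas = (dy * dz, dx * dz, dx * dy)
    total = 0.0
    for ax, fa in enumerate(face_areas):
        m = np.moveaxis(mask, ax, 0)
        total += fa * (m[0].sum() + m[-1].sum() + np.abs(np.diff(m.astype(np.int8), axis=0)).sum())
    return float(total)


def compactness(mask, spacing) -> float:
    mask = _as_bool(mask)
    if not mask.any():
        raise DegenerateInputError("empty mask has no compactness")
    vol = mask.sum() * float(np.prod(spacing))
    return surface_area(mask, spacing) ** 1.5 / vol


def compactness_score(y, yt, spacing) -> float:
    c = compactness(y, spacing)
    cgt = compactness(yt, spacing)
    return 1.0 - 2.0 * abs(c - cgt) / (c + cgt)


def precision_recall(y, yt) -> tuple[float, float]:
    y, yt = _check(y, yt)
    if not y.any():
        raise DegenerateInputError("empty prediction: precision undefined")
    if not yt.any():
        raise DegenerateInputError("empty ground truth: recall undefined")
    inter = np.logical_and(y, yt).sum()
    return inter / y.sum(), inter / yt.sum()


@dataclasses.dataclass
class MetricsReport:
    """Per-ROI metric values; unavailable entries are None with a reason."""

    per_roi: dict  # roi name -> {metric name -> float | None}
    reasons: dict  # roi name -> {metric name -> str}
    volumes_mm3: dict  # roi name -> {"pred": float, "truth": float}

    def as_flat_dict(self) -> dict:
        out = {}
        for roi, metrics in self.per_roi.items():
            for m, v in metrics.items():
                out[f"{roi}_{m}"] = v
            out[f"{roi}_volume_pred_mm3"] = self.volumes_mm3[roi]["pred"]
            out[f"{roi}_volume_truth_mm3"] = self.volumes_mm3[roi]["truth"]
        return out


def evaluate_masks(y, yt, spacing) -> tuple[dict, dict]:
    """All six metrics for one mask pair; per-metric failures recorded."""
    values, reasons = {}, {}

    def attempt(name, fn):
        try:
            values[name] = float(fn())
            return values[name]
        except DegenerateInputError as exc:
            values[name] = None
            reasons[name] = str(exc)
            return None

    attempt("dice", lambda: dice(y, yt))
    attempt("hd95", lambda: hd95(y, yt, spacing))
    attempt("vs", lambda: volume_similarity(y, yt))
    attempt("cs", lambda: compactness_score(y, yt, spacing))
    try:
        p, r = precision_recall(y, yt)
        values["precision"], values["recall"] = float(p), float(r)
    except DegenerateInputError as exc:
        # recall may survive an empty prediction and vice versa
        yb, ytb = _as_bool(y), _as_bool(yt)
        inter = np.logical_and(yb, ytb).sum()
        if yb.any():
            values["precision"] = float(inter / yb.sum())
        else:
            values["precision"] = None
            reasons["precision"] = "empty prediction"
        if ytb.any():
            values["recall"] = float(inter / ytb.sum())
        else:
            values["recall"] = None
            reasons["recall"] = "empty ground truth"
    return values, reasons


def evaluate_pair(pred: LabelMap, truth: LabelMap) -> MetricsReport:
    """Six metrics per hippocampus ROI plus volumes in mm^3."""
    if pred.shape != truth.shape:
        raise ShapeError("prediction and truth shapes differ")
    spacing = truth.spacing
    vox = truth.voxel_volume
    per_roi, reasons, volumes = {}, {}, {}
    for code, name in ROI_NAMES.items():
        y = pred.class_mask(code)
        yt = truth.class_mask(code)
        vals, why = evaluate_masks(y, yt, spacing)
        per_roi[name] = vals
        reasons[name] = why
        volumes[name] = {"pred": float(y.sum() * vox), "truth": float(yt.sum() * vox)}
    return MetricsReport(per_roi=per_roi, reasons=reasons, volumes_mm3=volumes)
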