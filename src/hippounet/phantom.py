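"""Synthetic rat-brain phantom cohorts with ground-truth labels.

Real preclinical TBI MRI is not redistributable, so every downstream stage of
the pipeline is exercised on stylized phantoms that reproduce the geometric
phenotypes that make the segmentation problem hard: an ellipsoidal brain, two
mirrored banana-shaped (torus-sector) hippocampi, a unilateral left cortical
lesion cavity, ventricular enlargement, hippocampal atrophy and displacement
that grow with post-injury time, a smooth multiplicative bias field, and
additive Gaussian noise.

Two voxel dialects mirror the two cohort types the tool targets: an isotropic
3D dialect (0.16 mm cubic voxels) and an anisotropic multi-slice dialect
(0.15 x 0.15 mm in-plane, 0.5 mm slices).

The generator is a pure function of its spec and seed: identical inputs give
bit-identical volumes.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SpecError
from .grids import IPSI, CONTRA, LabelMap, VolumeGrid, write_labels, write_volume

ISO_SPACING = (0.16, 0.16, 0.16)
ANISO_SPACING = (0.15, 0.15, 0.5)
DESK_SHAPE_ISO = (64, 64, 48)
DESK_SHAPE_ANISO = (64, 64, 24)

# stylized tissue intensities (arbitrary units, T2*-weighted-like contrast:
# CSF bright, parenchyma mid, extracranial dark)
I_BACKGROUND = 0.05
I_BRAIN = 1.0
I_HIPPO = 1.25
I_VENTRICLE = 1.7
I_LESION = 1.55
I_CORTEX = 0.9


@dataclasses.dataclass
class PhantomSpec:
    """Generative parameters for one synthetic animal at one timepoint."""

    shape: tuple[int, int, int] = DESK_SHAPE_ISO
    spacing: tuple[float, float, float] = ISO_SPACING
    injury: str = "sham"  # "sham" or "TBI"
    timepoint_days: int = 0
    lesion_severity: float = 0.0  # in [0, 1]
    atrophy_fraction: float = 0.0  # in [0, 0.5]
    ventricle_enlargement: float = 0.0  # >= 0, fractional radius growth
    noise_sd: float = 0.05
    bias_amplitude: float = 0.1
    size_factor: float = 1.0  # per-animal overall brain scale
    seed: int = 0

    def validate(self) -> None:
        if self.injury not in ("sham", "TBI"):
            raise SpecError(f"injury must be 'sham' or 'TBI', got {self.injury!r}")
        if self.injury == "sham" and (self.lesion_severity != 0 or self.atrophy_fraction != 0):
            raise SpecError("sham phantoms must have zero lesion severity and atrophy")
        if not 0.0 <= self.lesion_severity <= 1.0:
            raise SpecError("lesion_severity must lie in [0, 1]")
        if not 0.0 <= self.atrophy_fraction <= 0.5:
            raise SpecError("atrophy_fraction must lie in [0, 0.5]")
        if self.ventricle_enlargement < 0 or self.noise_sd < 0 or self.bias_amplitude < 0:
            raise SpecError("ventricle_enlargement, noise_sd, bias_amplitude must be >= 0")
        if self.timepoint_days < 0:
            raise SpecError("timepoint_days must be >= 0")
        if min(self.shape) < 8:
            raise SpecError("phantom grid too small")


def _mm_grids(shape, spacing):
    """Coordinate grids in mm, origin at the volume center."""
    axes = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(x, y, z, center, semi):
    return ((x - center[0]) / semi[0]) ** 2 + ((y - center[1]) / semi[1]) ** 2 + (
        (z - center[2]) / semi[2]
    ) ** 2 <= 1.0


def _hippocampus_mask(x, y, z, side, scale=1.0, shift=(0.0, 0.0, 0.0), extent_mm=None):
    """Banana-shaped hippocampus: a sector of a torus bent around a dorso-ventral
    axis placed in one hemisphere, elongated rostro-caudally.

    ``side`` is +1 for the right hemisphere (x > 0) and -1 for the left;
    ``scale`` shrinks the tube linearly in all directions about the structure
    center (volume ~ scale^3); ``shift`` displaces the center in mm.
    """
    ex, ey, ez = extent_mm
    # torus ring center per hemisphere; sized to sit fully inside the brain
    # ellipsoid so that linear scaling translates exactly into volume scaling
    cx = side * 0.12 * ex
    cy = 0.0
    cz = 0.05 * ez
    xs = (x - cx - shift[0]) / scale
    ys = (y - cy - shift[1]) / scale
    zs = (z - cz - shift[2]) / scale
    ring_r = 0.15 * ey  # major radius, bent in the x-y plane
    tube_a = 0.06 * ex  # tube semi-axis, left-right
    tube_c = 0.12 * ez  # tube semi-axis, dorso-ventral
    rho = np.sqrt(xs**2 + ys**2)
    radial = (rho - ring_r) / tube_a
    vertical = zs / tube_c
    in_tube = radial**2 + vertical**2 <= 1.0
    # keep a lateral-to-rostral arc that stays within its hemisphere
    theta = np.arctan2(ys, xs * side)
    sector = (theta > -0.25 * np.pi) & (theta < 0.58 * np.pi)
    return in_tube & sector


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeGrid, LabelMap]:
    """Generate one synthetic animal: intensity volume plus ground-truth labels."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape, spacing = tuple(spec.shape), tuple(spec.spacing)
    x, y, z = _mm_grids(shape, spacing)
    extent_mm = tuple(n * s for n, s in zip(shape, spacing))
    ex, ey, ez = extent_mm

    s = spec.size_factor
    brain = _ellipsoid(x, y, z, (0, 0, 0), (0.38 * ex * s, 0.44 * ey * s, 0.34 * ez * s))

    # ventricles: two small midline-adjacent ellipsoids, dilated under injury
    vent_grow = 1.0 + spec.ventricle_enlargement
    vent = np.zeros_like(brain)
    for side in (-1, 1):
        vent |= _ellipsoid(
            x,
            y,
            z,
            (side * 0.08 * ex, 0.05 * ey, 0.18 * ez),
            (0.045 * ex * vent_grow, 0.16 * ey * vent_grow, 0.07 * ez * vent_grow),
        )
    vent &= brain

    # hippocampi; left (= ipsilateral, label 1) atrophied and displaced for TBI
    scale_l = (1.0 - spec.atrophy_fraction) ** (1.0 / 3.0)
    # displacement towards the dorso-lateral left cavity
    disp = spec.lesion_severity * 0.35 + spec.atrophy_fraction * 0.5
    shift_l = (-disp * 0.04 * ex, 0.0, disp * 0.05 * ez)
    hc_left = _hippocampus_mask(x, y, z, side=-1, scale=scale_l, shift=shift_l, extent_mm=extent_mm)
    hc_right = _hippocampus_mask(x, y, z, side=+1, extent_mm=extent_mm)
    hc_left &= brain
    hc_right &= brain
    hc_left &= ~vent
    hc_right &= ~vent

    # cortical lesion cavity: dorso-lateral left spherical cap, never
    # overlapping the hippocampi
    lesion = np.zeros_like(brain)
    if spec.injury == "TBI" and spec.lesion_severity > 0:
        r = (0.06 + 0.10 * spec.lesion_severity) * min(ex, ez)
        center = (-0.26 * ex, -0.05 * ey, 0.22 * ez)
        lesion = _ellipsoid(x, y, z, center, (r, 1.8 * r, r)) & brain
        lesion &= ~(hc_left | hc_right)

    if not hc_left.any() or not hc_right.any():
        raise SpecError("lesion/atrophy parameters erased a hippocampus")

    labels = np.zeros(shape, dtype=np.uint8)
    labels[hc_left] = IPSI
    labels[hc_right] = CONTRA

    # intensity model: cortex rim darker than deep parenchyma for extra texture
    cortex = brain & ~_ellipsoid(
        x, y, z, (0, 0, 0), (0.33 * ex * s, 0.39 * ey * s, 0.29 * ez * s)
    )
    intens = np.full(shape, I_BACKGROUND, dtype=np.float32)
    intens[brain] = I_BRAIN
    intens[cortex] = I_CORTEX
    intens[hc_left | hc_right] = I_HIPPO
    intens[vent] = I_VENTRICLE
    intens[lesion] = I_LESION

    # smooth multiplicative bias field: low-order separable polynomial
    coeff = rng.uniform(-1.0, 1.0, size=6)
    u = x / (0.5 * ex)
    v = y / (0.5 * ey)
    w = z / (0.5 * ez)
    field = coeff[0] * u + coeff[1] * v + coeff[2] * w + coeff[3] * u * v + coeff[4] * v * w + coeff[5] * u * w
    field = 1.0 + spec.bias_amplitude * field / 2.0
    intens = intens * field.astype(np.float32)

    if spec.noise_sd > 0:
        intens = intens + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    vol = VolumeGrid(data=intens.astype(np.float32), spacing=spacing)
    lab = LabelMap(labels=labels, brain=brain, spacing=spacing)
    return vol, lab


@dataclasses.dataclass
class CohortSpec:
    """Animal x timepoint structure of a synthetic study."""

    n_tbi: int = 6
    n_sham: int = 4
    timepoints: tuple[int, ...] = (2, 9, 30, 150)
    dialect: str = "isotropic3D"  # or "anisotropic2D"
    missing: tuple[tuple[int, int], ...] = ()  # (animal_index, timepoint_days)
    shape: tuple[int, int, int] | None = None

    @property
    def n_animals(self) -> int:
        return self.n_tbi + self.n_sham

    def validate(self) -> None:
        if self.n_tbi < 0 or self.n_sham < 0 or self.n_animals == 0:
            raise SpecError("cohort must contain at least one animal")
        if self.dialect not in ("isotropic3D", "anisotropic2D"):
            raise SpecError(f"unknown dialect {self.dialect!r}")
        for a, t in self.missing:
            if not (0 <= a < self.n_animals):
                raise SpecError(f"missing entry names unknown animal {a}")
            if t not in self.timepoints:
                raise SpecError(f"missing entry names unknown timepoint {t}")

    def grid(self) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
        if self.dialect == "isotropic3D":
            return (self.shape or DESK_SHAPE_ISO, ISO_SPACING)
        return (self.shape or DESK_SHAPE_ANISO, ANISO_SPACING)


def _animal_effects(rng: np.random.Generator, is_tbi: bool) -> dict:
    """Per-animal random effects, constant across timepoints."""
    return {
        "size_factor": float(rng.uniform(0.92, 1.08)),
        "lesion_severity": float(rng.uniform(0.4, 0.9)) if is_tbi else 0.0,
        "max_atrophy": float(rng.uniform(0.15, 0.35)) if is_tbi else 0.0,
        "max_vent": float(rng.uniform(0.2, 0.6)) if is_tbi else 0.0,
    }


def _atrophy_at(max_atrophy: float, t_days: int) -> float:
    # saturating growth: ~0 at day 0, half-max around three weeks
    return max_atrophy * t_days / (t_days + 21.0)


def spec_for(cohort: CohortSpec, seed: int, animal: int, t_days: int) -> PhantomSpec:
    """PhantomSpec for one (animal, timepoint) cell of a cohort.

    Per-animal effects are drawn from a stream keyed by (seed, animal) only, so
    they are constant across timepoints; the per-scan noise seed is keyed by
    (seed, animal, timepoint).
    """
    cohort.validate()
    is_tbi = animal < cohort.n_tbi
    eff_rng = np.random.default_rng([seed, animal])
    eff = _animal_effects(eff_rng, is_tbi)
    shape, spacing = cohort.grid()
    atrophy = _atrophy_at(eff["max_atrophy"], t_days) if is_tbi else 0.0
    return PhantomSpec(
        shape=shape,
        spacing=spacing,
        injury="TBI" if is_tbi else "sham",
        timepoint_days=t_days,
        lesion_severity=eff["lesion_severity"] if is_tbi else 0.0,
        atrophy_fraction=round(atrophy, 6),
        ventricle_enlargement=eff["max_vent"] * t_days / (t_days + 21.0) if is_tbi else 0.0,
        size_factor=eff["size_factor"],
        seed=int(np.random.default_rng([seed, animal, t_days]).integers(0, 2**31 - 1)),
    )


def generate_cohort(cohort: CohortSpec, seed: int, out_dir, force: bool = False) -> pd.DataFrame:
    """Write one (volume, labels, brain) NIfTI triple per non-missing cell.

    Returns the manifest (also written as ``manifest.csv``) with columns
    animal, group, timepoint_days, volume_path, label_path, brain_path.
    """
    cohort.validate()
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not force:
        raise SpecError(f"{manifest_path} exists; pass force=True to overwrite")
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    missing = set((a, t) for a, t in cohort.missing)
    for animal in range(cohort.n_animals):
        group = "TBI" if animal < cohort.n_tbi else "sham"
        for t in cohort.timepoints:
            if (animal, t) in missing:
                continue
            spec = spec_for(cohort, seed, animal, t)
            vol, lab = generate_phantom(spec)
            stem = f"a{animal:02d}_d{t:03d}"
            vp = out_dir / f"{stem}_vol.nii"
            lp = out_dir / f"{stem}_lab.nii"
            bp = out_dir / f"{stem}_brain.nii"
            write_volume(vol, vp)
            write_labels(lab, lp, bp)
            rows.append(
                {
                    "animal": animal,
                    "group": group,
                    "timepoint_days": t,
                    "volume_path": str(vp),
                    "label_path": str(lp),
                    "brain_path": str(bp),
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, index=False)
    (out_dir / "manifest.json").write_text(
        json.dumps({"seed": seed, "cohort": dataclasses.asdict(cohort)}, default=list, indent=2)
    )
    return manifest


def cohort_in_memory(cohort: CohortSpec, seed: int) -> list[dict]:
    """Like :func:`generate_cohort` but keeps arrays in memory (no files)."""
    cohort.validate()
    out = []
    missing = set((a, t) for a, t in cohort.missing)
    for animal in range(cohort.n_animals):
        group = "TBI" if animal < cohort.n_tbi else "sham"
        for t in cohort.timepoints:
            if (animal, t) in missing:
                continue
            vol, lab = generate_phantom(spec_for(cohort, seed, animal, t))
            out.append(
                {"animal": animal, "group": group, "timepoint_days": t, "volume": vol, "labels": lab}
            )
    return out


def sparse_annotate(mask: np.ndarray) -> np.ndarray:
    """Zero out every second sagittal slice of a binary brain mask.

    Emulates sparse manual annotation where only alternating sagittal slices
    are outlined; the counterpart operation is
    :func:`hippounet.postprocess.complete_brain_mask`. The sagittal axis is
    axis 0 (left-right).
    """
    mask = np.asarray(mask).astype(bool)
    out = mask.copy()
    out[1::2, :, :] = False
    return out
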