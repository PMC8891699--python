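"""Volume and label containers plus NIfTI readers/writers.

A :class:`VolumeGrid` is a single-channel 3D intensity array with millimetre
voxel spacing and a 4x4 affine; a :class:`LabelMap` carries the integer-coded
segmentation (0 background, 1 ipsilateral hippocampus, 2 contralateral
hippocampus) together with a separate binary brain mask on the same grid.
"Ipsilateral" is fixed to the left hemisphere, matching the left-hemisphere
injury model the tool targets.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DegenerateInputError, FormatError, ShapeError

#: integer codes of the segmentation classes
BACKGROUND, IPSI, CONTRA = 0, 1, 2
N_CLASSES = 3


def _spacing_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


def _affine_from_spacing(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclasses.dataclass
class VolumeGrid:
    """3D intensity volume with voxel spacing in mm and orientation affine."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be three positive numbers, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume contains non-finite values")
        if self.affine is None:
            self.affine = _affine_from_spacing(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def slice_axis(self) -> int:
        """Axis along which 2D (coronal-plane) processing slices the volume.

        The slice axis is the lowest-resolution axis, i.e. the one with the
        largest voxel spacing; ties resolve to the last axis so isotropic
        volumes behave deterministically.
        """
        sp = np.asarray(self.spacing)
        return int(np.flatnonzero(sp == sp.max())[-1])


@dataclasses.dataclass
class LabelMap:
    """Integer segmentation plus binary brain mask aligned with a VolumeGrid."""

    labels: np.ndarray
    brain: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.brain = np.asarray(self.brain).astype(bool)
        if self.labels.ndim != 3 or self.brain.ndim != 3:
            raise ShapeError("labels and brain mask must be 3D")
        if self.labels.shape != self.brain.shape:
            raise ShapeError("labels and brain mask must share a shape")
        if not np.isin(np.unique(self.labels), (BACKGROUND, IPSI, CONTRA)).all():
            raise FormatError("labels must be coded {0, 1, 2}")
        self.labels = self.labels.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _affine_from_spacing(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def class_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def one_hot(self) -> np.ndarray:
        """(3, X, Y, Z) float32 one-hot encoding of the segmentation."""
        out = np.zeros((N_CLASSES,) + self.labels.shape, dtype=np.float32)
        for c in range(N_CLASSES):
            out[c] = self.labels == c
        return out


def read_volume(path) -> VolumeGrid:
    """Read a NIfTI volume.

    Singleton trailing dimensions (e.g. a 4D file with one frame) are
    squeezed; spacing comes from the header affine.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various types
        raise FormatError(f"not a readable NIfTI file: {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected a 3D payload in {path}, got shape {data.shape}")
    spacing = _spacing_from_affine(img.affine)
    if any(s <= 0 for s in spacing):
        raise FormatError(f"non-positive voxel spacing in {path}: {spacing}")
    data = np.asarray(data, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise FormatError(f"non-finite voxel values in {path}")
    return VolumeGrid(data=data, spacing=spacing, affine=img.affine)


def write_volume(v: VolumeGrid, path) -> None:
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), v.affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def read_labels(labels_path, brain_path) -> LabelMap:
    lab = read_volume(labels_path)
    brain = read_volume(brain_path)
    if lab.shape != brain.shape:
        raise ShapeError("label and brain volumes disagree in shape")
    return LabelMap(
        labels=np.rint(lab.data).astype(np.uint8),
        brain=np.rint(brain.data).astype(bool),
        spacing=lab.spacing,
        affine=lab.affine,
    )


def write_labels(l: LabelMap, labels_path, brain_path=None) -> None:
    img = nib.Nifti1Image(l.labels.astype(np.uint8), l.affine)
    img.header.set_zooms(l.spacing)
    nib.save(img, str(labels_path))
    if brain_path is not None:
        img = nib.Nifti1Image(l.brain.astype(np.uint8), l.affine)
        img.header.set_zooms(l.spacing)
        nib.save(img, str(brain_path))


def standardize(v: VolumeGrid) -> VolumeGrid:
    """Return a copy normalized to zero mean and unit variance.

    Raises :class:`DegenerateInputError` on (near-)constant volumes.
    """
    data = np.asarray(v.data, dtype=np.float32)
    mean = float(data.mean())
    std = float(data.std())
    if std < 1e-7:
        raise DegenerateInputError("cannot standardize a constant volume")
    return VolumeGrid(data=(data - mean) / std, spacing=v.spacing, affine=v.affine)
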