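"""Volumetric image containers, NIfTI-1 I/O, and binary mask morphology.

A study case bundles the three co-registered MR channels used for tumor
profiling (contrast-enhanced VIBE, the ADC map, and the b=1000 diffusion
image) with a binary tumor mask on the same voxel grid.  Masks produced by
automated segmentation may contain several disconnected components; all
foreground voxels are profiled.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

CHANNELS = ("VIBE+C", "ADC", "b1000")
FIELD_STRENGTHS = ("1.5T", "3T")

#: 6-connected cross-shaped 3x3x3 structuring element used by the
#: mask-perturbation robustness protocol.
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


class GeometryError(ValueError):
    """Shapes or spacings of channels/mask disagree."""


class EmptyMaskError(ValueError):
    """Mask contains no foreground voxels (undetected tumor)."""


class NonFiniteDataError(ValueError):
    """Voxel data contain NaN or infinity."""


@dataclasses.dataclass
class ImageVolume:
    """One MR channel: a 3D voxel array with physical spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    channel: str
    field_strength: str = "1.5T"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise GeometryError("channel volume must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"non-positive spacing {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise NonFiniteDataError(f"channel {self.channel} has non-finite voxels")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if self.field_strength not in FIELD_STRENGTHS:
            raise ValueError(f"unknown field strength {self.field_strength!r}")


@dataclasses.dataclass
class TumorMask:
    """Binary tumor segmentation on the same grid as the channels."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise GeometryError("mask must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"non-positive spacing {self.spacing}")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclasses.dataclass
class ClinicalRecord:
    """Clinico-pathological annotation for one patient.

    Categorical fields use the closed vocabularies of the cohort tables
    (histology endometrioid / non-endometrioid, grade 1-2 / 3, FIGO I-II /
    III-IV, ...); survival times are in months.
    """

    age_class: str | None = None
    histologic_type: str | None = None
    grade: str | None = None
    figo_stage: str | None = None
    myometrial_infiltration: str | None = None
    lymph_node_metastasis: str | None = None
    er_status: str | None = None
    pr_status: str | None = None
    ar_status: str | None = None
    molecular_class: str | None = None
    survival_months: float | None = None
    dss_event: int | None = None
    recurrence_months: float | None = None
    recurrence_event: int | None = None

    def __post_init__(self) -> None:
        for t in (self.survival_months, self.recurrence_months):
            if t is not None and t < 0:
                raise ValueError("survival/recurrence time must be >= 0")


@dataclasses.dataclass
class StudyCase:
    """One patient: three channel volumes + tumor mask + optional clinical data."""

    case_id: str
    channels: Mapping[str, ImageVolume]
    mask: TumorMask
    clinical: ClinicalRecord | None = None
    group_truth: str | None = None  # planted group for synthetic cohorts

    def __post_init__(self) -> None:
        shapes = {c.voxels.shape for c in self.channels.values()}
        shapes.add(self.mask.voxels.shape)
        if len(shapes) != 1:
            raise GeometryError(f"case {self.case_id}: inconsistent grids {shapes}")
        fs = {c.field_strength for c in self.channels.values()}
        if len(fs) != 1:
            raise GeometryError(f"case {self.case_id}: inconsistent field strengths {fs}")

    @property
    def field_strength(self) -> str:
        return next(iter(self.channels.values())).field_strength

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.mask.spacing


# ---------------------------------------------------------------------------
# NIfTI-1 I/O
# ---------------------------------------------------------------------------

def _affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_case(case: StudyCase, out_dir: str | Path) -> dict[str, Path]:
    """Write each channel and the mask as .nii.gz; returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    aff = _affine(case.spacing)
    for tag, vol in case.channels.items():
        safe = tag.replace("+", "").replace("/", "_").lower()
        p = out_dir / f"{case.case_id}_{safe}.nii.gz"
        nib.save(nib.Nifti1Image(vol.voxels.astype(np.float64), aff), p)
        paths[tag] = p
    p = out_dir / f"{case.case_id}_mask.nii.gz"
    nib.save(nib.Nifti1Image(case.mask.voxels.astype(np.uint8), aff), p)
    paths["mask"] = p
    return paths


def read_case(
    case_id: str,
    channel_paths: Mapping[str, str | Path],
    mask_path: str | Path,
    field_strength: str = "1.5T",
    clinical: ClinicalRecord | None = None,
    geometry_tolerance: float = 1e-4,
) -> StudyCase:
    """Load a case from NIfTI-1 files, validating a shared grid.

    The mask is binarized at > 0.5 (tolerant of interpolated masks).
    Raises :class:`GeometryError` on shape/spacing mismatch,
    :class:`NonFiniteDataError` on NaN/inf voxels, and
    :class:`EmptyMaskError` when the mask has no foreground (such cases
    are excluded from analysis, mirroring undetected tumors).
    """
    channels: dict[str, ImageVolume] = {}
    ref_shape = None
    ref_spacing = None
    for tag, path in channel_paths.items():
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        if ref_shape is None:
            ref_shape, ref_spacing = data.shape, spacing
        else:
            if data.shape != ref_shape:
                raise GeometryError(f"{case_id}: channel {tag} shape {data.shape} != {ref_shape}")
            if max(abs(a - b) for a, b in zip(spacing, ref_spacing)) > geometry_tolerance:
                raise GeometryError(f"{case_id}: channel {tag} spacing {spacing} != {ref_spacing}")
        channels[tag] = ImageVolume(data, spacing, channel=tag, field_strength=field_strength)

    mimg = nib.load(str(mask_path))
    mdata = np.asarray(mimg.dataobj, dtype=float)
    mspacing = tuple(float(z) for z in mimg.header.get_zooms()[:3])
    if mdata.shape != ref_shape:
        raise GeometryError(f"{case_id}: mask shape {mdata.shape} != {ref_shape}")
    if max(abs(a - b) for a, b in zip(mspacing, ref_spacing)) > geometry_tolerance:
        raise GeometryError(f"{case_id}: mask spacing {mspacing} != {ref_spacing}")
    mask = TumorMask(mdata > 0.5, mspacing)
    if mask.n_voxels == 0:
        raise EmptyMaskError(f"{case_id}: empty tumor mask")
    return StudyCase(case_id, channels, mask, clinical=clinical)


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

def dilate_mask(mask: TumorMask) -> TumorMask:
    """One binary dilation with the 6-connected 3x3x3 cross element."""
    return TumorMask(ndimage.binary_dilation(mask.voxels, structure=STRUCT_6), mask.spacing)


def erode_mask(mask: TumorMask) -> TumorMask:
    """One binary erosion with the 6-connected cross element.

    May return an empty mask; callers must check :attr:`TumorMask.n_voxels`
    and exclude (not silently drop) emptied cases.
    """
    return TumorMask(ndimage.binary_erosion(mask.voxels, structure=STRUCT_6), mask.spacing)


def connected_components(binary: np.ndarray, connectivity: int = 6):
    """Label connected components of a 3D binary array.

    connectivity 6 counts face neighbours only; 26 also counts edge and
    corner neighbours.  Returns ``(labels, sizes)`` with sizes in voxels,
    ordered by label id.
    """
    if connectivity == 6:
        struct = ndimage.generate_binary_structure(3, 1)
    elif connectivity == 26:
        struct = ndimage.generate_binary_structure(3, 3)
    else:
        raise ValueError("connectivity must be 6 or 26")
    binary = np.asarray(binary).astype(bool)
    labels, n = ndimage.label(binary, structure=struct)
    sizes = np.bincount(labels.ravel())[1:] if n else np.array([], dtype=int)
    return labels, sizes.astype(int)
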