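"""Dose-volume handling: loading, resampling, BED conversion and discretization.

The texture analysis downstream operates on a 3D planned dose distribution
restricted to the rectum contour. This module brings heterogeneous inputs
(DICOM RTDOSE + RTSTRUCT, NRRD, NIfTI) onto a common isotropic grid, converts
physical dose (PhyD) to biological effective dose (BED) voxel by voxel with
the linear-quadratic model, and discretizes masked doses into 1-based integer
gray levels for the texture matrices.

Conventions
-----------
* Arrays are indexed ``(axis0, axis1, axis2)``; ``spacing`` and ``origin`` are
  stored in the same axis order, in millimetres.
* Doses are in Gy and non-negative.
* Gray levels are 1-based; a voxel with dose ``D`` falls into level
  ``floor(D / bin_width) + 1`` with half-open bins and a closed top bin.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import SimpleITK as sitk


class DoseVolumeError(ValueError):
    """Invalid dose/mask geometry or content."""


class EmptyStructureError(DoseVolumeError):
    """A structure mask contains no voxels."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FractionationScheme:
    """A prescription: total dose delivered in a fixed number of fractions.

    ``scheme_code`` is the binary covariate used when hypo- and conventionally
    fractionated patients are modelled together (1 = HF, 0 = CF).
    """

    name: str
    total_dose: float
    n_fractions: int
    scheme_code: int

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.total_dose <= 0:
            raise ValueError("total_dose must be positive")
        if self.name == "HF" and self.scheme_code != 1:
            raise ValueError("HF scheme_code must be 1")
        if self.name == "CF" and self.scheme_code != 0:
            raise ValueError("CF scheme_code must be 0")

    @property
    def fraction_size(self) -> float:
        """Prescribed dose per fraction (Gy)."""
        return self.total_dose / self.n_fractions


#: Hypofractionation: 64.6 Gy in 19 fractions (3.4 Gy/fraction).
HF = FractionationScheme("HF", 64.6, 19, 1)
#: Conventional fractionation: 78 Gy in 39 fractions (2 Gy/fraction).
CF = FractionationScheme("CF", 78.0, 39, 0)

SCHEMES = {"HF": HF, "CF": CF}


@dataclass(frozen=True)
class DoseRepresentation:
    """How voxel doses are expressed: physical dose or BED at a given α/β."""

    kind: str  # "phyd" | "bed"
    alpha_beta: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("phyd", "bed"):
            raise ValueError(f"unknown representation kind {self.kind!r}")
        if self.kind == "bed" and (self.alpha_beta is None or self.alpha_beta <= 0):
            raise ValueError("BED representation requires alpha_beta > 0")

    @property
    def label(self) -> str:
        if self.kind == "phyd":
            return "phyd"
        return f"bed{self.alpha_beta:g}"


REPRESENTATIONS = {
    "phyd": DoseRepresentation("phyd"),
    "bed2": DoseRepresentation("bed", 2.0),
    "bed3": DoseRepresentation("bed", 3.0),
}


@dataclass
class DoseGrid:
    """A 3D scalar absorbed-dose field with physical geometry metadata."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.size == 0:
            raise DoseVolumeError("dose array must be non-empty and 3D")
        if np.any(self.values < 0):
            raise DoseVolumeError("negative dose values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise DoseVolumeError("spacing must be strictly positive on 3 axes")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class StructureMask:
    """A binary mask congruent with a :class:`DoseGrid`."""

    values: np.ndarray
    label: str = "rectum"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise DoseVolumeError("mask array must be 3D")
        if not self.values.any():
            raise EmptyStructureError(f"empty structure {self.label!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class DiscretizedVolume:
    """Integer gray-level volume defined on masked voxels.

    ``levels`` holds 1-based gray levels wherever the mask is set (0 outside).
    """

    levels: np.ndarray
    n_levels: int
    bin_width: float
    mask: StructureMask

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int32)
        if self.n_levels < 1:
            raise DoseVolumeError("n_levels must be >= 1")
        inside = self.levels[self.mask.values]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise DoseVolumeError("masked levels out of [1, n_levels]")

    @property
    def masked_levels(self) -> np.ndarray:
        return self.levels[self.mask.values]


# ---------------------------------------------------------------------------
# SimpleITK bridging
# ---------------------------------------------------------------------------


def _to_sitk(values: np.ndarray, spacing: Sequence[float], origin: Sequence[float]) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(values))
    # SimpleITK uses (x, y, z) order; our arrays are (axis0, axis1, axis2).
    img.SetSpacing(tuple(spacing)[::-1])
    img.SetOrigin(tuple(origin)[::-1])
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    values = sitk.GetArrayFromImage(img)
    spacing = tuple(img.GetSpacing())[::-1]
    origin = tuple(img.GetOrigin())[::-1]
    return values, spacing, origin


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_VOLUME_SUFFIXES = (".nrrd", ".nii", ".nii.gz", ".mha", ".mhd")


def write_volume(path: str | os.PathLike, grid: DoseGrid | StructureMask) -> None:
    """Write a dose grid or mask to NRRD/NIfTI (format from file suffix)."""
    if isinstance(grid, StructureMask):
        img = _to_sitk(grid.values.astype(np.uint8), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
    else:
        img = _to_sitk(grid.values, grid.spacing, grid.origin)
    sitk.WriteImage(img, str(path))


def write_mask(path: str | os.PathLike, mask: StructureMask, like: DoseGrid) -> None:
    """Write a mask on the geometry of ``like``."""
    img = _to_sitk(mask.values.astype(np.uint8), like.spacing, like.origin)
    sitk.WriteImage(img, str(path))


def read_volume(
    dose_path: str | os.PathLike,
    mask_path: str | os.PathLike | None = None,
    *,
    structure: str = "rectum",
    resample_mask: bool = True,
) -> tuple[DoseGrid, StructureMask]:
    """Read a dose distribution and its structure mask onto a common grid.

    Parameters
    ----------
    dose_path
        NRRD/NIfTI dose volume, or a DICOM RTDOSE file.
    mask_path
        NRRD/NIfTI binary mask, or a DICOM RTSTRUCT file when ``dose_path``
        is an RTDOSE.
    structure
        Structure (ROI) name for RTSTRUCT inputs, matched case-insensitively.
    resample_mask
        When the mask sits on a different physical frame than the dose,
        resample it onto the dose grid (nearest neighbour); otherwise raise.
    """
    dose_path = Path(dose_path)
    if mask_path is None:
        raise DoseVolumeError("a mask source is required")
    mask_path = Path(mask_path)

    if dose_path.name.lower().endswith(_VOLUME_SUFFIXES):
        dimg = sitk.ReadImage(str(dose_path))
        mimg = sitk.ReadImage(str(mask_path))
        if (
            dimg.GetSize() != mimg.GetSize()
            or not np.allclose(dimg.GetSpacing(), mimg.GetSpacing())
            or not np.allclose(dimg.GetOrigin(), mimg.GetOrigin())
        ):
            if not resample_mask:
                raise DoseVolumeError(
                    "mask and dose are on different physical frames"
                )
            mimg = sitk.Resample(mimg, dimg, sitk.Transform(), sitk.sitkNearestNeighbor, 0)
        values, spacing, origin = _from_sitk(dimg)
        mvalues = sitk.GetArrayFromImage(mimg) > 0
        dose = DoseGrid(values, spacing, origin)
        mask = StructureMask(mvalues, label=structure)
        return dose, mask

    # DICOM route: RTDOSE + RTSTRUCT
    return _read_dicom_rt(dose_path, mask_path, structure=structure)


def _read_dicom_rt(
    rtdose_path: Path, rtstruct_path: Path, *, structure: str
) -> tuple[DoseGrid, StructureMask]:
    import pydicom

    ds = pydicom.dcmread(str(rtdose_path))
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    values = ds.pixel_array.astype(np.float64) * scaling  # (frame, row, col)
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    if len(offsets) > 1:
        dz = float(np.diff(offsets).mean())
    else:
        dz = float(getattr(ds, "SliceThickness", 1.0) or 1.0)
    ipp = [float(v) for v in ds.ImagePositionPatient]  # (x, y, z)
    spacing = (abs(dz), row_sp, col_sp)
    origin = (ipp[2] + offsets[0], ipp[1], ipp[0])  # array order (z, y, x)
    dose = DoseGrid(values, spacing, origin)

    rs = pydicom.dcmread(str(rtstruct_path))
    roi_number = None
    for roi in rs.StructureSetROISequence:
        if structure.lower() in str(roi.ROIName).lower():
            roi_number = roi.ROINumber
            break
    if roi_number is None:
        raise DoseVolumeError(f"missing structure label {structure!r} in RTSTRUCT")
    contours = None
    for rc in rs.ROIContourSequence:
        if rc.ReferencedROINumber == roi_number:
            contours = getattr(rc, "ContourSequence", [])
            break
    mask_values = _rasterize_contours(contours or [], dose)
    mask = StructureMask(mask_values, label=structure)
    return dose, mask


def _rasterize_contours(contours: Iterable, dose: DoseGrid) -> np.ndarray:
    """Rasterize closed planar contours (patient mm) onto the dose grid.

    Multiple contours on one slice combine by even-odd rule (XOR), which
    handles rings/holes the way planning systems export them.
    """
    nz, ny, nx = dose.shape
    oz, oy, ox = dose.origin
    sz, sy, sx = dose.spacing
    ys = oy + sy * np.arange(ny)
    xs = ox + sx * np.arange(nx)
    gx, gy = np.meshgrid(xs, ys)  # (ny, nx)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    mask = np.zeros(dose.shape, dtype=bool)
    for c in contours:
        data = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
        z = data[:, 2].mean()
        k = int(round((z - oz) / sz))
        if not 0 <= k < nz:
            continue
        inside = _points_in_polygon(pts, data[:, :2]).reshape(ny, nx)
        mask[k] ^= inside
    return mask


def _points_in_polygon(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd-rule point-in-polygon test, vectorized over points."""
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < xint)
    return inside


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def resample_to_isotropic(
    dose: DoseGrid,
    mask: StructureMask,
    target_spacing: float = 1.0,
) -> tuple[DoseGrid, StructureMask]:
    """Resample dose (cubic B-spline) and mask (linear + 0.5 threshold) to an
    isotropic grid.

    Cubic interpolation can overshoot below zero near steep gradients; such
    values are clipped to 0 Gy since absorbed dose cannot be negative.
    """
    if target_spacing <= 0:
        raise DoseVolumeError("target_spacing must be positive")
    t = float(target_spacing)
    # keep all new voxel centers inside the original center extent so no
    # out-of-support extrapolation (zero fill) enters the field
    new_size_arr = [
        max(1, int(np.floor((n - 1) * s / t + 1e-9)) + 1)
        for n, s in zip(dose.shape, dose.spacing)
    ]

    dimg = _to_sitk(dose.values, dose.spacing, dose.origin)
    mimg = _to_sitk(mask.values.astype(np.float32), dose.spacing, dose.origin)

    ref = sitk.Image(new_size_arr[::-1], sitk.sitkFloat64)
    ref.SetSpacing((t, t, t))
    ref.SetOrigin(dose.origin[::-1])

    dres = sitk.Resample(dimg, ref, sitk.Transform(), sitk.sitkBSpline, 0.0)
    mres = sitk.Resample(mimg, ref, sitk.Transform(), sitk.sitkLinear, 0.0)

    values, spacing, origin = _from_sitk(dres)
    values = np.clip(values, 0.0, None)
    mvalues = sitk.GetArrayFromImage(mres) >= 0.5
    if not mvalues.any():
        raise EmptyStructureError(
            "resampling emptied the structure mask (degenerate geometry)"
        )
    return DoseGrid(values, spacing, origin), StructureMask(mvalues, label=mask.label)


# ---------------------------------------------------------------------------
# BED and discretization
# ---------------------------------------------------------------------------


def bed_transform(
    dose: DoseGrid, scheme: FractionationScheme, alpha_beta: float
) -> DoseGrid:
    """Convert physical dose to biological effective dose voxel by voxel.

    Each voxel's total dose ``D`` is delivered over the scheme's ``n``
    fractions, so its per-fraction dose is ``d = D / n`` and

        BED = D * (1 + d / (α/β))

    BED is monotone in D and never smaller than D.
    """
    if alpha_beta <= 0:
        raise ValueError("alpha_beta must be positive")
    d = dose.values / scheme.n_fractions
    bed = dose.values * (1.0 + d / alpha_beta)
    return replace(dose, values=bed)


def apply_representation(
    dose: DoseGrid, scheme: FractionationScheme, representation: DoseRepresentation | str
) -> DoseGrid:
    """Express ``dose`` in the requested representation (PhyD is identity)."""
    if isinstance(representation, str):
        representation = REPRESENTATIONS[representation]
    if representation.kind == "phyd":
        return dose
    return bed_transform(dose, scheme, representation.alpha_beta)


def discretize(
    dose: DoseGrid,
    mask: StructureMask,
    bin_width: float = 1.0,
    range_max: float | None = None,
) -> DiscretizedVolume:
    """Discretize masked voxel doses into 1-based gray levels.

    Bins are half-open ``[(k-1)·w, k·w)``; the top bin is closed so a voxel at
    exactly ``range_max`` falls into level ``n_levels``. Zero dose maps to
    level 1. With 1-Gy bins the number of levels equals the dose range in Gy.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if dose.values.shape != mask.values.shape:
        raise DoseVolumeError("dose and mask shapes differ")
    masked = dose.values[mask.values]
    dmax = float(masked.max())
    if range_max is None:
        range_max = compute_range_max([(dose, mask)], bin_width=bin_width)
    if dmax > range_max * (1 + 1e-12):
        raise DoseVolumeError(
            f"masked voxel dose {dmax:.3f} Gy exceeds range_max {range_max:.3f} Gy"
        )
    n_levels = max(1, int(np.ceil(range_max / bin_width - 1e-12)))
    levels = np.zeros(dose.values.shape, dtype=np.int32)
    lv = np.floor(dose.values[mask.values] / bin_width).astype(np.int32) + 1
    np.clip(lv, 1, n_levels, out=lv)
    levels[mask.values] = lv
    return DiscretizedVolume(levels, n_levels, float(bin_width), mask)


def compute_range_max(
    cohort: Sequence[tuple[DoseGrid, StructureMask]],
    bin_width: float = 1.0,
) -> float:
    """Global maximum masked voxel dose over a cohort, rounded up to the next
    bin edge.

    Sharing one range across all patients of a set keeps the gray-level axes
    of their texture matrices comparable.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    gmax = max(float(d.values[m.values].max()) for d, m in cohort)
    edge = np.ceil(gmax / bin_width - 1e-12) * bin_width
    return float(max(edge, bin_width))
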