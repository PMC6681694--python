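"""Shared data model and NIfTI / JSON / CSV input-output.

Conventions
-----------
* Volumes and masks are 3D arrays; by package convention the index order is
  (z, y, x), i.e. axis 0 is the axial (slice) direction.  ``spacing`` is the
  voxel edge length in mm along each *array axis* in the same order.  All
  operations are either voxelwise or use Euclidean voxel offsets, so only the
  pairing of axis and spacing matters; no world-space affine math is done
  beyond spacing (single-station axial volumes need no reorientation).
* Times are minutes post-injection as floats; 0 = injection.
* NIfTI (.nii / .nii.gz) is the sole volumetric format; subject metadata is
  JSON; tabular outputs are CSV.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import GridMismatchError

__all__ = [
    "ValueKind",
    "VolumeImage",
    "RoiMask",
    "SubjectRecord",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_results_table",
    "read_results_table",
    "check_grids_match",
]


class ValueKind(str, enum.Enum):
    """What the scalar voxel values of a volume mean."""

    ACTIVITY = "activity_Bq_per_mL"
    SUV = "SUV_g_per_mL"
    SUL = "SUL_g_per_mL"
    ADC = "ADC_1e-3_mm2_per_s"


def _as_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(sp)}")
    if any(not np.isfinite(s) or s <= 0 for s in sp):
        raise ValueError(f"spacing components must be strictly positive, got {sp}")
    return sp  # type: ignore[return-value]


@dataclass
class VolumeImage:
    """A 3D scalar grid with anisotropic voxel spacing and a declared value kind.

    Parameters
    ----------
    values
        3D float array, finite everywhere.
    spacing
        Voxel edge lengths (mm) along each array axis.
    value_kind
        One of :class:`ValueKind` (activity, SUV, SUL or ADC).
    frame_window
        Optional (start, end) of the reconstruction frame in minutes
        post-injection.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    value_kind: ValueKind
    frame_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.values.ndim}D")
        self.spacing = _as_spacing(self.spacing)
        self.value_kind = ValueKind(self.value_kind)
        n_bad = int(np.size(self.values) - np.isfinite(self.values).sum())
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxel(s)")
        if self.frame_window is not None:
            t0, t1 = (float(t) for t in self.frame_window)
            if t1 <= t0:
                raise ValueError(f"frame_window end must exceed start, got {(t0, t1)}")
            self.frame_window = (t0, t1)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mL(self) -> float:
        """Voxel volume in mL (= mm^3 / 1000)."""
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def with_values(self, values: np.ndarray, value_kind: ValueKind) -> "VolumeImage":
        """New volume on the same grid with replaced values and kind."""
        return VolumeImage(values, self.spacing, value_kind, self.frame_window)


@dataclass
class RoiMask:
    """Binary 3D region-of-interest mask sharing a :class:`VolumeImage` grid."""

    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.mask.ndim}D")
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_mL(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0


@dataclass
class SubjectRecord:
    """Demographics, dose and per-session timing for one imaging session.

    ``sex`` must be ``"male"`` or ``"female"`` (the James lean-body-mass
    formula is sex-specific).  ``injection_time_min`` is the time origin and
    is 0 by convention.  ``acquisition_start_min`` / ``acquisition_duration_min``
    describe the list-mode window of this session (minutes post-injection)
    and feed uptake-time matching; they may be omitted for metric-level data.
    """

    subject_id: str
    sex: str
    weight_kg: float
    height_cm: float
    injected_dose_MBq: float
    session: int
    modality: str
    injection_time_min: float = 0.0
    acquisition_start_min: float | None = None
    acquisition_duration_min: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("weight_kg", "height_cm", "injected_dose_MBq"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
            setattr(self, name, v)
        if int(self.session) not in (1, 2):
            raise ValueError(f"session must be 1 or 2, got {self.session}")
        self.session = int(self.session)
        if self.modality not in ("PETCT", "PETMR"):
            raise ValueError(f"modality must be 'PETCT' or 'PETMR', got {self.modality!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SubjectRecord":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# grid compatibility


def check_grids_match(
    shape_a: tuple[int, ...],
    spacing_a: Sequence[float],
    shape_b: tuple[int, ...],
    spacing_b: Sequence[float],
    spacing_rtol: float = 1e-3,
) -> None:
    """Raise :class:`GridMismatchError` unless the two grids agree.

    Downstream operations reject mismatched grids rather than silently
    resampling; registration/resampling is out of scope.
    """
    if tuple(shape_a) != tuple(shape_b):
        raise GridMismatchError(f"grid shapes differ: {tuple(shape_a)} vs {tuple(shape_b)}")
    sa, sb = np.asarray(spacing_a, float), np.asarray(spacing_b, float)
    if not np.allclose(sa, sb, rtol=spacing_rtol, atol=0.0):
        raise GridMismatchError(f"voxel spacings differ: {tuple(sa)} vs {tuple(sb)}")


# ---------------------------------------------------------------------------
# NIfTI I/O


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D with shape {data.shape}: {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data, dtype=float), _as_spacing(spacing)


def read_volume(path: str | Path, value_kind: ValueKind | str) -> VolumeImage:
    """Read a 3D NIfTI volume, taking voxel spacing from the header.

    Raises on missing files, non-3D images, non-positive spacing and
    non-finite voxels (reported with their count).
    """
    data, spacing = _load_nifti(path)
    return VolumeImage(data, spacing, ValueKind(value_kind))


def write_volume(volume: VolumeImage, path: str | Path) -> None:
    """Write a volume as NIfTI with a diagonal spacing affine."""
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.values.astype(np.float64), affine), str(path))


def read_mask(
    path: str | Path, reference: VolumeImage, spacing_rtol: float = 1e-3
) -> RoiMask:
    """Read an ROI mask NIfTI and check it against a reference grid.

    Nonzero voxels become True.  An empty mask is a warning at load time
    (metric extraction raises).
    """
    data, spacing = _load_nifti(path)
    check_grids_match(data.shape, spacing, reference.shape, reference.spacing, spacing_rtol)
    mask = RoiMask(data != 0, reference.spacing)
    if mask.n_voxels == 0:
        warnings.warn(f"mask {path} is empty (0 voxels set)", stacklevel=2)
    return mask


def write_mask(mask: RoiMask, path: str | Path) -> None:
    affine = np.diag(list(mask.spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine), str(path))


# ---------------------------------------------------------------------------
# result tables


def write_results_table(
    rows: Sequence[dict] | pd.DataFrame,
    path: str | Path,
    fieldnames: Sequence[str] | None = None,
) -> None:
    """Write records as a CSV with header; an empty row list yields a
    header-only file (``fieldnames`` supplies the schema in that case)."""
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows), columns=fieldnames)
    df.to_csv(path, index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
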