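"""Tumor-ROI metric extraction: extrema, sphere peak/trough, isocontour, volumes.

The *peak* of a lesion is the highest mean value achievable by a 1-cm^3
sphere positioned with its center inside the lesion contour (PERCIST-style
SUL_peak); the *trough* is the mirror-image minimum-mean sphere, used for
ADC maps where tumors are dark.  The sphere is discretized on the voxel
grid: candidate centers are voxel centers inside the mask, kernel membership
is by voxel-center inclusion within the sphere radius, and the sphere may
extend beyond the lesion contour but not beyond the image.

The percent isocontour (default 40%) keeps all in-mask voxels with value at
least ``fraction`` x the in-mask maximum (inclusive threshold, no
connected-component filtering by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import EmptyMaskError, GridMismatchError, ValueKindError
from .formats_io import RoiMask, ValueKind, VolumeImage, check_grids_match

__all__ = [
    "SphereKernel",
    "PeakResult",
    "MetricSet",
    "VALID_METRICS",
    "metric_extremum",
    "metric_mean_median",
    "metric_peak_sphere",
    "percent_isocontour",
    "roi_volume",
    "total_lesion_glycolysis",
    "extract_metric_set",
]


@dataclass(frozen=True)
class SphereKernel:
    """Discrete spherical neighborhood of a target volume on a voxel grid.

    ``offsets`` are integer voxel offsets whose centers lie within the sphere
    radius of the kernel center; ``realized_volume_mL`` (offset count x voxel
    volume) approximates ``target_volume_mL`` with a spacing-dependent error
    that this class reports rather than hides.
    """

    spacing: tuple[float, float, float]
    target_volume_mL: float = 1.0
    radius_mm: float = field(init=False)
    offsets: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.target_volume_mL <= 0:
            raise ValueError("target_volume_mL must be positive")
        sp = np.asarray(self.spacing, float)
        if sp.shape != (3,) or np.any(sp <= 0):
            raise ValueError(f"invalid spacing {self.spacing}")
        # target volume in mm^3; radius of the equivalent sphere
        r = (3.0 * self.target_volume_mL * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        object.__setattr__(self, "radius_mm", float(r))
        half = np.floor(r / sp).astype(int)
        grids = np.meshgrid(*(np.arange(-h, h + 1) for h in half), indexing="ij")
        offs = np.stack([g.ravel() for g in grids], axis=1)
        d2 = ((offs * sp) ** 2).sum(axis=1)
        offs = offs[d2 <= r * r + 1e-9]
        if offs.shape[0] == 0:  # voxels coarser than the sphere: keep the center
            offs = np.zeros((1, 3), dtype=int)
        object.__setattr__(self, "offsets", offs)

    @property
    def n_voxels(self) -> int:
        return int(self.offsets.shape[0])

    @property
    def realized_volume_mL(self) -> float:
        dx, dy, dz = self.spacing
        return self.n_voxels * dx * dy * dz / 1000.0


@dataclass(frozen=True)
class PeakResult:
    """Extremal sphere mean with the winning center and a clipped-kernel flag."""

    value: float
    center: tuple[int, int, int]
    clipped: bool


def _require_compatible(volume: VolumeImage, mask: RoiMask) -> None:
    check_grids_match(volume.shape, volume.spacing, mask.shape, mask.spacing)
    if mask.n_voxels == 0:
        raise EmptyMaskError("metric extraction requires a nonempty mask")


def metric_extremum(volume: VolumeImage, mask: RoiMask, mode: str = "max") -> float:
    """Max (or min) voxel value inside the mask (SUV_max, ADC_min, ...)."""
    _require_compatible(volume, mask)
    vals = volume.values[mask.mask]
    if mode == "max":
        return float(vals.max())
    if mode == "min":
        return float(vals.min())
    raise ValueError(f"mode must be 'max' or 'min', got {mode!r}")


def metric_mean_median(volume: VolumeImage, mask: RoiMask) -> tuple[float, float]:
    """Arithmetic mean and median of in-mask voxels.

    Median uses the midpoint-of-central-order-statistics convention for even
    counts (numpy's default).
    """
    _require_compatible(volume, mask)
    vals = volume.values[mask.mask]
    return float(vals.mean()), float(np.median(vals))


def metric_peak_sphere(
    volume: VolumeImage,
    mask: RoiMask,
    kernel: SphereKernel | None = None,
    mode: str = "max",
    _chunk: int = 4096,
) -> PeakResult:
    """Extremal sphere-mean over all candidate centers inside the mask.

    Candidate centers are in-mask voxel centers whose full kernel lies inside
    the image (the sphere may leave the mask, never the image).  If no center
    admits the full kernel, the kernel is clipped to in-bounds voxels per
    center and the result is flagged ``clipped=True``.
    """
    _require_compatible(volume, mask)
    if mode not in ("max", "min"):
        raise ValueError(f"mode must be 'max' or 'min', got {mode!r}")
    if kernel is None:
        kernel = SphereKernel(volume.spacing)
    centers = np.argwhere(mask.mask)
    shape = np.asarray(volume.shape)
    offs = kernel.offsets

    full_ok = np.all(centers + offs.min(axis=0) >= 0, axis=1) & np.all(
        centers + offs.max(axis=0) <= shape - 1, axis=1
    )
    clipped = not bool(full_ok.any())
    cand = centers if clipped else centers[full_ok]

    best_val = -np.inf
    best_center = tuple(int(c) for c in cand[0])
    sign = 1.0 if mode == "max" else -1.0
    vals = volume.values
    for i in range(0, len(cand), _chunk):
        block = cand[i : i + _chunk]  # (B, 3)
        pos = block[:, None, :] + offs[None, :, :]  # (B, K, 3)
        if clipped:
            inb = np.all((pos >= 0) & (pos < shape), axis=2)
            pos_c = np.clip(pos, 0, shape - 1)
            v = vals[pos_c[..., 0], pos_c[..., 1], pos_c[..., 2]]
            means = np.where(inb, v, 0.0).sum(axis=1) / inb.sum(axis=1)
        else:
            means = vals[pos[..., 0], pos[..., 1], pos[..., 2]].mean(axis=1)
        scored = sign * means
        j = int(np.argmax(scored))
        if scored[j] > best_val:
            best_val = float(scored[j])
            best_center = tuple(int(c) for c in block[j])
    return PeakResult(sign * best_val, best_center, clipped)


def percent_isocontour(
    volume: VolumeImage, mask: RoiMask, fraction: float = 0.40
) -> RoiMask:
    """In-mask voxels with value >= fraction x in-mask maximum (inclusive).

    Always contains the argmax voxel; undefined (error) when the in-mask
    maximum is not positive.
    """
    _require_compatible(volume, mask)
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    vmax = float(volume.values[mask.mask].max())
    if vmax <= 0:
        raise ValueError(f"isocontour undefined: in-mask maximum {vmax:g} <= 0")
    return RoiMask(mask.mask & (volume.values >= fraction * vmax), mask.spacing)


def roi_volume(mask: RoiMask, spacing: Sequence[float] | None = None) -> float:
    """Mask volume in mL (voxel count x voxel volume); empty mask -> 0."""
    sp = np.asarray(spacing if spacing is not None else mask.spacing, float)
    return float(mask.n_voxels * np.prod(sp) / 1000.0)


def total_lesion_glycolysis(volume: VolumeImage, mask: RoiMask) -> float:
    """TLG (g) = mean in-mask SUV (or SUL) x ROI volume (mL)."""
    _require_compatible(volume, mask)
    if volume.value_kind not in (ValueKind.SUV, ValueKind.SUL):
        raise ValueKindError(
            f"total lesion glycolysis requires SUV or SUL, got {volume.value_kind.value}"
        )
    return float(volume.values[mask.mask].sum() * volume.voxel_volume_mL)


# ---------------------------------------------------------------------------
# metric sets

#: Metric names valid per value kind.
VALID_METRICS: dict[ValueKind, tuple[str, ...]] = {
    ValueKind.SUV: (
        "suv_max",
        "suv_mean",
        "suv_median",
        "suv_peak",
        "metabolic_tumor_volume_mL",
        "total_lesion_glycolysis_g",
    ),
    ValueKind.SUL: (
        "sul_peak",
        "metabolic_tumor_volume_mL",
        "total_lesion_glycolysis_g",
    ),
    ValueKind.ADC: (
        "adc_max",
        "adc_min",
        "adc_mean",
        "adc_median",
        "adc_trough",
        "diffusional_tumor_volume_mL",
    ),
}


@dataclass
class MetricSet:
    """Named scalar metrics extracted from one volume + mask.

    Only requested metrics are populated (in ``values``); ``meta`` carries
    sphere-search metadata (winning center, clipped flag, realized kernel
    volume).
    """

    value_kind: ValueKind
    values: dict[str, float] = field(default_factory=dict)
    meta: dict[str, object] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_row(self) -> dict[str, float]:
        return dict(self.values)


def extract_metric_set(
    volume: VolumeImage,
    mask: RoiMask,
    metrics: Iterable[str],
    kernel: SphereKernel | None = None,
) -> MetricSet:
    """Compute the requested metrics, validating metric/value-kind pairing."""
    _require_compatible(volume, mask)
    requested = list(metrics)
    if volume.value_kind not in VALID_METRICS:
        raise ValueKindError(
            f"no named metrics for value kind {volume.value_kind.value}; "
            "convert activity volumes to SUV/SUL first"
        )
    allowed = VALID_METRICS[volume.value_kind]
    bad = [m for m in requested if m not in allowed]
    if bad:
        raise ValueKindError(
            f"metrics {bad} invalid for value kind {volume.value_kind.value}; "
            f"allowed: {list(allowed)}"
        )
    if kernel is None and any(m in ("suv_peak", "sul_peak", "adc_trough") for m in requested):
        kernel = SphereKernel(volume.spacing)

    out = MetricSet(volume.value_kind)
    mean, median = metric_mean_median(volume, mask)
    for m in requested:
        if m in ("suv_max", "adc_max"):
            out.values[m] = metric_extremum(volume, mask, "max")
        elif m == "adc_min":
            out.values[m] = metric_extremum(volume, mask, "min")
        elif m in ("suv_mean", "adc_mean"):
            out.values[m] = mean
        elif m in ("suv_median", "adc_median"):
            out.values[m] = median
        elif m in ("suv_peak", "sul_peak"):
            pk = metric_peak_sphere(volume, mask, kernel, "max")
            out.values[m] = pk.value
            out.meta[f"{m}_center"] = pk.center
            out.meta[f"{m}_clipped"] = pk.clipped
        elif m == "adc_trough":
            tr = metric_peak_sphere(volume, mask, kernel, "min")
            out.values[m] = tr.value
            out.meta["adc_trough_center"] = tr.center
            out.meta["adc_trough_clipped"] = tr.clipped
        elif m in ("metabolic_tumor_volume_mL", "diffusional_tumor_volume_mL"):
            out.values[m] = roi_volume(mask)
        elif m == "total_lesion_glycolysis_g":
            out.values[m] = total_lesion_glycolysis(volume, mask)
        else:  # pragma: no cover - guarded by the allowed-list check
            raise ValueError(f"unknown metric {m!r}")
    if kernel is not None:
        out.meta["kernel_realized_volume_mL"] = kernel.realized_volume_mL
    return out
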