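"""SUV / SUL conversion: decay correction and the James lean-body-mass formula.

SUV (standardized uptake value) normalizes tissue activity concentration by
injected dose per body weight:

    SUV [g/mL] = C [Bq/mL] / (D(t) [Bq] / W [g])

with D(t) the injected dose decay-corrected to the reference time of the
reconstructed frame.  SUL replaces total body weight W by the lean body mass
(LBM), computed here with the James (1976) formula:

    male:   LBM = 1.10 W - 128 (W/H)^2
    female: LBM = 1.07 W - 148 (W/H)^2      (W in kg, H in cm)

The decay reference time defaults to the start of the selected reconstruction
frame (the common console convention); the choice only rescales all SUVs of a
session by a common factor and cancels in paired relative differences.
"""

from __future__ import annotations

import math

import numpy as np

from .exceptions import OutOfDomainError, ValueKindError
from .formats_io import SubjectRecord, ValueKind, VolumeImage

__all__ = [
    "F18_HALF_LIFE_MIN",
    "decay_correct_dose",
    "lean_body_mass_james",
    "activity_to_suv",
    "suv_to_sul",
]

#: Physical half-life of 18F in minutes.
F18_HALF_LIFE_MIN = 109.771

_JAMES_COEFFS = {"male": (1.10, 128.0), "female": (1.07, 148.0)}


def decay_correct_dose(
    dose_MBq: float,
    injection_time_min: float,
    reference_time_min: float,
    half_life_min: float = F18_HALF_LIFE_MIN,
) -> float:
    """Residual activity (MBq) at ``reference_time_min``.

    Returns ``dose * 2**(-dt / half_life)`` with ``dt = reference - injection``.
    """
    if half_life_min <= 0:
        raise ValueError(f"half_life_min must be positive, got {half_life_min}")
    dt = float(reference_time_min) - float(injection_time_min)
    if dt < 0:
        raise ValueError(
            f"reference time precedes injection time (elapsed = {dt:g} min)"
        )
    return float(dose_MBq) * 2.0 ** (-dt / half_life_min)


def lean_body_mass_james(weight_kg: float, height_cm: float, sex: str) -> float:
    """Lean body mass (kg) by the James formula.

    For physiologic inputs LBM <= weight; the quadratic term dominates at
    extreme weight-for-height and drives the formula negative, which is
    reported as out-of-domain rather than clamped.
    """
    if sex not in _JAMES_COEFFS:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    w, h = float(weight_kg), float(height_cm)
    if w <= 0 or h <= 0:
        raise ValueError(f"weight and height must be positive, got {w} kg, {h} cm")
    a, b = _JAMES_COEFFS[sex]
    lbm = a * w - b * (w / h) ** 2
    if lbm <= 0:
        raise OutOfDomainError(
            f"James LBM non-positive ({lbm:.2f} kg) for weight={w} kg, height={h} cm"
        )
    return lbm


def activity_to_suv(
    volume: VolumeImage,
    subject: SubjectRecord,
    reference_time_min: float,
    half_life_min: float = F18_HALF_LIFE_MIN,
) -> VolumeImage:
    """Convert an activity-concentration volume (Bq/mL) to SUV (g/mL).

    ``reference_time_min`` is the decay reference, conventionally the start
    of the reconstruction frame.
    """
    if volume.value_kind is not ValueKind.ACTIVITY:
        raise ValueKindError(
            f"activity_to_suv requires {ValueKind.ACTIVITY.value}, got {volume.value_kind.value}"
        )
    dose_Bq = (
        decay_correct_dose(
            subject.injected_dose_MBq,
            subject.injection_time_min,
            reference_time_min,
            half_life_min,
        )
        * 1e6
    )
    weight_g = subject.weight_kg * 1000.0
    suv = volume.values * (weight_g / dose_Bq)
    return volume.with_values(suv, ValueKind.SUV)


def suv_to_sul(volume: VolumeImage, subject: SubjectRecord) -> VolumeImage:
    """Rescale an SUV volume to SUL (lean-body-mass-normalized), voxelwise."""
    if volume.value_kind is not ValueKind.SUV:
        raise ValueKindError(
            f"suv_to_sul requires {ValueKind.SUV.value}, got {volume.value_kind.value}"
        )
    lbm = lean_body_mass_james(subject.weight_kg, subject.height_cm, subject.sex)
    return volume.with_values(volume.values * (lbm / subject.weight_kg), ValueKind.SUL)
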