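"""Uptake-time-matched frame selection across two imaging sessions.

Static frames are cut from each session's list-mode acquisition window so
that both sessions share *exactly* the same effective uptake interval
(minutes post-injection), not merely the same duration.  Within the overlap
of the two windows the frame is taken from the latest portion (PET/CT
convention, pushing uptake times toward the subsequent PET/MRI exam) or the
earliest portion (PET/MRI convention, pulling them toward the preceding
PET/CT) — the pairing that minimizes the uptake-time gap between modalities.

Intervals are half-open ``[start, end)`` real-valued minutes; list-mode
event replay and reconstruction are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import InsufficientOverlapError

__all__ = ["AcquisitionWindow", "MatchedIntervals", "matched_interval", "uptake_report"]


@dataclass(frozen=True)
class AcquisitionWindow:
    """One session's list-mode window: start (min post-injection) + duration."""

    start_min: float
    duration_min: float

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError(f"duration_min must be positive, got {self.duration_min}")

    @property
    def end_min(self) -> float:
        return self.start_min + self.duration_min


@dataclass(frozen=True)
class MatchedIntervals:
    """A common uptake interval and the per-session offsets realizing it.

    ``offsets_min[i]`` is the time skipped at the start of session *i*'s
    list-mode stream, so ``window_i.start + offset_i == uptake_interval[0]``
    for both sessions.
    """

    frame_duration_min: float
    uptake_interval: tuple[float, float]
    offsets_min: tuple[float, float]
    policy: str


def matched_interval(
    w1: AcquisitionWindow,
    w2: AcquisitionWindow,
    frame_duration_min: float,
    policy: str = "latest",
) -> MatchedIntervals:
    """Select one frame of ``frame_duration_min`` common to both windows.

    ``policy='latest'`` places the frame at the end of the overlap,
    ``'earliest'`` at its beginning.  Raises
    :class:`InsufficientOverlapError` (reporting the shortfall in minutes)
    when the overlap is shorter than the frame.
    """
    if policy not in ("latest", "earliest"):
        raise ValueError(f"policy must be 'latest' or 'earliest', got {policy!r}")
    f = float(frame_duration_min)
    if f <= 0:
        raise ValueError(f"frame_duration_min must be positive, got {f}")
    lo = max(w1.start_min, w2.start_min)
    hi = min(w1.end_min, w2.end_min)
    overlap = hi - lo
    if overlap < f:
        raise InsufficientOverlapError(
            f"windows overlap for {max(overlap, 0.0):g} min, "
            f"{f - max(overlap, 0.0):g} min short of the {f:g}-min frame"
        )
    if policy == "latest":
        interval = (hi - f, hi)
    else:
        interval = (lo, lo + f)
    offsets = (interval[0] - w1.start_min, interval[0] - w2.start_min)
    return MatchedIntervals(f, interval, offsets, policy)


def uptake_report(
    intervals: Iterable[MatchedIntervals] | Sequence[MatchedIntervals],
) -> dict[str, float | int | tuple[float, float]]:
    """Cohort audit summary of matched intervals.

    Reports mean/range of frame *endpoints* for latest-policy intervals and
    of frame *start points* for earliest-policy intervals (the quantity each
    policy pins down).
    """
    ivs = list(intervals)
    if not ivs:
        raise ValueError("uptake_report requires at least one matched interval")
    policies = {iv.policy for iv in ivs}
    if len(policies) > 1:
        raise ValueError(f"mixed policies in report: {sorted(policies)}")
    policy = policies.pop()
    pts = np.array(
        [iv.uptake_interval[1] if policy == "latest" else iv.uptake_interval[0] for iv in ivs]
    )
    key = "endpoint" if policy == "latest" else "start_point"
    return {
        "n": len(ivs),
        "policy": policy,
        f"mean_{key}_min": float(pts.mean()),
        f"{key}_range_min": (float(pts.min()), float(pts.max())),
    }
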