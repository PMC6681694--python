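"""Synthetic test-retest cohorts and lesion phantoms with known ground truth.

Two levels of simulation, designed to agree with each other:

* **Metric level** — per-subject true metric values M_i drawn from a
  lognormal between-subject distribution; the two session measurements are
  m_ij = M_i * exp(eps_ij) with eps_ij ~ Normal(0, sigma_w^2) independent
  across subjects and sessions.  Multiplicative lognormal within-subject
  error makes the %D framework distributionally clean and scale-free, and
  sigma_w is (to first order) the per-measurement CV.

* **Image level** — an ellipsoidal lesion (semi-axes >= 10 mm by default, so
  maximum diameter >= 2.0 cm, matching the study inclusion floor) of
  amplitude A * session_factor on a uniform background, convolved with a
  Gaussian point-spread function and degraded with additive Gaussian noise;
  the ROI mask is the pre-blur ellipsoid indicator.  With noise and
  background switched off, every linear metric's between-session %D reduces
  exactly to the session-factor %D, which ties the two levels together.

Defaults emulate the study conditions: 14 subjects, single pelvic lesion,
two sessions, within-subject CV 0.10 (mid-range of published FDG-PET
SUV_max repeatability); phantom geometry/intensity defaults are arbitrary
fixtures, not study ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .formats_io import (
    RoiMask,
    SubjectRecord,
    ValueKind,
    VolumeImage,
    write_mask,
    write_volume,
)
from .repeatability import PairedMeasurements

__all__ = [
    "CohortSimConfig",
    "PhantomConfig",
    "simulate_metric_cohort",
    "generate_lesion_phantom",
    "generate_paired_study",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class CohortSimConfig:
    """Metric-level cohort simulation parameters.

    ``between_subject_median``/``between_subject_sigma`` parameterize the
    lognormal distribution of true values M_i (median and log-scale SD);
    ``within_subject_cv`` is sigma_w, the SD of the per-measurement log
    error.  Identical seeds yield identical cohorts.
    """

    n_subjects: int = 14
    between_subject_median: float = 8.0
    between_subject_sigma: float = 0.4
    within_subject_cv: float = 0.10
    sessions: int = 2
    seed: int = 0
    metric_name: str = "suv_max"

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if self.within_subject_cv < 0:
            raise ValueError(f"within_subject_cv must be >= 0, got {self.within_subject_cv}")
        if self.between_subject_median <= 0 or self.between_subject_sigma < 0:
            raise ValueError("between-subject lognormal parameters out of range")
        if self.sessions != 2:
            raise ValueError("only the two-session test-retest design is supported")


def simulate_metric_cohort(config: CohortSimConfig) -> PairedMeasurements:
    """Draw a paired test-retest cohort: m_ij = M_i * exp(eps_ij)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    true_vals = config.between_subject_median * np.exp(
        rng.normal(0.0, config.between_subject_sigma, size=n)
    )
    eps = rng.normal(0.0, config.within_subject_cv, size=(n, 2))
    m = true_vals[:, None] * np.exp(eps)
    ids = [f"S{i + 1:03d}" for i in range(n)]
    return PairedMeasurements(config.metric_name, ids, m[:, 0], m[:, 1])


@dataclass
class PhantomConfig:
    """Image-level phantom parameters (all defaults are arbitrary fixtures).

    ``semi_axes_mm`` are the ellipsoid semi-axes along the array axes;
    the default keeps every semi-axis >= 10 mm (diameter >= 2.0 cm).
    ``invert_contrast=False`` gives a hot lesion on a cold background (PET);
    ``True`` gives a cold lesion on a bright background (ADC maps, where
    tumors are dark), with lesion value = background - amplitude * factor.
    ``within_subject_cv`` drives the per-session multiplicative factor
    exp(Normal(0, sigma_w^2)).
    """

    shape: tuple[int, int, int] = (40, 40, 40)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background: float = 1000.0
    semi_axes_mm: tuple[float, float, float] = (12.0, 10.0, 10.0)
    center: tuple[float, float, float] | None = None
    amplitude: float = 20000.0
    psf_fwhm_mm: float = 6.0
    noise_sd: float = 200.0
    within_subject_cv: float = 0.10
    value_kind: ValueKind = ValueKind.ACTIVITY
    invert_contrast: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.value_kind = ValueKind(self.value_kind)
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if not self.invert_contrast and self.amplitude <= self.background:
            raise ValueError("hot-lesion phantom requires amplitude > background")
        if self.invert_contrast and self.background <= self.amplitude:
            raise ValueError("inverted-contrast phantom requires background > amplitude")
        if self.noise_sd < 0 or self.psf_fwhm_mm < 0 or self.within_subject_cv < 0:
            raise ValueError("noise_sd, psf_fwhm_mm, within_subject_cv must be >= 0")
        ctr = self.center
        if ctr is None:
            ctr = tuple((s - 1) / 2.0 for s in self.shape)
        self.center = tuple(float(c) for c in ctr)
        extent_vox = [
            ax / sp for ax, sp in zip(self.semi_axes_mm, self.spacing, strict=True)
        ]
        for c, e, s in zip(self.center, extent_vox, self.shape, strict=True):
            if c - e < -0.5 or c + e > s - 0.5:
                raise ValueError(
                    f"lesion (center {self.center}, semi-axes {self.semi_axes_mm} mm) "
                    f"exceeds the {self.shape} grid"
                )


def _ellipsoid_indicator(config: PhantomConfig) -> np.ndarray:
    coords = np.meshgrid(*(np.arange(s, dtype=float) for s in config.shape), indexing="ij")
    acc = np.zeros(config.shape, dtype=float)
    for x, c, sp, ax in zip(coords, config.center, config.spacing, config.semi_axes_mm, strict=True):
        acc += ((x - c) * sp / ax) ** 2
    return acc <= 1.0


def generate_lesion_phantom(
    config: PhantomConfig,
    session: int = 1,
    session_factor: float | None = None,
) -> tuple[VolumeImage, RoiMask, dict]:
    """Ellipsoidal-lesion phantom for one session, with ground truth.

    The RNG stream is derived from (seed, session), so the two sessions of a
    subject differ only by their independently drawn session factor and
    noise.  An explicit ``session_factor`` overrides the drawn one (used by
    the paired-study generator to keep factors in the manifest).
    """
    if session not in (1, 2):
        raise ValueError(f"session must be 1 or 2, got {session}")
    rng = np.random.default_rng([config.seed, session])
    if session_factor is None:
        session_factor = float(np.exp(rng.normal(0.0, config.within_subject_cv)))
    ind = _ellipsoid_indicator(config)
    contrast = config.amplitude * session_factor
    if config.invert_contrast:
        values = config.background - contrast * ind
    else:
        values = config.background + contrast * ind
    if config.psf_fwhm_mm > 0:
        sigma_vox = [
            config.psf_fwhm_mm * _FWHM_TO_SIGMA / sp for sp in config.spacing
        ]
        values = ndimage.gaussian_filter(values, sigma=sigma_vox, mode="nearest")
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=config.shape)
    volume = VolumeImage(values, config.spacing, config.value_kind)
    mask = RoiMask(ind, config.spacing)
    a, b, c = config.semi_axes_mm
    truth = {
        "session": session,
        "session_factor": session_factor,
        "amplitude": config.amplitude,
        "background": config.background,
        "lesion_contrast": contrast,
        "lesion_value": config.background + (-contrast if config.invert_contrast else contrast),
        "ellipsoid_volume_mL": 4.0 / 3.0 * np.pi * a * b * c / 1000.0,
        "lesion_voxel_count": int(ind.sum()),
        "invert_contrast": config.invert_contrast,
    }
    return volume, mask, truth


# ---------------------------------------------------------------------------
# on-disk paired study fixtures


#: Modality-specific list-mode window defaults (start mean/SD, duration),
#: minutes post-injection, chosen to reproduce the study's printed timing
#: (PET/CT frames ending ~75 min, PET/MRI frames starting ~95 min).
_WINDOW_DEFAULTS = {
    "PETCT": {"start_mean": 60.0, "start_sd": 1.5, "duration": 15.0},
    "PETMR": {"start_mean": 95.0, "start_sd": 4.0, "duration": 30.0},
}


def _json_default(o):
    if isinstance(o, ValueKind):
        return o.value
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def generate_paired_study(
    cohort_config: CohortSimConfig,
    phantom_config: PhantomConfig,
    out_dir: str | Path,
    modalities: tuple[str, ...] = ("PETCT", "PETMR"),
    include_adc: bool = True,
    frame_duration_min: float = 3.0,
    recon_label: str = "OSEM",
) -> Path:
    """Write a full on-disk test-retest fixture study; returns the manifest path.

    Per subject x session x modality: a PET activity volume + mask +
    subject-record JSON; PET/MRI sessions additionally get an ADC channel
    (inverted-contrast phantom on the same grid).  A JSON manifest records
    every file plus ground truth (session factors, base amplitudes, seeds),
    enabling end-to-end parameter-recovery tests.  Demographics are drawn
    from study-like distributions (weight ~ N(82.5, 21^2) kg, height ~
    N(170, 10^2) cm, 13:1 female:male, 370 MBq dose).

    Re-running with the same configs produces a byte-identical manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cohort_config.seed, 0xC0F0])
    sw = cohort_config.within_subject_cv

    channels = []
    for mod in modalities:
        channels.append((mod, "PET", ValueKind.ACTIVITY))
        if mod == "PETMR" and include_adc:
            channels.append((mod, "ADC", ValueKind.ADC))

    entries = []
    for i in range(cohort_config.n_subjects):
        sid = f"S{i + 1:03d}"
        sex = "female" if rng.random() < 13.0 / 14.0 else "male"
        weight = float(np.clip(rng.normal(82.5, 21.0), 40.0, 160.0))
        height = float(np.clip(rng.normal(170.0, 10.0), 145.0, 200.0))
        # per-subject lesion amplitude (between-subject lognormal), shared
        # across channels; ADC base is fixed physiology-scale
        amp_scale = float(np.exp(rng.normal(0.0, cohort_config.between_subject_sigma)))
        win_starts = {
            mod: {
                s: float(
                    rng.normal(_WINDOW_DEFAULTS[mod]["start_mean"], _WINDOW_DEFAULTS[mod]["start_sd"])
                )
                for s in (1, 2)
            }
            for mod in modalities
        }
        for mod, channel, kind in channels:
            factors = {s: float(np.exp(rng.normal(0.0, sw))) for s in (1, 2)}
            for session in (1, 2):
                if kind is ValueKind.ADC:
                    cfg = PhantomConfig(
                        shape=phantom_config.shape,
                        spacing=phantom_config.spacing,
                        background=2.2,
                        semi_axes_mm=phantom_config.semi_axes_mm,
                        amplitude=1.4,
                        psf_fwhm_mm=phantom_config.psf_fwhm_mm / 2.0,
                        noise_sd=0.05 if phantom_config.noise_sd > 0 else 0.0,
                        within_subject_cv=sw,
                        value_kind=ValueKind.ADC,
                        invert_contrast=True,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                else:
                    cfg = PhantomConfig(
                        shape=phantom_config.shape,
                        spacing=phantom_config.spacing,
                        background=phantom_config.background,
                        semi_axes_mm=phantom_config.semi_axes_mm,
                        amplitude=phantom_config.amplitude * amp_scale,
                        psf_fwhm_mm=phantom_config.psf_fwhm_mm,
                        noise_sd=phantom_config.noise_sd,
                        within_subject_cv=sw,
                        value_kind=ValueKind.ACTIVITY,
                        invert_contrast=False,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                volume, mask, truth = generate_lesion_phantom(
                    cfg, session, session_factor=factors[session]
                )
                stem = f"{sid}_ses{session}_{mod}_{channel}"
                vol_path = out_dir / f"{stem}.nii.gz"
                mask_path = out_dir / f"{stem}_mask.nii.gz"
                rec_path = out_dir / f"{sid}_ses{session}_{mod}.json"
                write_volume(volume, vol_path)
                write_mask(mask, mask_path)
                record = SubjectRecord(
                    subject_id=sid,
                    sex=sex,
                    weight_kg=weight,
                    height_cm=height,
                    injected_dose_MBq=370.0,
                    session=session,
                    modality=mod,
                    acquisition_start_min=win_starts[mod][session],
                    acquisition_duration_min=_WINDOW_DEFAULTS[mod]["duration"],
                )
                record.to_json(rec_path)
                entries.append(
                    {
                        "subject_id": sid,
                        "session": session,
                        "modality": mod,
                        "channel": channel,
                        "value_kind": kind.value,
                        "volume": vol_path.name,
                        "mask": mask_path.name,
                        "record": rec_path.name,
                        "frame_duration_min": frame_duration_min,
                        "recon_label": recon_label,
                        "acquisition_start_min": win_starts[mod][session],
                        "acquisition_duration_min": _WINDOW_DEFAULTS[mod]["duration"],
                        "session_factor": factors[session],
                        "phantom_seed": cfg.seed,
                    }
                )
    manifest = {
        "cohort_config": asdict(cohort_config),
        "phantom_config": asdict(phantom_config),
        "modalities": list(modalities),
        "include_adc": include_adc,
        "entries": entries,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=_json_default) + "\n"
    )
    return manifest_path
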