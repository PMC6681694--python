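"""End-to-end synthetic study: phantoms -> metrics -> repeatability tables.

Generates a small paired PET/CT + PET/MRI cohort on disk (NIfTI volumes,
masks, subject records, ground-truth manifest), then runs the full pipeline:
uptake matching, SUV/SUL conversion, metric extraction, Bland-Altman
repeatability and a cross-modality mean-|%D| comparison with BH FDR control.
"""

import tempfile
from pathlib import Path

from repeatquant import (
    CohortSimConfig,
    PhantomConfig,
    StudyConfig,
    generate_paired_study,
    run_study,
)

workdir = Path(tempfile.mkdtemp(prefix="repeatquant_study_"))
cohort = CohortSimConfig(n_subjects=6, within_subject_cv=0.10, seed=3)
phantom = PhantomConfig(
    shape=(24, 24, 24), spacing=(3.0, 3.0, 3.0), semi_axes_mm=(12, 10, 10),
    psf_fwhm_mm=6.0, noise_sd=100.0, within_subject_cv=0.10,
)
manifest = generate_paired_study(cohort, phantom, workdir)

config = StudyConfig(
    manifest=manifest,
    comparison_plan=(
        {"metric_a": "suv_max", "modality_a": "PETCT",
         "metric_b": "suv_max", "modality_b": "PETMR"},
        {"metric_a": "sul_peak", "modality_a": "PETCT",
         "metric_b": "adc_median", "modality_b": "PETMR"},
    ),
    out_dir=workdir / "results",
)
result = run_study(config)

cols = ["metric", "modality", "n", "mean_pct_delta", "wcv_pct",
        "repeatability_coefficient_pct", "rc_coverage"]
print("repeatability per metric x modality:")
print(result.repeatability[cols].round(2).to_string(index=False))
print("\nuptake-time audit:")
print(result.uptake.to_string(index=False))
print("\ncross-modality mean |%D| comparisons (BH q = 0.05):")
print(result.pairwise_comparisons[
    ["metric_a", "modality_a", "metric_b", "modality_b",
     "mean_abs_pct_delta_a", "mean_abs_pct_delta_b", "p", "bh_reject"]
].round(3).to_string(index=False))
print(f"\ntables written to {workdir / 'results'}")
print("wCV ~10% reflects the simulated within-subject CV; with n = 6 the")
print("estimates scatter widely, mirroring small-cohort clinical studies.")
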