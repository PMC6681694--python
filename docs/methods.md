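# Methods

## Data model and conventions

Volumes are 3D scalar arrays with per-axis voxel spacing in mm and a
declared value kind (activity in Bq/mL, SUV or SUL in g/mL, ADC in
10⁻³ mm²/s). Array index order is (z, y, x) by convention; no world-space
affine math is performed beyond spacing, because single-station axial
volumes with a shared grid need no reorientation, and all mask/volume
pairings are validated for shape and spacing rather than resampled. NIfTI
is the sole volumetric format; "manual delineation" is represented as a
provided voxelized mask (one mask per subject/session/modality — whether a
contour is shared across modalities is left to how the caller builds the
manifest). Times are minutes post-injection as floats, injection = 0.

## SUV and SUL

SUV = C/(D(t)/W) with C the voxel activity concentration, W body weight and
D(t) the injected dose decay-corrected with the ¹⁸F half-life (109.771 min,
overridable). The decay reference time is the **start of the selected
reconstruction frame**; console software conventions differ here, but any
alternative only rescales all SUVs of a session by a common factor, which
cancels in the paired %Δ statistics that are this package's endpoint. SUL
rescales SUV by LBM/W with the James (1976) lean body mass:
male 1.10·W − 128·(W/H)², female 1.07·W − 148·(W/H)² (W kg, H cm). Outside
the physiologic domain the formula goes non-positive and is reported as an
error rather than clamped. No other LBM formula (e.g. Janmahasatian) and no
glucose correction are implemented.

## Sphere peak and trough

SUL_peak/SUV_peak is the highest — ADC_trough the lowest — mean over a
1-cm³ sphere positioned with its center inside the lesion contour. The
discretization: candidate centers are in-mask voxel centers (no sub-voxel
optimization — this keeps an exhaustive brute-force scan an exact oracle);
kernel membership is binary voxel-center inclusion within the equivalent
radius r = (3V/4π)^⅓ ≈ 6.204 mm; the sphere may extend beyond the contour
(PERCIST convention) but not beyond the image. The realized kernel volume
(count × voxel volume) deviates from 1 cm³ by a spacing-dependent amount
that is reported per kernel rather than corrected; at 2-mm isotropic
spacing it is 0.984 mL (123 voxels). When no candidate center admits the
full kernel (lesions near the image border on small fields of view), the
kernel is clipped to in-bounds voxels and the result carries a
`clipped=True` flag. ADC_trough has no universally printed formula; it is
defined here as the exact mirror (minimum-mean sphere) of the peak.

## Isocontour and volumes

The p% isocontour keeps in-mask voxels with value ≥ p% of the in-mask
maximum — inclusive threshold, no connected-component filtering (the
definition is purely threshold-based; a component filter could be layered
on but is deliberately absent). It is undefined (error) when the in-mask
maximum is ≤ 0. MTV/diffusional tumor volume is voxel count × voxel volume;
TLG is mean SUV (or SUL) × volume. Median uses the midpoint convention for
even counts.

## Uptake-time matching

Each session contributes a half-open list-mode window [start, start+dur) in
minutes post-injection (15 min for PET/CT, 30 min for PET/MRI in the
emulated design). A frame of duration f is placed in the overlap of the two
windows: `latest` policy at the overlap's end (PET/CT), `earliest` at its
beginning (PET/MRI) — this pairing minimizes the uptake gap between a
PET/CT exam and the PET/MRI exam that follows it. Both sessions then share
the uptake interval exactly, not merely its duration. Insufficient overlap
raises an error reporting the shortfall in minutes; list-mode replay and
OSEM/PSF reconstruction are out of scope (reconstruction labels pass
through as metadata).

## Repeatability statistics

%Δ uses the pair mean as denominator, making it antisymmetric in the
sessions, scale-free, and undefined for non-positive pair means (an error,
not a NaN). SD uses the n−1 denominator. RC = 1.96·SD exactly;
LOR = mean ± RC. The wCV divisor is a config flag: `sqrt2` (default) is the
standard within-subject CV from paired relative differences — for
m_ij = M_i·exp(ε_ij), ε ~ N(0, σ_w²), SD(%Δ) → 100·σ_w·√2, so SD/√2
estimates 100·σ_w, which the Monte-Carlo tests verify; `"2"` reproduces an
alternative printed convention and estimates 100·σ_w/√2. Both are reported
side by side in output tables rather than silently resolved.

Session comparisons use the Wilcoxon signed-rank test with zero differences
dropped (Wilcoxon's original convention — consequential at n = 14 and
therefore explicit), exact null distribution for ≤ 25 untied differences
and the tie-corrected normal approximation otherwise; unpaired comparisons
use Mann–Whitney U (exact for small untied samples). Both come from
scipy.stats; brute-force sign/label enumeration oracles in the test suite
pin the exact branches. All p-values are two-sided.

Benjamini–Hochberg step-up (in-package, ~10 lines, cross-checked against
statsmodels and a literal-definition oracle) rejects the k smallest
p-values for the largest k with p₍ₖ₎ ≤ kq/m and reports the **realized
cutoff** p₍ₖ₎ — study-specific significance thresholds like "P ≤ 0.01" are
outputs of the procedure on a given p-value set, not constants, so the
implementation never hard-codes them.

Normality of %Δ is assessed numerically by Shapiro–Wilk (a reproducible
surrogate for visual Q-Q inspection; attached for 3 ≤ n ≤ 5000, above which
scipy's p-value approximation degrades). `log_transform_check` recomputes
the diagnostic on 100·(ln m₂ − ln m₁) and reports whether normality
improves; the analysis proceeds on untransformed %Δ regardless, since
deviations from normality are benign for repeatability limits.

## Synthetic data

The metric-level generator draws M_i ~ lognormal(median 8.0, log-SD 0.4 —
an SUV_max-like scale and spread for pelvic tumors) and applies
multiplicative within-subject error exp(N(0, σ_w²)). Defaults emulate the
study conditions: n = 14 subjects, two sessions, σ_w = 0.10 (mid-range of
published FDG-PET SUV_max wCVs). The lognormal within-subject model is this
module's own assumption — no distributional model is implied by the %Δ
framework itself — chosen because it makes relative differences exact and
scale-free.

The image-level generator builds an ellipsoid indicator (default semi-axes
12/10/10 mm, keeping the maximum diameter ≥ 2.0 cm), scales it by
amplitude × session factor over a uniform background, applies Gaussian PSF
blur (a stand-in for reconstruction resolution, default FWHM 6 mm) and
additive Gaussian noise. The mask is the pre-blur indicator. ADC phantoms
reuse the generator with inverted contrast (lesion = background − contrast,
tumors being dark on ADC) and physiology-scale values (~2.2 background, 0.8
lesion, 10⁻³ mm²/s). `generate_paired_study` writes a full on-disk cohort
(volumes, masks, subject records with study-like demographics and
acquisition windows — PET/CT start ~N(60, 1.5²) min for 15 min, PET/MRI
~N(95, 4²) for 30 min — and a byte-reproducible ground-truth manifest).

What the phantoms do **not** model: realistic anatomy, attenuation-correction
artifacts, bladder filling/peristalsis, respiratory motion, Poisson count
statistics, or reconstruction nonlinearity. Passing tests therefore
demonstrate the correctness of the measurement-and-statistics chain under a
known error model, not the magnitude of clinical variability.

## Pipeline

`run_study` consumes a manifest, excludes (with a logged reason) any
subject missing one of the two sessions for a modality/channel — mirroring
real cohorts where artifacts or dropout shrink, e.g., an ADC analysis from
14 to 12 subjects — matches uptake intervals, converts activity → SUV → SUL,
extracts metrics, and emits per-subject metric tables, session-mean
Wilcoxon comparisons, per-metric repeatability summaries with RC-interval
coverage, Bland–Altman plot data (points + μ, μ±SD, μ±RC lines), an
uptake-time audit, and a declarative mean-|%Δ| comparison plan with BH
control across the plan. Which metric pairs to compare is explicit
configuration, not a judgment baked into code. Every table is reproducible
from the per-subject metric table by the public statistics functions; the
bundle holds no hidden state.

## Numerical and testing choices

Test problem sizes are chosen for tight oracles at interactive runtimes:
oracle-equivalence sweeps use ≥ 200 random instances per algorithm on grids
≤ 13³ and rank-test samples ≤ 12 (where enumeration is exact); coverage and
FDR checks use 10,000 subjects / 2,000 replicates; parameter recovery uses
200 cohorts of n = 14, whose recovered wCV spread is additionally checked
against the closed-form χ(13 df) distribution of an SD estimate. End-to-end
exactness uses noiseless, zero-background phantoms, where PSF blur is
linear and every intensity metric's %Δ collapses exactly to the
session-factor %Δ.

## Known limitations

No DICOM ingestion, registration, resampling or contour propagation; no
sub-voxel or partial-volume-weighted sphere placement; no
variance-components/ICC repeatability models; single lesion per subject;
the 40% isocontour is provided as an operation but not wired into the
default pipeline metric set.
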