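"""Bland-Altman test-retest repeatability statistics and hypothesis testing.

For paired measurements (m1, m2) of a metric on the same subject in two
sessions, the percentage difference is

    %D = 100 * (m2 - m1) / ((m1 + m2) / 2)

i.e. relative to the pair mean, which makes the statistic antisymmetric in
the sessions and scale-free.  Across a cohort:

* SD        — sample standard deviation of %D (n-1 denominator)
* wCV       — within-subject coefficient of variation, SD / divisor.  The
              standard divisor for paired relative differences is sqrt(2)
              (under which wCV estimates the per-measurement CV); divisor 2
              is offered as an alternative convention.  See docs/methods.md.
* RC        — repeatability coefficient, 1.96 * SD (exactly)
* LOR       — 95% limits of repeatability, mean %D +/- RC
* mean |%D| — mean absolute percentage difference, 0 only under perfect
              repeatability; used for pairwise repeatability comparisons.

Under approximate normality of %D, about 95% of subjects fall within one RC
of the mean %D.

Hypothesis tests (two-sided throughout): Wilcoxon signed-rank for paired
comparisons, Mann-Whitney U for unpaired, Benjamini-Hochberg step-up to
control the false-discovery rate across a battery of tests, and
Shapiro-Wilk as the numeric normality diagnostic (replacing visual Q-Q
inspection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "RepeatabilitySummary",
    "percent_difference",
    "repeatability_summary",
    "coverage_check",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "MannWhitneyResult",
    "mann_whitney_u",
    "BHResult",
    "benjamini_hochberg",
    "normality_diagnostic",
    "log_transform_check",
    "bland_altman_data",
]

_WCV_DIVISORS = {"sqrt2": math.sqrt(2.0), "2": 2.0}


@dataclass
class PairedMeasurements:
    """Session-1 / session-2 values of one metric across a cohort.

    Each subject appears once; values must be finite and (for %D) have a
    positive pair mean.
    """

    metric: str
    subject_ids: list[str]
    m1: np.ndarray
    m2: np.ndarray

    def __post_init__(self) -> None:
        self.m1 = np.asarray(self.m1, dtype=float)
        self.m2 = np.asarray(self.m2, dtype=float)
        n = len(self.subject_ids)
        if self.m1.shape != (n,) or self.m2.shape != (n,):
            raise ValueError(
                f"m1/m2 must have one value per subject ({n}), "
                f"got {self.m1.shape} and {self.m2.shape}"
            )
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        if not (np.isfinite(self.m1).all() and np.isfinite(self.m2).all()):
            raise ValueError("measurements must be finite")

    @classmethod
    def from_records(
        cls, metric: str, records: Sequence[tuple[str, float, float]]
    ) -> "PairedMeasurements":
        ids = [r[0] for r in records]
        return cls(
            metric,
            ids,
            np.array([r[1] for r in records], float),
            np.array([r[2] for r in records], float),
        )

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    def pct_deltas(self) -> np.ndarray:
        return percent_difference(self.m1, self.m2)

    def pair_means(self) -> np.ndarray:
        return (self.m1 + self.m2) / 2.0

    def swapped(self) -> "PairedMeasurements":
        return PairedMeasurements(self.metric, list(self.subject_ids), self.m2, self.m1)


def percent_difference(m1, m2):
    """%D = 100 (m2 - m1) / pair mean; antisymmetric under session swap.

    Accepts scalars or arrays; raises when any pair mean is non-positive
    (the relative difference is then undefined).
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    mean = (m1 + m2) / 2.0
    if np.any(mean <= 0):
        bad = int(np.sum(mean <= 0))
        raise ValueError(f"%Δ undefined for {bad} pair(s) with non-positive pair mean")
    out = 100.0 * (m2 - m1) / mean
    return float(out) if out.ndim == 0 else out


@dataclass
class RepeatabilitySummary:
    """Cohort %D distribution statistics for one metric."""

    metric: str
    n: int
    mean_pct_delta: float
    sd_pct_delta: float
    wcv_pct: float
    repeatability_coefficient_pct: float
    lor_lower_pct: float
    lor_upper_pct: float
    mean_abs_pct_delta: float
    wcv_divisor: str
    normality_statistic: float = float("nan")
    normality_p: float = float("nan")

    def to_row(self) -> dict:
        return {
            "metric": self.metric,
            "n": self.n,
            "mean_pct_delta": self.mean_pct_delta,
            "sd_pct_delta": self.sd_pct_delta,
            "wcv_pct": self.wcv_pct,
            "repeatability_coefficient_pct": self.repeatability_coefficient_pct,
            "lor_lower_pct": self.lor_lower_pct,
            "lor_upper_pct": self.lor_upper_pct,
            "mean_abs_pct_delta": self.mean_abs_pct_delta,
            "wcv_divisor": self.wcv_divisor,
            "normality_statistic": self.normality_statistic,
            "normality_p": self.normality_p,
        }


def repeatability_summary(
    pairs: PairedMeasurements, wcv_divisor: str = "sqrt2"
) -> RepeatabilitySummary:
    """Full Bland-Altman repeatability battery for one metric's cohort.

    Requires n >= 2 subjects.  The Shapiro-Wilk normality diagnostic is
    attached when n >= 3 and the %D values are not all identical (it is
    undefined for constant samples); otherwise NaN.
    """
    if wcv_divisor not in _WCV_DIVISORS:
        raise ValueError(f"wcv_divisor must be one of {sorted(_WCV_DIVISORS)}")
    if pairs.n < 2:
        raise ValueError(f"repeatability summary requires n >= 2, got n = {pairs.n}")
    pd_ = pairs.pct_deltas()
    mean = float(pd_.mean())
    sd = float(pd_.std(ddof=1))
    rc = 1.96 * sd
    # Shapiro-Wilk is attached for cohort-scale samples; above n=5000 its
    # p-value approximation degrades and the diagnostic is uninformative
    w_stat, w_p = float("nan"), float("nan")
    if 3 <= pairs.n <= 5000 and np.ptp(pd_) > 0:
        w_stat, w_p = (float(x) for x in stats.shapiro(pd_))
    return RepeatabilitySummary(
        metric=pairs.metric,
        n=pairs.n,
        mean_pct_delta=mean,
        sd_pct_delta=sd,
        wcv_pct=sd / _WCV_DIVISORS[wcv_divisor],
        repeatability_coefficient_pct=rc,
        lor_lower_pct=mean - rc,
        lor_upper_pct=mean + rc,
        mean_abs_pct_delta=float(np.abs(pd_).mean()),
        wcv_divisor=wcv_divisor,
        normality_statistic=w_stat,
        normality_p=w_p,
    )


def coverage_check(pairs: PairedMeasurements, summary: RepeatabilitySummary) -> float:
    """Fraction of subjects with |%D - mean %D| <= RC (expected ~0.95)."""
    pd_ = pairs.pct_deltas()
    return float(
        np.mean(np.abs(pd_ - summary.mean_pct_delta) <= summary.repeatability_coefficient_pct)
    )


# ---------------------------------------------------------------------------
# hypothesis tests


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    pvalue: float
    n_nonzero: int
    all_zero: bool


def wilcoxon_signed_rank(a, b) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon's original convention; with a
    14-subject cohort this choice is consequential and therefore explicit).
    The p-value is from the exact null distribution for n <= 25 untied
    differences, otherwise from the tie-corrected normal approximation.
    All-zero differences yield p = 1 with ``all_zero=True``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("paired samples must be equal-length nonempty 1D arrays")
    d = b - a
    d = d[d != 0]
    if d.size == 0:
        return WilcoxonResult(0.0, 1.0, 0, True)
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return WilcoxonResult(float(res.statistic), float(res.pvalue), int(d.size), False)


@dataclass(frozen=True)
class MannWhitneyResult:
    statistic: float
    pvalue: float


def mann_whitney_u(group_a, group_b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test on two independent samples.

    Exact null distribution for small untied samples (both n <= 25),
    tie-corrected normal approximation with continuity correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not ties and max(a.size, b.size) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(float(res.statistic), float(res.pvalue))


@dataclass(frozen=True)
class BHResult:
    """Benjamini-Hochberg outcome: per-hypothesis flags (input order) and the
    realized p-value cutoff (largest rejected p; 0 when nothing is rejected)."""

    reject: np.ndarray
    cutoff: float
    n_rejected: int


def benjamini_hochberg(p_values, q: float = 0.05) -> BHResult:
    """BH step-up procedure controlling the FDR at level ``q``.

    Sort p ascending; find the largest k with p_(k) <= k q / m; reject the k
    smallest p-values.  The realized cutoff p_(k) is reported because it —
    not q — is the study-specific significance threshold the procedure
    induces on a given p-value set.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1D array")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = (np.arange(1, m + 1) * q) / m
    passing = np.nonzero(sorted_p <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size == 0:
        return BHResult(reject, 0.0, 0)
    k = int(passing[-1])  # largest index with p_(k) <= k q / m
    cutoff = float(sorted_p[k])
    reject[p <= cutoff] = True
    return BHResult(reject, cutoff, int(reject.sum()))


# ---------------------------------------------------------------------------
# normality diagnostics


def normality_diagnostic(values) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p for a %D sample (numeric stand-in for
    visual Q-Q inspection); requires n >= 3 non-constant values."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"normality diagnostic requires n >= 3, got {x.size}")
    stat, p = stats.shapiro(x)
    return float(stat), float(p)


def log_transform_check(pairs: PairedMeasurements) -> dict:
    """Compare normality of raw %D vs log-scale paired differences.

    The log branch uses 100 (ln m2 - ln m1), directly interpretable as a
    relative difference.  Reports both Shapiro-Wilk results and whether the
    log transform improves the normality statistic; the repeatability
    analysis itself proceeds on untransformed %D regardless (deviations from
    normality are benign in repeatability settings).
    """
    if np.any(pairs.m1 <= 0) or np.any(pairs.m2 <= 0):
        raise ValueError("log-transform check requires strictly positive measurements")
    raw = pairs.pct_deltas()
    logd = 100.0 * (np.log(pairs.m2) - np.log(pairs.m1))
    raw_stat, raw_p = normality_diagnostic(raw)
    log_stat, log_p = normality_diagnostic(logd)
    return {
        "raw_statistic": raw_stat,
        "raw_p": raw_p,
        "log_statistic": log_stat,
        "log_p": log_p,
        "log_improves_normality": log_stat > raw_stat,
    }


# ---------------------------------------------------------------------------
# Bland-Altman plot data


def bland_altman_data(
    pairs: PairedMeasurements, summary: RepeatabilitySummary
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-subject (pair mean, %D) points plus reference-line levels.

    Reference lines: mean %D, mean +/- SD (dotted in the conventional plot)
    and mean +/- RC (the 95% limits of repeatability); upper minus lower RC
    line equals 2 RC.
    """
    points = pd.DataFrame(
        {
            "subject_id": pairs.subject_ids,
            "pair_mean": pairs.pair_means(),
            "pct_delta": pairs.pct_deltas(),
        }
    )
    mu, sd, rc = summary.mean_pct_delta, summary.sd_pct_delta, summary.repeatability_coefficient_pct
    lines = {
        "mean": mu,
        "mean_minus_sd": mu - sd,
        "mean_plus_sd": mu + sd,
        "lor_lower": mu - rc,
        "lor_upper": mu + rc,
    }
    return points, lines
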