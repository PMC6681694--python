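"""End-to-end study orchestration.

``run_study`` drives the full analysis on a manifest of per-subject,
per-session, per-modality volumes and masks:

1. load the cohort manifest, excluding (with a logged reason) any subject
   missing one of the two sessions for a modality/channel;
2. uptake-time bookkeeping: match a common reconstruction interval per
   subject x modality (latest-overlap policy for PET/CT, earliest for
   PET/MRI) and summarize endpoints/start points per modality;
3. convert PET activity volumes to SUV and SUL (decay reference = matched
   frame start) and extract the configured metrics per channel;
4. paired statistics per metric x modality x frame x reconstruction:
   session-1 vs session-2 Wilcoxon signed-rank, the Bland-Altman
   repeatability battery, RC-interval coverage and plot data;
5. pairwise repeatability comparisons of mean |%D| per the declarative
   comparison plan, with Benjamini-Hochberg FDR control across the plan.

Every table in the result bundle is reproducible by calling the underlying
module functions on the per-subject metric table; the bundle holds no
hidden state.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import RepeatQuantError
from .formats_io import (
    SubjectRecord,
    ValueKind,
    read_mask,
    read_volume,
    write_results_table,
)
from .repeatability import (
    PairedMeasurements,
    benjamini_hochberg,
    bland_altman_data,
    coverage_check,
    mann_whitney_u,
    repeatability_summary,
    wilcoxon_signed_rank,
)
from .roi_metrics import SphereKernel, extract_metric_set
from .suv_sul import activity_to_suv, suv_to_sul
from .uptake_timing import AcquisitionWindow, matched_interval, uptake_report

__all__ = ["StudyConfig", "StudyResult", "run_study"]

logger = logging.getLogger("repeatquant.pipeline")

#: Default metric requests per channel.
DEFAULT_PET_METRICS = (
    "suv_max",
    "suv_mean",
    "suv_median",
    "suv_peak",
    "metabolic_tumor_volume_mL",
    "total_lesion_glycolysis_g",
)
DEFAULT_SUL_METRICS = ("sul_peak",)
DEFAULT_ADC_METRICS = ("adc_mean", "adc_median", "adc_trough", "diffusional_tumor_volume_mL")

#: Overlap policy per modality: push PET/CT frames late, PET/MRI frames
#: early, minimizing the uptake-time gap between the two scanners.
_POLICY = {"PETCT": "latest", "PETMR": "earliest"}


@dataclass
class StudyConfig:
    """Declarative configuration of one study run.

    ``comparison_plan`` entries are dicts with keys ``metric_a``,
    ``modality_a``, ``metric_b``, ``modality_b`` and optional ``test``
    ("mann_whitney", the default, or "wilcoxon" for subject-paired
    comparisons) selecting the mean-|%D| repeatability comparison to run.
    """

    manifest: str | Path
    modalities: tuple[str, ...] = ("PETCT", "PETMR")
    frame_durations: tuple[float, ...] = (3.0,)
    pet_metrics: tuple[str, ...] = DEFAULT_PET_METRICS
    sul_metrics: tuple[str, ...] = DEFAULT_SUL_METRICS
    adc_metrics: tuple[str, ...] = DEFAULT_ADC_METRICS
    wcv_divisor: str = "sqrt2"
    fdr_q: float = 0.05
    comparison_plan: tuple[dict, ...] = ()
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ValueError("at least one modality required")
        known = set(self.pet_metrics) | set(self.sul_metrics) | set(self.adc_metrics)
        if not known:
            raise ValueError("at least one metric required")
        for comp in self.comparison_plan:
            for k in ("metric_a", "modality_a", "metric_b", "modality_b"):
                if k not in comp:
                    raise ValueError(f"comparison plan entry missing {k!r}: {comp}")
            for k in ("metric_a", "metric_b"):
                if comp[k] not in known:
                    raise ValueError(f"comparison references undefined metric {comp[k]!r}")


@dataclass
class StudyResult:
    """Bundle of result tables from one :func:`run_study` call."""

    metrics: pd.DataFrame
    session_comparisons: pd.DataFrame
    repeatability: pd.DataFrame
    pairwise_comparisons: pd.DataFrame
    bland_altman: pd.DataFrame
    uptake: pd.DataFrame
    exclusions: list[dict] = field(default_factory=list)
    pairs: dict[tuple, PairedMeasurements] = field(default_factory=dict)


def _metric_requests(config: StudyConfig, kind: ValueKind) -> tuple[str, ...]:
    if kind is ValueKind.ACTIVITY:
        return config.pet_metrics
    if kind is ValueKind.ADC:
        return config.adc_metrics
    raise RepeatQuantError(f"unsupported channel value kind {kind}")


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full repeatability analysis described by ``config``."""
    manifest_path = Path(config.manifest)
    base = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    entries = [e for e in manifest["entries"] if e["modality"] in config.modalities]
    if not entries:
        raise RepeatQuantError("manifest has no entries for the configured modalities")

    # ---- group by (subject, modality, channel, frame, recon); enforce pairing
    groups: dict[tuple, dict[int, dict]] = {}
    for e in entries:
        if e["frame_duration_min"] not in config.frame_durations:
            continue
        key = (e["subject_id"], e["modality"], e["channel"], e["frame_duration_min"], e["recon_label"])
        groups.setdefault(key, {})[int(e["session"])] = e
    exclusions: list[dict] = []
    complete: dict[tuple, dict[int, dict]] = {}
    for key, sessions in groups.items():
        missing = [s for s in (1, 2) if s not in sessions]
        if missing:
            reason = f"missing session(s) {missing}"
            logger.warning("excluding %s / %s / %s: %s", key[0], key[1], key[2], reason)
            exclusions.append(
                {"subject_id": key[0], "modality": key[1], "channel": key[2], "reason": reason}
            )
        else:
            complete[key] = sessions
    if not complete:
        raise RepeatQuantError("no subject has both sessions for any modality/channel")

    # ---- uptake-time matching per subject x modality x frame duration
    uptake_rows = []
    matched: dict[tuple, object] = {}
    by_mod: dict[tuple, list] = {}
    for key, sessions in complete.items():
        sid, mod, channel, frame, recon = key
        if channel != "PET":
            continue
        e1, e2 = sessions[1], sessions[2]
        if e1.get("acquisition_start_min") is None:
            continue
        w1 = AcquisitionWindow(e1["acquisition_start_min"], e1["acquisition_duration_min"])
        w2 = AcquisitionWindow(e2["acquisition_start_min"], e2["acquisition_duration_min"])
        iv = matched_interval(w1, w2, frame, policy=_POLICY.get(mod, "latest"))
        matched[(sid, mod, frame)] = iv
        by_mod.setdefault((mod, frame), []).append(iv)
    for (mod, frame), ivs in sorted(by_mod.items()):
        rep = uptake_report(ivs)
        row = {"modality": mod, "frame_duration_min": frame, **rep}
        rng_key = [k for k in rep if k.endswith("_range_min")][0]
        row[rng_key] = str(rep[rng_key])
        uptake_rows.append(row)
    uptake_df = pd.DataFrame(uptake_rows)

    # ---- metric extraction
    metric_rows = []
    kernels: dict[tuple, SphereKernel] = {}
    for key in sorted(complete):
        sid, mod, channel, frame, recon = key
        for session in (1, 2):
            e = complete[key][session]
            kind = ValueKind(e["value_kind"])
            volume = read_volume(base / e["volume"], kind)
            mask = read_mask(base / e["mask"], volume)
            if tuple(volume.spacing) not in kernels:
                kernels[tuple(volume.spacing)] = SphereKernel(volume.spacing)
            kernel = kernels[tuple(volume.spacing)]
            record = SubjectRecord.from_json(base / e["record"])
            sets = []
            if kind is ValueKind.ACTIVITY:
                iv = matched.get((sid, mod, frame))
                ref_time = iv.uptake_interval[0] if iv is not None else (
                    e.get("acquisition_start_min") or 0.0
                )
                suv = activity_to_suv(volume, record, ref_time)
                suv.frame_window = iv.uptake_interval if iv is not None else None
                sets.append(extract_metric_set(suv, mask, config.pet_metrics, kernel))
                if config.sul_metrics:
                    sul = suv_to_sul(suv, record)
                    sets.append(extract_metric_set(sul, mask, config.sul_metrics, kernel))
            elif kind is ValueKind.ADC:
                sets.append(extract_metric_set(volume, mask, config.adc_metrics, kernel))
            else:
                raise RepeatQuantError(f"unexpected value kind in manifest: {kind}")
            for ms in sets:
                for name, value in ms.values.items():
                    metric_rows.append(
                        {
                            "subject_id": sid,
                            "session": session,
                            "modality": mod,
                            "channel": channel,
                            "frame_duration_min": frame,
                            "recon_label": recon,
                            "metric": name,
                            "value": value,
                        }
                    )
    metrics_df = pd.DataFrame(metric_rows)

    # ---- paired statistics per metric cell
    pairs: dict[tuple, PairedMeasurements] = {}
    session_rows, repeat_rows, ba_rows = [], [], []
    cell_cols = ["modality", "frame_duration_min", "recon_label", "metric"]
    for cell, sub in metrics_df.groupby(cell_cols):
        mod, frame, recon, metric = cell
        wide = sub.pivot(index="subject_id", columns="session", values="value").dropna()
        if len(wide) < 2:
            continue
        pm = PairedMeasurements(
            metric, list(wide.index), wide[1].to_numpy(), wide[2].to_numpy()
        )
        pairs[cell] = pm
        wres = wilcoxon_signed_rank(pm.m1, pm.m2)
        session_rows.append(
            {
                "modality": mod,
                "frame_duration_min": frame,
                "recon_label": recon,
                "metric": metric,
                "n": pm.n,
                "mean_session1": float(pm.m1.mean()),
                "mean_session2": float(pm.m2.mean()),
                "wilcoxon_statistic": wres.statistic,
                "wilcoxon_p": wres.pvalue,
                "all_differences_zero": wres.all_zero,
            }
        )
        summ = repeatability_summary(pm, wcv_divisor=config.wcv_divisor)
        row = summ.to_row()
        row.update(
            {
                "modality": mod,
                "frame_duration_min": frame,
                "recon_label": recon,
                "rc_coverage": coverage_check(pm, summ),
            }
        )
        repeat_rows.append(row)
        points, lines = bland_altman_data(pm, summ)
        points = points.assign(
            modality=mod, frame_duration_min=frame, recon_label=recon, metric=metric, **lines
        )
        ba_rows.append(points)
    session_df = pd.DataFrame(session_rows)
    repeat_df = pd.DataFrame(repeat_rows)
    ba_df = pd.concat(ba_rows, ignore_index=True) if ba_rows else pd.DataFrame()

    # ---- pairwise mean-|%D| comparisons with BH FDR control
    comp_rows = []
    if config.comparison_plan:
        pvals = []
        for comp in config.comparison_plan:
            pa = _find_pair(pairs, comp["metric_a"], comp["modality_a"])
            pb = _find_pair(pairs, comp["metric_b"], comp["modality_b"])
            abs_a, abs_b = np.abs(pa.pct_deltas()), np.abs(pb.pct_deltas())
            test = comp.get("test", "mann_whitney")
            if test == "wilcoxon":
                shared = sorted(set(pa.subject_ids) & set(pb.subject_ids))
                ia = [pa.subject_ids.index(s) for s in shared]
                ib = [pb.subject_ids.index(s) for s in shared]
                res = wilcoxon_signed_rank(abs_a[ia], abs_b[ib])
                stat, p = res.statistic, res.pvalue
            elif test == "mann_whitney":
                res = mann_whitney_u(abs_a, abs_b)
                stat, p = res.statistic, res.pvalue
            else:
                raise ValueError(f"unknown comparison test {test!r}")
            pvals.append(p)
            comp_rows.append(
                {
                    "metric_a": comp["metric_a"],
                    "modality_a": comp["modality_a"],
                    "metric_b": comp["metric_b"],
                    "modality_b": comp["modality_b"],
                    "test": test,
                    "mean_abs_pct_delta_a": float(abs_a.mean()),
                    "mean_abs_pct_delta_b": float(abs_b.mean()),
                    "statistic": stat,
                    "p": p,
                }
            )
        bh = benjamini_hochberg(pvals, q=config.fdr_q)
        for row, rej in zip(comp_rows, bh.reject, strict=True):
            row["bh_reject"] = bool(rej)
            row["bh_cutoff"] = bh.cutoff
    comp_df = pd.DataFrame(comp_rows)

    result = StudyResult(
        metrics=metrics_df,
        session_comparisons=session_df,
        repeatability=repeat_df,
        pairwise_comparisons=comp_df,
        bland_altman=ba_df,
        uptake=uptake_df,
        exclusions=exclusions,
        pairs=pairs,
    )
    if config.out_dir is not None:
        _write_bundle(result, Path(config.out_dir))
    return result


def _find_pair(
    pairs: dict[tuple, PairedMeasurements], metric: str, modality: str
) -> PairedMeasurements:
    hits = [pm for (mod, _f, _r, met), pm in pairs.items() if met == metric and mod == modality]
    if not hits:
        raise RepeatQuantError(
            f"comparison plan references unavailable cell: {metric} / {modality}"
        )
    return hits[0]


def _write_bundle(result: StudyResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_results_table(result.metrics, out_dir / "metrics.csv")
    write_results_table(result.session_comparisons, out_dir / "session_comparisons.csv")
    write_results_table(result.repeatability, out_dir / "repeatability.csv")
    write_results_table(
        result.pairwise_comparisons,
        out_dir / "pairwise_comparisons.csv",
        fieldnames=["metric_a", "modality_a", "metric_b", "modality_b", "test", "p"],
    )
    write_results_table(result.bland_altman, out_dir / "bland_altman.csv")
    write_results_table(result.uptake, out_dir / "uptake.csv")
    (out_dir / "exclusions.json").write_text(json.dumps(result.exclusions, indent=1) + "\n")
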