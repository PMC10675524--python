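"""End-to-end orchestration of the validation pipeline.

Stages (in dependency order): simulate -> preprocess -> responses ->
{validate, associate, xcorr} -> report. Each stage reads the CSV outputs of
its upstream stages from the artifact directory and writes its own, so a
partial rerun reuses cached upstream outputs. All randomness derives from the
config seed; a JSON-lines run log records seeds, exclusion counts and the
selected random structure.

Conventions: stimulus onset is t=0; EMG sample indices are 0-based; frame
bins are half-open [i/fps, (i+1)/fps); tabular interchange is long-format CSV
with a header and empty fields for missing values.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, save_config
from .contrasts import ConditionContrastModel, ModelFitError
from .latency import (
    aggregate_xcorr,
    apply_quality_mask,
    cross_correlation,
    group_average_timeseries,
    resample_emg_to_frames,
    zero_anchor,
)
from .preprocess import preprocess_trace
from .responses import (
    detection_metrics,
    mimicry_confusion,
    response_pairs,
    sign_congruence_accuracy,
    zero_output_report,
)
from .rmcorr import RepeatedMeasuresCorr
from .synthetic import (
    cohort_au_frame,
    cohort_emg_frame,
    simulate_cohort,
    trials_from_frames,
    write_cohort_csv,
)

STAGES = ("simulate", "preprocess", "responses", "validate", "associate", "xcorr", "report")

_DEPENDENCIES = {
    "simulate": (),
    "preprocess": ("emg.csv",),
    "responses": ("emg_preprocessed.csv", "au.csv"),
    "validate": ("responses.csv",),
    "associate": ("responses.csv",),
    "xcorr": ("emg_preprocessed.csv", "au.csv"),
    "report": ("responses.csv",),
}


class StageDependencyError(RuntimeError):
    """Raised when a requested stage is missing its upstream outputs."""


class RunLog:
    """Append-only JSON-lines run log."""

    def __init__(self, path: Path):
        self.path = Path(path)

    def record(self, stage: str, **info) -> None:
        entry = {"ts": time.strftime("%Y-%m-%dT%H:%M:%S"), "stage": stage, **info}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def run_pipeline(
    config: RunConfig, stages: list[str] | None = None, outdir: str | Path | None = None
) -> dict[str, Path]:
    """Run the requested stages; returns a name -> path map of artifacts."""
    stages = list(STAGES) if stages is None else list(stages)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    stages.sort(key=STAGES.index)
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog(out / "runlog.jsonl")
    artifacts: dict[str, Path] = {}

    for stage in stages:
        missing = [f for f in _DEPENDENCIES[stage] if not (out / f).exists()]
        if missing:
            raise StageDependencyError(
                f"stage {stage!r} requires upstream outputs {missing}; "
                "run the earlier stages first"
            )
        _RUNNERS[stage](config, out, log, artifacts)
    return artifacts


# -- stage implementations ----------------------------------------------


def _stage_simulate(cfg: RunConfig, out: Path, log: RunLog, artifacts: dict) -> None:
    trials = simulate_cohort(
        cfg.design,
        cfg.ground_truth,
        software_tag=cfg.software_tag,
        exclude_live_mishaps=cfg.exclude_live_mishaps,
        seed=cfg.seed,
    )
    write_cohort_csv(trials, out / "emg.csv", out / "au.csv")
    save_config(cfg, out / "manifest.yaml")
    log.record("simulate", seed=cfg.seed, n_trials=len(trials), software_tag=cfg.software_tag)
    artifacts["emg"] = out / "emg.csv"
    artifacts["au"] = out / "au.csv"
    artifacts["manifest"] = out / "manifest.yaml"


def _load_trials(cfg: RunConfig, out: Path, emg_name: str = "emg.csv"):
    emg = pd.read_csv(out / emg_name)
    au = pd.read_csv(out / "au.csv")
    return trials_from_frames(
        emg,
        au,
        onset_index=cfg.design.onset_index,
        emg_rate_hz=cfg.design.emg_rate_hz,
        au_fps=cfg.design.au_fps,
        software_tag=cfg.software_tag,
    )


def _stage_preprocess(cfg: RunConfig, out: Path, log: RunLog, artifacts: dict) -> None:
    emg = pd.read_csv(out / "emg.csv")
    parts = []
    n_flagged = 0
    for (subject, trial), g in emg.groupby(["subject", "trial"], sort=False):
        g = g.sort_values("sample_index")
        tr_zm = preprocess_trace(
            g["zm"].to_numpy(float), cfg.design.onset_index, cfg.design.emg_rate_hz,
            cfg.preprocess, channel="ZM",
        )
        tr_cs = preprocess_trace(
            g["cs"].to_numpy(float), cfg.design.onset_index, cfg.design.emg_rate_hz,
            cfg.preprocess, channel="CS",
        )
        n_flagged += int(tr_zm.artifact_flag or tr_cs.artifact_flag)
        gg = g.copy()
        gg["zm"] = tr_zm.amplitude
        gg["cs"] = tr_cs.amplitude
        gg["artifact"] = tr_zm.artifact_flag or tr_cs.artifact_flag
        parts.append(gg)
    pd.concat(parts, ignore_index=True).to_csv(out / "emg_preprocessed.csv", index=False)
    log.record("preprocess", n_trials=len(parts), n_artifact_flagged=n_flagged)
    artifacts["emg_preprocessed"] = out / "emg_preprocessed.csv"


def _stage_responses(cfg: RunConfig, out: Path, log: RunLog, artifacts: dict) -> None:
    trials = _load_trials(cfg, out)
    pairs = response_pairs(trials, preproc=cfg.preprocess, windows=cfg.windows)
    pairs.to_csv(out / "responses.csv", index=False)
    log.record(
        "responses",
        n_trials=len(pairs),
        n_zero_output=int(pairs["zero_output"].sum()),
        n_artifact=int(pairs["artifact"].sum()),
    )
    artifacts["responses"] = out / "responses.csv"


def _stage_validate(cfg: RunConfig, out: Path, log: RunLog, artifacts: dict) -> None:
    pairs = pd.read_csv(out / "responses.csv")
    trials = _load_trials(cfg, out)
    n_zero, n_total, prop = zero_output_report(trials)
    rows = []
    for au_channel in ("au12", "au4"):
        for mode in ("single_channel", "compound"):
            for include_zero in (False, True):
                counts = mimicry_confusion(
                    pairs, mode=mode, au_channel=au_channel, include_zero_output=include_zero
                )
                m = detection_metrics(counts)
                rows.append(
                    {
                        "software_tag": cfg.software_tag,
                        "au_channel": au_channel,
                        "mode": mode,
                        "include_zero_output": include_zero,
                        "tp": counts.tp,
                        "fp": counts.fp,
                        "tn": counts.tn,
                        "fn": counts.fn,
                        "sensitivity": m.sensitivity,
                        "specificity": m.specificity,
                        "ppv": m.ppv,
                        "npv": m.npv,
                        "f1": m.f1,
                        "response_accuracy": sign_congruence_accuracy(
                            pairs,
                            emg_col="zm_response" if au_channel == "au12" else "cs_response",
                            au_col=f"{au_channel}_response",
                            include_zero_output=include_zero,
                        ),
                    }
                )
    pd.DataFrame(rows).to_csv(out / "detection_metrics.csv", index=False)
    with open(out / "zero_output.json", "w") as fh:
        json.dump({"n_zero": n_zero, "n_total": n_total, "proportion": prop}, fh)
    log.record("validate", n_zero_output=n_zero, n_total=n_total, proportion=prop)
    artifacts["detection_metrics"] = out / "detection_metrics.csv"
    artifacts["zero_output"] = out / "zero_output.json"


def _stage_associate(cfg: RunConfig, out: Path, log: RunLog, artifacts: dict) -> None:
    pairs = pd.read_csv(out / "responses.csv")
    usable = pairs[pairs["exclude_reason"] != "zero_output"]
    model = RepeatedMeasuresCorr(
        usable["zm_response"], usable["au12_response"], usable["subject"]
    )
    res = model.fit(n_boot=cfg.rmcorr.n_boot, seed=cfg.seed)
    pd.DataFrame(
        [
            {
                "x": "zm_response",
                "y": "au12_response",
                "r": res.r,
                "df": res.df,
                "p": res.pvalue,
                "ci_lower": res.ci95[0] if res.ci95 else np.nan,
                "ci_upper": res.ci95[1] if res.ci95 else np.nan,
                "n_obs": res.n_obs,
                "n_subjects": res.n_subjects,
                "n_boot": res.n_boot,
            }
        ]
    ).to_csv(out / "rmcorr.csv", index=False)

    lme = ConditionContrastModel(pairs, "au12_response")
    try:
        final, report = lme.fit_with_exclusion(cfg.exclusion)
        final.fixed_effects_table().to_csv(out / "fixed_effects.csv")
        final.simple_effects().to_csv(out / "simple_effects.csv")
        log.record(
            "associate",
            seed=cfg.seed,
            rmcorr_r=res.r,
            rmcorr_df=res.df,
            re_formula=final.re_formula,
            n_excluded_trials=len(report.excluded_trials),
            excluded_subjects=report.excluded_subjects,
            n_retained=report.n_retained,
        )
        artifacts["fixed_effects"] = out / "fixed_effects.csv"
        artifacts["simple_effects"] = out / "simple_effects.csv"
    except ModelFitError as exc:
        log.record("associate", seed=cfg.seed, rmcorr_r=res.r, rmcorr_df=res.df, error=str(exc))
    artifacts["rmcorr"] = out / "rmcorr.csv"


def _stage_xcorr(cfg: RunConfig, out: Path, log: RunLog, artifacts: dict) -> None:
    emg = pd.read_csv(out / "emg_preprocessed.csv")
    au = pd.read_csv(out / "au.csv")
    trials = trials_from_frames(
        emg, au,
        onset_index=cfg.design.onset_index,
        emg_rate_hz=cfg.design.emg_rate_hz,
        au_fps=cfg.design.au_fps,
        software_tag=cfg.software_tag,
    )
    series = []
    results, subjects, conditions = [], [], []
    n_excluded = {"zero_output": 0, "low_quality": 0}
    for tr in trials:
        masked, reason = apply_quality_mask(tr, cfg.quality)
        if masked is None:
            n_excluded[reason] += 1
            continue
        zm_frames = resample_emg_to_frames(
            tr.emg_zm, tr.emg_rate_hz, tr.onset_index,
            fps=tr.au_fps, n_frames=cfg.design.n_frames,
        )
        cond = f"{tr.emotion}_{tr.presentation}"
        series.append((cond, "zm", zm_frames))
        series.append((cond, "au12", masked.au12))
        if tr.emotion == "positive" and np.isfinite(masked.au12).all():
            res = cross_correlation(
                zm_frames, masked.au12,
                max_lag=cfg.xcorr.max_lag, fps=tr.au_fps,
                peak_search=cfg.xcorr.peak_search, method=cfg.xcorr.method,
            )
            if res.valid:
                results.append(res)
                subjects.append(tr.subject)
                conditions.append(cond)
    group_average_timeseries(series).to_csv(out / "group_timeseries.csv", index=False)
    groups = aggregate_xcorr(
        results, subjects, conditions, fps=cfg.design.au_fps, peak_search=cfg.xcorr.peak_search
    )
    rows = []
    peaks = {}
    for cond, g in groups.items():
        for lag, r in zip(g.lags, g.r_by_lag):
            rows.append({"condition": cond, "lag": int(lag), "r": r})
        peaks[cond] = {
            "peak_lags": list(g.peak_lags),
            "peak_r": g.peak_r,
            "latency_ms_range": list(g.latency_ms_range),
            "n_subjects": g.n_subjects,
            "n_trials": g.n_trials,
        }
    pd.DataFrame(rows).to_csv(out / "crosscorr.csv", index=False)
    with open(out / "xcorr_peaks.json", "w") as fh:
        json.dump(peaks, fh, default=_json_default)
    log.record("xcorr", n_excluded=n_excluded, peaks=peaks)
    artifacts["group_timeseries"] = out / "group_timeseries.csv"
    artifacts["crosscorr"] = out / "crosscorr.csv"
    artifacts["xcorr_peaks"] = out / "xcorr_peaks.json"


def _stage_report(cfg: RunConfig, out: Path, log: RunLog, artifacts: dict) -> None:
    summary: dict = {"seed": cfg.seed, "software_tag": cfg.software_tag}
    for name in ("detection_metrics", "rmcorr", "crosscorr"):
        p = out / f"{name}.csv"
        if p.exists():
            summary[name] = pd.read_csv(p).to_dict(orient="records")
    for name in ("zero_output", "xcorr_peaks"):
        p = out / f"{name}.json"
        if p.exists():
            summary[name] = json.loads(p.read_text())
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    log.record("report")
    artifacts["summary"] = out / "summary.json"


_RUNNERS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "responses": _stage_responses,
    "validate": _stage_validate,
    "associate": _stage_associate,
    "xcorr": _stage_xcorr,
    "report": _stage_report,
}
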