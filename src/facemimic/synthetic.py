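"""Synthetic session generator.

Generates cohorts of passive-viewing trials with the statistical structure the
downstream validation pipeline assumes: amplitude-modulated band-limited EMG
noise on ZM/CS, latency-shifted AU12/AU4 intensity series coupled to the same
latent mimicry strength, per-frame quality/confidence scores, and the software
pathologies observed in automated FACS output (whole-trial zero AU series,
positive drift, quality dips). No video or face-landmark synthesis is
performed: only the output characteristics of AU-estimation software are
emulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .design import (
    EMOTIONS,
    PRESENTATIONS,
    SOFTWARE_TAGS,
    DesignError,
    GroundTruthParams,
    SessionDesign,
)

__all__ = [
    "TrialRecording",
    "drive",
    "simulate_trial",
    "simulate_cohort",
    "enumerate_trials",
    "cohort_emg_frame",
    "cohort_au_frame",
    "write_cohort_csv",
]


@dataclass
class TrialRecording:
    """One trial's raw signals and labels.

    ``emg_zm``/``emg_cs`` include the pre-stimulus pad; ``onset_index`` marks
    stimulus onset. ``au12``/``au4``/``quality`` are frame-aligned series of
    length ``n_frames``.
    """

    subject: int
    trial: int
    emotion: str
    presentation: str
    emg_zm: np.ndarray
    emg_cs: np.ndarray
    au12: np.ndarray
    au4: np.ndarray
    quality: np.ndarray
    onset_index: int
    emg_rate_hz: float
    au_fps: float
    software_tag: str = "generic"


def drive(t, params: GroundTruthParams):
    """Normalized expression intensity at time ``t`` seconds after onset.

    Raised-cosine ramp: 0 for t <= ramp_start_s, 1 for t >= ramp_end_s, and a
    smooth monotone half-cosine in between (0.5 at the ramp midpoint).
    Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    x = np.clip((t - params.ramp_start_s) / (params.ramp_end_s - params.ramp_start_s), 0.0, 1.0)
    out = 0.5 - 0.5 * np.cos(np.pi * x)
    return float(out) if out.ndim == 0 else out


def _carrier_band(rate_hz: float) -> tuple[float, float]:
    # Surface-EMG spectral band, kept below Nyquist for reduced-rate designs.
    return 20.0, min(450.0, 0.45 * rate_hz)


def _bandlimited_noise(rng: np.random.Generator, n: int, rate_hz: float) -> np.ndarray:
    """Unit-SD Gaussian noise band-passed to the surface-EMG band."""
    lo, hi = _carrier_band(rate_hz)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate_hz, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _smooth_au_noise(noise: np.ndarray, params: GroundTruthParams) -> np.ndarray:
    if params.au_smoothing == "exp":
        a = params.au_exp_smoothing_alpha
        out = np.empty_like(noise)
        acc = 0.0
        for i, v in enumerate(noise):
            acc = a * v + (1.0 - a) * acc
            out[i] = acc
        return out
    # default: 3-frame moving average
    kernel = np.ones(3) / 3.0
    return np.convolve(noise, kernel, mode="same")


def latent_strengths(
    params: GroundTruthParams,
    emotion: str,
    presentation: str,
    rng: np.random.Generator,
    subject_effects: tuple[float, float] = (0.0, 0.0),
) -> tuple[float, float]:
    """Draw the (ZM/AU12, CS/AU4) latent mimicry strengths for one trial."""
    u0, u1 = subject_effects
    positive = emotion == "positive"
    fixed_zm = 0.0
    if positive:
        fixed_zm = params.zm_gain_pos_video * (
            params.live_amplification if presentation == "live" else 1.0
        )
    s_zm = fixed_zm + params.zm_gain_pos_video * (
        u0 + (u1 if positive else 0.0) + rng.normal(0.0, params.trial_gain_sd)
    )
    s_cs = params.cs_gain_neg * (
        (1.0 if emotion == "negative" else 0.0) + rng.normal(0.0, params.trial_gain_sd)
    )
    return s_zm, s_cs


def simulate_trial(
    design: SessionDesign,
    params: GroundTruthParams,
    emotion: str,
    presentation: str,
    rng: np.random.Generator,
    software_tag: str = "generic",
    subject_effects: tuple[float, float] = (0.0, 0.0),
    subject: int = 0,
    trial: int = 0,
) -> TrialRecording:
    """Simulate one trial's EMG channels, AU series and quality scores.

    The EMG channels are zero-mean band-limited noise whose instantaneous SD
    is ``emg_baseline_sd * max(1 + s * drive(t), 0.05)`` with the latent
    strength ``s`` shared between the EMG channel and its paired AU series, so
    trial-wise EMG and AU responses are correlated within subject. AU series
    are latency-shifted drives scaled by ``au_scale * s`` plus drift and
    smoothed frame noise. ``openface_like`` trials are replaced by a
    whole-trial zero AU12 series with probability ``p_zero_output``.
    """
    if emotion not in EMOTIONS:
        raise DesignError(f"unknown emotion label {emotion!r}")
    if presentation not in PRESENTATIONS:
        raise DesignError(f"unknown presentation label {presentation!r}")
    if software_tag not in SOFTWARE_TAGS:
        raise DesignError(f"unknown software_tag {software_tag!r}")
    params.validate_against(design)

    n = design.n_emg_samples
    onset = design.onset_index
    rate = design.emg_rate_hz
    t = (np.arange(n) - onset) / rate  # seconds relative to onset; pad < 0
    d_emg = drive(np.maximum(t, 0.0), params)

    s_zm, s_cs = latent_strengths(params, emotion, presentation, rng, subject_effects)

    def channel(s: float) -> np.ndarray:
        sd_factor = np.maximum(1.0 + s * d_emg, 0.05)
        return _bandlimited_noise(rng, n, rate) * params.emg_baseline_sd * sd_factor

    emg_zm = channel(s_zm)
    emg_cs = channel(s_cs)

    frames = np.arange(design.n_frames)
    t_frames = frames / design.au_fps
    d_au = drive(t_frames - params.au_latency_frames / design.au_fps, params)

    def au_series(s: float) -> np.ndarray:
        noise = _smooth_au_noise(rng.normal(0.0, params.au_noise_sd, design.n_frames), params)
        return params.au_scale * s * d_au + params.au_drift_per_frame * frames + noise

    au12 = au_series(s_zm)
    au4 = au_series(s_cs)

    quality = np.clip(1.0 - np.abs(rng.normal(0.0, 0.02, design.n_frames)), 0.0, 1.0)
    dips = rng.random(design.n_frames) < params.p_lowquality_frame
    if dips.any():
        quality[dips] = rng.uniform(0.2, 0.55, int(dips.sum()))

    if software_tag == "openface_like" and rng.random() < params.p_zero_output:
        au12 = np.zeros(design.n_frames)

    return TrialRecording(
        subject=subject,
        trial=trial,
        emotion=emotion,
        presentation=presentation,
        emg_zm=emg_zm,
        emg_cs=emg_cs,
        au12=au12,
        au4=au4,
        quality=quality,
        onset_index=onset,
        emg_rate_hz=rate,
        au_fps=design.au_fps,
        software_tag=software_tag,
    )


def enumerate_trials(
    design: SessionDesign,
    exclude_live_mishaps: bool = False,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Trial manifest: subject, trial, emotion, presentation.

    Condition order is pseudo-randomized per subject when an ``rng`` is given,
    deterministic (cycled) otherwise. With ``exclude_live_mishaps`` the
    manifest drops one positive-live trial for each of the first two subjects
    and one negative-live trial for each of the next two, emulating live
    performances excluded after visual inspection (3000 -> 2996 at defaults).
    """
    rows = []
    for subj in range(design.n_subjects):
        cells = [c for c in design.conditions for _ in range(design.trials_per_condition)]
        if rng is not None:
            order = rng.permutation(len(cells))
            cells = [cells[i] for i in order]
        for i, (emotion, presentation) in enumerate(cells):
            rows.append((subj, i, emotion, presentation))
    df = pd.DataFrame(rows, columns=["subject", "trial", "emotion", "presentation"])

    if exclude_live_mishaps:
        if design.n_subjects < 4:
            raise DesignError("live-mishap exclusion needs at least 4 subjects")
        drop_idx = []
        for subj, emotion in ((0, "positive"), (1, "positive"), (2, "negative"), (3, "negative")):
            m = (
                (df["subject"] == subj)
                & (df["emotion"] == emotion)
                & (df["presentation"] == "live")
            )
            drop_idx.append(df.index[m][-1])
        df = df.drop(index=drop_idx).reset_index(drop=True)
    return df


def simulate_cohort(
    design: SessionDesign,
    params: GroundTruthParams,
    software_tag: str = "generic",
    exclude_live_mishaps: bool = False,
    seed: int | None = None,
) -> list[TrialRecording]:
    """Simulate a full cohort of trials.

    Subject-level random effects (intercept + emotion slope on the gain
    scale) are drawn once per subject so mixed-model recovery is testable.
    Deterministic given ``seed`` (defaults to ``params.seed``).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    u0 = rng.normal(0.0, params.re_intercept_sd, design.n_subjects)
    u1 = rng.normal(0.0, params.re_emotion_slope_sd, design.n_subjects)
    manifest = enumerate_trials(design, exclude_live_mishaps=exclude_live_mishaps, rng=rng)
    trials = []
    for row in manifest.itertuples(index=False):
        trials.append(
            simulate_trial(
                design,
                params,
                row.emotion,
                row.presentation,
                rng,
                software_tag=software_tag,
                subject_effects=(u0[row.subject], u1[row.subject]),
                subject=row.subject,
                trial=row.trial,
            )
        )
    return trials


def cohort_emg_frame(trials: list[TrialRecording]) -> pd.DataFrame:
    """Long-format EMG table: subject, trial, emotion, presentation, sample_index, zm, cs."""
    parts = []
    for tr in trials:
        n = len(tr.emg_zm)
        parts.append(
            pd.DataFrame(
                {
                    "subject": tr.subject,
                    "trial": tr.trial,
                    "emotion": tr.emotion,
                    "presentation": tr.presentation,
                    "sample_index": np.arange(n),
                    "zm": tr.emg_zm,
                    "cs": tr.emg_cs,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def cohort_au_frame(trials: list[TrialRecording]) -> pd.DataFrame:
    """Long-format AU table: subject, trial, emotion, presentation, frame, au12, au4, quality."""
    parts = []
    for tr in trials:
        parts.append(
            pd.DataFrame(
                {
                    "subject": tr.subject,
                    "trial": tr.trial,
                    "emotion": tr.emotion,
                    "presentation": tr.presentation,
                    "frame": np.arange(len(tr.au12)),
                    "au12": tr.au12,
                    "au4": tr.au4,
                    "quality": tr.quality,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_cohort_csv(trials: list[TrialRecording], emg_path, au_path) -> None:
    """Write the two long-format CSV files defined by the pipeline contract."""
    cohort_emg_frame(trials).to_csv(emg_path, index=False)
    cohort_au_frame(trials).to_csv(au_path, index=False)


def trials_from_frames(
    emg: pd.DataFrame,
    au: pd.DataFrame,
    onset_index: int,
    emg_rate_hz: float,
    au_fps: float,
    software_tag: str = "generic",
) -> list[TrialRecording]:
    """Rebuild TrialRecording objects from the long-format CSV tables."""
    keys = ["subject", "trial"]
    au_groups = {k: g for k, g in au.groupby(keys, sort=False)}
    out = []
    for k, g in emg.groupby(keys, sort=False):
        ga = au_groups[k]
        g = g.sort_values("sample_index")
        ga = ga.sort_values("frame")
        out.append(
            TrialRecording(
                subject=k[0],
                trial=k[1],
                emotion=g["emotion"].iloc[0],
                presentation=g["presentation"].iloc[0],
                emg_zm=g["zm"].to_numpy(float),
                emg_cs=g["cs"].to_numpy(float),
                au12=ga["au12"].to_numpy(float),
                au4=ga["au4"].to_numpy(float),
                quality=ga["quality"].to_numpy(float),
                onset_index=onset_index,
                emg_rate_hz=emg_rate_hz,
                au_fps=au_fps,
                software_tag=software_tag,
            )
        )
    return out
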