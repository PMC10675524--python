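"""Trial-wise response extraction and mimicry detection metrics.

The trial response is the mean signal over the maximal expression phase
(2.5-3.0 s after onset) minus the mean over the neutral phase (0-1 s).
Mimicry detection treats the sign of the EMG response as ground truth and the
sign of the paired AU response as the automated prediction; a response of
exactly zero is grouped with negative ("null or negative" counts as
non-response).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import PreprocParams, preprocess_trace
from .synthetic import TrialRecording

LABELS = ("TP", "FP", "TN", "FN")


@dataclass(frozen=True)
class ResponseWindows:
    """Half-open [start, end) windows in seconds after stimulus onset."""

    neutral_s: tuple[float, float] = (0.0, 1.0)
    maximal_s: tuple[float, float] = (2.5, 3.0)

    def __post_init__(self) -> None:
        n, m = self.neutral_s, self.maximal_s
        if not (n[0] < n[1] and m[0] < m[1]):
            raise ValueError("response windows must be ordered (start < end)")
        if n[1] > m[0] and m[1] > n[0]:
            raise ValueError("neutral and maximal windows must be disjoint")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class DetectionMetrics:
    """Derived detection metrics; undefined ratios are carried as NaN."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float


def _window_mask(n: int, rate: float, window: tuple[float, float], onset_index: int) -> np.ndarray:
    i = np.arange(n)
    t = (i - onset_index) / rate
    return (t >= window[0]) & (t < window[1])


def trial_response(
    series: np.ndarray,
    rate: float,
    windows: ResponseWindows | None = None,
    onset_index: int = 0,
) -> float:
    """Maximal-window mean minus neutral-window mean.

    Sample ``i`` belongs to a window when its onset-relative time
    ``(i - onset_index) / rate`` lies in the half-open interval [start, end).
    Works for EMG samples (rate in Hz) and AU frames (rate = fps) alike.
    """
    windows = windows if windows is not None else ResponseWindows()
    x = np.asarray(series, dtype=float)
    m_neutral = _window_mask(len(x), rate, windows.neutral_s, onset_index)
    m_maximal = _window_mask(len(x), rate, windows.maximal_s, onset_index)
    if not m_neutral.any() or not m_maximal.any():
        raise ValueError("response window falls outside the series")
    return float(np.nanmean(x[m_maximal]) - np.nanmean(x[m_neutral]))


def response_pairs(
    trials: list[TrialRecording],
    preproc: PreprocParams | None = None,
    windows: ResponseWindows | None = None,
) -> pd.DataFrame:
    """Trial-wise response table for a cohort.

    Preprocesses both EMG channels and extracts the four responses per trial.
    ``emg_response``/``au_response`` hold the condition-congruent pair
    (ZM/AU12 in positive trials, CS/AU4 in negative trials). ``exclude_reason``
    is one of none / zero_output / artifact.
    """
    windows = windows if windows is not None else ResponseWindows()
    rows = []
    for tr in trials:
        if preproc is None:
            pp = PreprocParams.for_rate(tr.emg_rate_hz)
        else:
            pp = preproc
        zm = preprocess_trace(tr.emg_zm, tr.onset_index, tr.emg_rate_hz, pp, channel="ZM")
        cs = preprocess_trace(tr.emg_cs, tr.onset_index, tr.emg_rate_hz, pp, channel="CS")
        zm_resp = trial_response(zm.amplitude, tr.emg_rate_hz, windows, tr.onset_index)
        cs_resp = trial_response(cs.amplitude, tr.emg_rate_hz, windows, tr.onset_index)
        au12_resp = trial_response(tr.au12, tr.au_fps, windows)
        au4_resp = trial_response(tr.au4, tr.au_fps, windows)
        zero_output = bool(np.all(tr.au12 == 0.0))
        artifact = zm.artifact_flag or cs.artifact_flag
        positive = tr.emotion == "positive"
        reason = "zero_output" if zero_output else ("artifact" if artifact else "none")
        rows.append(
            {
                "subject": tr.subject,
                "trial": tr.trial,
                "emotion": tr.emotion,
                "presentation": tr.presentation,
                "software_tag": tr.software_tag,
                "zm_response": zm_resp,
                "cs_response": cs_resp,
                "au12_response": au12_resp,
                "au4_response": au4_resp,
                "emg_response": zm_resp if positive else cs_resp,
                "au_response": au12_resp if positive else au4_resp,
                "zero_output": zero_output,
                "artifact": artifact,
                "exclude_reason": reason,
            }
        )
    return pd.DataFrame(rows)


def sign_congruence_accuracy(
    pairs: pd.DataFrame,
    emg_col: str = "emg_response",
    au_col: str = "au_response",
    include_zero_output: bool = False,
) -> float:
    """Proportion of AU responses with the same sign as the EMG response.

    Zero responses count as negative. Excluded trials (zero-output AU series,
    flagged artifacts) are omitted from the denominator unless
    ``include_zero_output`` keeps zero-output trials in.
    """
    df = pairs
    if "exclude_reason" in df.columns:
        keep = df["exclude_reason"] == "none"
        if include_zero_output:
            keep |= df["exclude_reason"] == "zero_output"
        df = df[keep]
    if len(df) == 0:
        raise ValueError("no trials remain after exclusion")
    emg_pos = df[emg_col].to_numpy(float) > 0
    au_pos = df[au_col].to_numpy(float) > 0
    return float(np.mean(emg_pos == au_pos))


def classify_mimicry_trial(
    au12_resp: float,
    au4_resp: float | None,
    zm_resp: float,
    cs_resp: float | None,
    mode: str = "single_channel",
) -> str:
    """Confusion label for one positive-condition trial.

    Ground truth (muscular mimicry): ZM contraction alone in single_channel
    mode; ZM contraction with CS relaxation (cs <= 0) in compound mode.
    Prediction mirrors the same rule on AU12/AU4. Combinations the compound
    taxonomy leaves uncovered (e.g. both AU responses positive) count as
    non-detection.
    """
    if mode == "single_channel":
        truth = zm_resp > 0
        pred = au12_resp > 0
    elif mode == "compound":
        if au4_resp is None or cs_resp is None:
            raise ValueError("compound mode requires AU4 and CS responses")
        truth = (zm_resp > 0) and (cs_resp <= 0)
        pred = (au12_resp > 0) and (au4_resp <= 0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if truth:
        return "TP" if pred else "FN"
    return "FP" if pred else "TN"


def mimicry_confusion(
    pairs: pd.DataFrame,
    mode: str = "single_channel",
    au_channel: str = "au12",
    include_zero_output: bool = False,
) -> ConfusionCounts:
    """Tally the confusion matrix over condition-congruent trials.

    AU12 mimicry is assessed on positive-condition trials against ZM;
    the AU4 analogue uses negative-condition trials against CS (contraction
    of the context-congruent muscle as ground truth).
    """
    if au_channel not in ("au12", "au4"):
        raise ValueError("au_channel must be 'au12' or 'au4'")
    emotion = "positive" if au_channel == "au12" else "negative"
    df = pairs[pairs["emotion"] == emotion]
    if "exclude_reason" in df.columns:
        keep = df["exclude_reason"] == "none"
        if include_zero_output:
            keep |= df["exclude_reason"] == "zero_output"
        df = df[keep]
    counts = {k: 0 for k in LABELS}
    for row in df.itertuples(index=False):
        if au_channel == "au12":
            label = classify_mimicry_trial(
                row.au12_response, row.au4_response, row.zm_response, row.cs_response, mode
            )
        else:
            # mirrored channel pairing: AU4 vs CS, with AU12/ZM as the antagonists
            label = classify_mimicry_trial(
                row.au4_response, row.au12_response, row.cs_response, row.zm_response, mode
            )
        counts[label] += 1
    return ConfusionCounts(tp=counts["TP"], fp=counts["FP"], tn=counts["TN"], fn=counts["FN"])


def detection_metrics(counts: ConfusionCounts) -> DetectionMetrics:
    """Sensitivity, specificity, PPV, NPV and F1 from confusion counts."""

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return DetectionMetrics(
        sensitivity=ratio(counts.tp, counts.tp + counts.fn),
        specificity=ratio(counts.tn, counts.tn + counts.fp),
        ppv=ratio(counts.tp, counts.tp + counts.fp),
        npv=ratio(counts.tn, counts.tn + counts.fn),
        f1=ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn),
    )


def zero_output_report(trials: list[TrialRecording]) -> tuple[int, int, float]:
    """Count trials whose whole AU12 series is exactly zero.

    Returns (n_zero, n_total, proportion) with the proportion rounded to
    3 significant figures for display (e.g. 1360 of 2996 -> 0.454).
    """
    n_total = len(trials)
    n_zero = sum(bool(np.all(tr.au12 == 0.0)) for tr in trials)
    if n_total == 0:
        return 0, 0, 0.0
    proportion = float(f"{n_zero / n_total:.3g}")
    return n_zero, n_total, proportion
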