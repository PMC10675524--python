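"""Study design and generator ground-truth parameters.

The session layout mirrors a passive-viewing facial-mimicry experiment with a
2 x 2 within-subject design: emotion (positive vs. negative expression) crossed
with presentation (live performance vs. prerecorded video). Each trial lasts
3 s (neutral face, sigmoidal ramp, sustained maximal expression), with surface
EMG of the zygomaticus major (ZM) and corrugator supercilii (CS) sampled at
1000 Hz and automated action-unit (AU12/AU4) intensity estimates at the video
frame rate of 29.97 fps (90 frames per trial).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

EMOTIONS = ("positive", "negative")
PRESENTATIONS = ("live", "video")
SOFTWARE_TAGS = ("generic", "facereader_like", "pyfeat_like", "openface_like")


class DesignError(ValueError):
    """Raised when a design or parameter invariant is violated."""


@dataclass(frozen=True)
class SessionDesign:
    """Sampling layout of one recording session.

    Parameters
    ----------
    n_subjects : int
        Number of participants in the cohort.
    trials_per_condition : int
        Passive-viewing trials per condition cell (4 cells).
    trial_duration_s : float
        Post-onset trial length in seconds.
    prestimulus_pad_s : float
        Pre-onset EMG padding; must cover the 3 s baseline window.
    emg_rate_hz : float
        EMG sampling rate in Hz.
    au_fps : float
        Video frame rate for AU estimation.
    """

    n_subjects: int = 50
    trials_per_condition: int = 15
    trial_duration_s: float = 3.0
    prestimulus_pad_s: float = 3.0
    emg_rate_hz: float = 1000.0
    au_fps: float = 29.97

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_condition < 1:
            raise DesignError("n_subjects and trials_per_condition must be >= 1")
        if self.trial_duration_s <= 0 or self.emg_rate_hz <= 0 or self.au_fps <= 0:
            raise DesignError("durations and rates must be positive")
        if self.prestimulus_pad_s < 3.0:
            raise DesignError(
                "prestimulus_pad_s must be >= 3 s to cover the baseline window"
            )

    @property
    def n_frames(self) -> int:
        """AU frames per trial: floor(duration * fps + 0.5); 90 at defaults."""
        return int(math.floor(self.trial_duration_s * self.au_fps + 0.5))

    @property
    def conditions(self) -> tuple[tuple[str, str], ...]:
        """All (emotion, presentation) cells."""
        return tuple(product(EMOTIONS, PRESENTATIONS))

    @property
    def n_trials(self) -> int:
        """Total trial count before any exclusion."""
        return self.n_subjects * len(self.conditions) * self.trials_per_condition

    @property
    def n_emg_samples(self) -> int:
        """EMG samples per trial, pre-stimulus pad included."""
        return int(round((self.prestimulus_pad_s + self.trial_duration_s) * self.emg_rate_hz))

    @property
    def onset_index(self) -> int:
        """0-based sample index of stimulus onset within the EMG trace."""
        return int(round(self.prestimulus_pad_s * self.emg_rate_hz))


@dataclass(frozen=True)
class GroundTruthParams:
    """Ground truth of the synthetic generator.

    The latent per-trial mimicry strength for the ZM/AU12 pair is

        s = g(e, p) + zm_gain_pos_video * (u0 + u1*[positive] + eps_trial)

    where the fixed gain g(e, p) is ``zm_gain_pos_video`` in positive trials
    (multiplied by ``live_amplification`` when live) and 0 in negative trials;
    u0, u1 are subject random effects (intercept / emotion slope) and
    eps_trial is trial-level noise, all expressed relative to the reference
    gain so that a fully null generator (gain 0) produces exactly null latent
    strength. The CS/AU4 pair uses ``cs_gain_neg`` with its own trial noise.

    EMG channels are band-limited Gaussian noise whose instantaneous SD is
    ``emg_baseline_sd * (1 + s * drive(t))``; AU series are
    ``au_scale * s * drive(t - latency)`` plus drift and smoothed frame noise.

    Random-effect SDs default to 50% of the corresponding fixed effect (the
    emotion effect on the gain scale), stated explicitly here because the
    underlying study reports no variance components.
    """

    zm_gain_pos_video: float = 1.0
    live_amplification: float = 1.5
    cs_gain_neg: float = 1.0
    au_scale: float = 0.5
    au_latency_frames: int = 5
    au_noise_sd: float = 0.05
    au_drift_per_frame: float = 0.0
    emg_baseline_sd: float = 1.0
    p_zero_output: float = 0.454
    p_lowquality_frame: float = 0.001
    ramp_start_s: float = 1.0
    ramp_end_s: float = 2.5
    re_intercept_sd: float = 0.5
    re_emotion_slope_sd: float = 0.5
    trial_gain_sd: float = 0.5
    au_smoothing: str = "ma3"  # "ma3" (3-frame moving average) or "exp"
    au_exp_smoothing_alpha: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_zero_output", "p_lowquality_frame"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DesignError(f"{name} must lie in [0, 1]; got {v}")
        if not self.ramp_start_s < self.ramp_end_s:
            raise DesignError("ramp_start_s must be < ramp_end_s")
        if self.live_amplification < 0:
            raise DesignError("live_amplification must be >= 0")
        if self.au_latency_frames < 0:
            raise DesignError("au_latency_frames must be >= 0")
        if self.au_smoothing not in ("ma3", "exp"):
            raise DesignError("au_smoothing must be 'ma3' or 'exp'")

    def validate_against(self, design: SessionDesign) -> None:
        if self.ramp_end_s > design.trial_duration_s:
            raise DesignError("ramp_end_s must be <= trial_duration_s")


def openface_like_params(base: GroundTruthParams | None = None) -> GroundTruthParams:
    """Preset emulating OpenFace-style output pathologies.

    Whole-trial zero AU12 output at the observed 45.4% rate (applied only to
    ``openface_like`` trials) and a positive per-frame intensity drift.
    """
    from dataclasses import replace

    base = base if base is not None else GroundTruthParams()
    return replace(base, p_zero_output=0.454, au_drift_per_frame=0.001)


def facereader_like_params(base: GroundTruthParams | None = None) -> GroundTruthParams:
    """Preset emulating FaceReader-style heavily smoothed AU series."""
    from dataclasses import replace

    base = base if base is not None else GroundTruthParams()
    return replace(base, p_zero_output=0.0, au_smoothing="exp", au_exp_smoothing_alpha=0.2)
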