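"""Study configuration: generative model, cleaning pipeline and power-simulation
constants.

Three frozen-default dataclasses hold every tunable of the package:

* :class:`GenerativeParams` — the synthetic study generator (fixed effects in mm,
  variance components, pupil-response shape, blink/sampling process, feedback rules).
* :class:`PipelineConfig` — the trace-cleaning chain (QC thresholds, blink margins,
  resampling rate, smoothing width, baseline and analysis windows).
* :class:`PowerConfig` — the simulation-based power analysis for the 2x2
  within-subject peak-pupil-dilation design.

:func:`load_config` reads a YAML file with optional ``generative`` / ``pipeline`` /
``power`` sections; unknown keys are rejected so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "GenerativeParams",
    "PipelineConfig",
    "PowerConfig",
    "StudyConfig",
    "ConfigError",
    "load_config",
]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a configuration file."""


# 2x2 fixed effects under treatment coding: (intercept, load, copresence,
# load x copresence). Reference cell is single-sentence load with distractor
# copresence, so the load coefficient is the change from single- to
# dual-sentence load.
Effects4 = tuple[float, float, float, float]


@dataclass(frozen=True)
class GenerativeParams:
    """Constants of the synthetic-study generator.

    The defaults encode the published study conditions: 30 trials per condition,
    sentences of 1.2-2.0 s with 4-9 words, a ~90 Hz eye tracker with frame-rate
    jitter, a dilation response peaking 2.5-3 s after sentence onset, agent
    feedback shown with 15% probability (80% negative after errors in the
    single-sentence condition) capped at 3 negative / 5 positive animations per
    agent per condition, and fixed effects equal to the reported baseline pupil
    size (BPS), peak pupil dilation (PPD) and subjective-rating estimates.
    Variance components are calibration defaults chosen so simulated 95% CIs
    approximate the reported CI widths; they are not published values.
    """

    # Fixed effects, mm. BPS is the pre-onset tonic level; amp is the amplitude
    # of the evoked dilation pulse whose unit peak makes it interpretable as PPD.
    bps_effects_mm: Effects4 = (4.52, 0.32, 0.07, -0.08)
    amp_effects_mm: Effects4 = (0.29, 0.18, -0.02, -0.01)
    # Variance components, mm (calibrated, see docs/methods.md).
    tau_bps_mm: float = 0.8
    sigma_bps_mm: float = 0.45
    tau_amp_mm: float = 0.18
    sigma_amp_mm: float = 0.14
    # Measurement noise added to every sample, mm.
    sample_noise_mm: float = 0.02

    # Response shape: gamma-density pulse, zero before sentence onset, unit peak
    # at t_peak.
    t_peak_s: float = 2.75
    pulse_shape: float = 4.0

    # Blink process: Poisson onsets, lognormal durations; marks equal the blink
    # interval.
    blink_rate_hz: float = 0.25
    blink_mean_dur_s: float = 0.20
    blink_sigma_log: float = 0.40

    # Sampling: nominal HMD frame rate with jitter on the frame interval.
    sample_rate_hz: float = 90.0
    jitter_sd_s: float = 0.001

    # Trial plan.
    trials_per_condition: int = 30
    sentence_dur_range_s: tuple[float, float] = (1.2, 2.0)
    words_range: tuple[int, int] = (4, 9)

    # Word-repetition accuracy (per-word Bernoulli means).
    p_word_single: float = 0.97
    p_word_dual_left: float = 0.80
    p_word_dual_right: float = 0.53

    # Agent feedback.
    p_feedback: float = 0.15
    p_negative_after_error_single: float = 0.80
    cap_negative: int = 3
    cap_positive: int = 5

    # Subjective ratings: (intercept, load, copresence, interaction) on the
    # 1-10 visual-analogue scale, plus shared variance components.
    effort_effects: Effects4 = (5.13, 2.88, -0.13, 0.18)
    performance_effects: Effects4 = (8.50, -3.49, -0.26, 0.52)
    engagement_effects: Effects4 = (6.83, 0.36, 0.45, -0.50)
    difficulty_effects: Effects4 = (3.95, 3.93, 0.18, -0.20)
    rating_tau: float = 1.0
    rating_sigma: float = 1.0
    round_ratings: bool = False

    # Questionnaire summaries.
    ipq_mean: float = 41.1
    ipq_sd: float = 8.4
    agent_presence_mean: float = 4.3
    agent_presence_sd: float = 1.1
    agent_valence_mean: float = 3.9
    agent_valence_sd: float = 0.9

    def __post_init__(self) -> None:
        for name in ("tau_bps_mm", "sigma_bps_mm", "tau_amp_mm", "sigma_amp_mm",
                     "sample_noise_mm", "blink_rate_hz", "blink_mean_dur_s",
                     "jitter_sd_s", "rating_tau", "rating_sigma"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and >= 0, got {v!r}")
        for name in ("p_feedback", "p_negative_after_error_single",
                     "p_word_single", "p_word_dual_left", "p_word_dual_right"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {v!r}")
        if not 2.5 <= self.t_peak_s <= 3.0:
            raise ConfigError(
                f"t_peak_s must lie in [2.5, 3.0] s (observed peak latency), "
                f"got {self.t_peak_s!r}")
        if self.pulse_shape <= 0 or self.sample_rate_hz <= 0:
            raise ConfigError("pulse_shape and sample_rate_hz must be positive")
        if self.trials_per_condition < 1:
            raise ConfigError("trials_per_condition must be >= 1")
        lo, hi = self.sentence_dur_range_s
        if not (0 < lo <= hi):
            raise ConfigError(f"invalid sentence_dur_range_s {self.sentence_dur_range_s!r}")
        wlo, whi = self.words_range
        if not (1 <= wlo <= whi):
            raise ConfigError(f"invalid words_range {self.words_range!r}")
        if self.cap_negative < 0 or self.cap_positive < 0:
            raise ConfigError("feedback caps must be >= 0")


@dataclass(frozen=True)
class PipelineConfig:
    """Constants of the trace-cleaning chain.

    Traces with more than ``qc_marked_fraction`` eye-closed samples are removed;
    a participant x condition cell with ``condition_min_bad`` or more removed
    traces is dropped entirely. Blink marks are widened by ``blink_pre_ms`` /
    ``blink_post_ms`` to catch eyelid artifacts, traces are regridded to
    ``resample_hz``, gaps linearly interpolated, baseline-corrected against the
    mean over ``baseline_window_s`` (the last second of masker noise), smoothed
    with a ``smooth_points``-point moving average, the first ``drop_first_n``
    trials of each condition discarded, and the result cropped to the
    ``analysis_window_s`` (masker lead + shortest sentence + masker tail).
    """

    qc_marked_fraction: float = 0.20
    condition_min_bad: int = 6
    blink_pre_ms: float = 83.0
    blink_post_ms: float = 133.0
    resample_hz: float = 60.0
    smooth_points: int = 11
    baseline_window_s: tuple[float, float] = (-1.0, 0.0)
    drop_first_n: int = 4
    masker_lead_s: float = 3.0
    shortest_sentence_s: float = 1.2
    masker_tail_s: float = 3.0

    @property
    def analysis_window_s(self) -> float:
        """Total analysed window: masker lead + shortest sentence + tail."""
        return self.masker_lead_s + self.shortest_sentence_s + self.masker_tail_s

    @property
    def window_start_s(self) -> float:
        return -self.masker_lead_s

    @property
    def window_end_s(self) -> float:
        return self.window_start_s + self.analysis_window_s

    def __post_init__(self) -> None:
        if not 0.0 < self.qc_marked_fraction <= 1.0:
            raise ConfigError("qc_marked_fraction must be in (0, 1]")
        if self.condition_min_bad < 1:
            raise ConfigError("condition_min_bad must be >= 1")
        if self.blink_pre_ms < 0 or self.blink_post_ms < 0:
            raise ConfigError("blink margins must be >= 0")
        if self.resample_hz <= 0:
            raise ConfigError("resample_hz must be positive")
        if self.smooth_points < 1:
            raise ConfigError("smooth_points must be >= 1")
        if self.smooth_points % 2 == 0:
            raise ConfigError("smooth_points must be odd (centered window)")
        if self.drop_first_n < 0:
            raise ConfigError("drop_first_n must be >= 0")
        b0, b1 = self.baseline_window_s
        if not (self.window_start_s <= b0 < b1 <= self.window_end_s):
            raise ConfigError("baseline window must lie inside the analysis window")


@dataclass(frozen=True)
class PowerConfig:
    """Simulation-based power analysis for the 2x2 PPD design.

    Condition-level PPD is simulated from a random-intercept model with a
    strong load effect (0.20 mm) and a weak copresence effect (0.025 mm), no
    interaction, and variance components calibrated to the reported CI widths;
    the trial residual shrinks by ``sqrt(n_trials_averaged)`` because PPD is
    read off a per-condition mean trace.
    """

    effect_load_mm: float = 0.20
    effect_copresence_mm: float = 0.025
    intercept_mm: float = 0.29
    alpha: float = 0.05
    target_power: float = 0.80
    n_grid: tuple[int, ...] = (6, 8, 10, 12, 14, 16, 20, 26, 33)
    replicates: int = 200
    tau_mm: float = 0.18
    sigma_trial_mm: float = 0.14
    n_trials_averaged: int = 26

    @property
    def sigma_condition_mm(self) -> float:
        """Residual SD of a condition-level PPD (mean of n_trials_averaged trials)."""
        return self.sigma_trial_mm / math.sqrt(self.n_trials_averaged)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if not 0.0 < self.target_power < 1.0:
            raise ConfigError("target_power must be in (0, 1)")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if any(n < 2 for n in self.n_grid):
            raise ConfigError("every n in n_grid must be >= 2")
        if self.tau_mm < 0 or self.sigma_trial_mm <= 0:
            raise ConfigError("variance components must be non-negative (sigma > 0)")
        if self.n_trials_averaged < 1:
            raise ConfigError("n_trials_averaged must be >= 1")


@dataclass(frozen=True)
class StudyConfig:
    """Bundle of the three configuration blocks."""

    generative: GenerativeParams = field(default_factory=GenerativeParams)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    power: PowerConfig = field(default_factory=PowerConfig)


def _build(cls, section: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{name}' section: {sorted(unknown)}; "
            f"valid keys: {sorted(valid)}")
    coerced = {}
    for key, value in section.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    return cls(**coerced)


def load_config(path: str | Path | None = None) -> StudyConfig:
    """Load a YAML configuration; every omitted key keeps its study default.

    Parameters
    ----------
    path
        YAML file with optional top-level sections ``generative``, ``pipeline``
        and ``power``. ``None`` or an empty file yields the full default set.

    Raises
    ------
    ConfigError
        On unknown sections/keys or invalid values.
    """
    if path is None:
        return StudyConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - {"generative", "pipeline", "power"}
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    return StudyConfig(
        generative=_build(GenerativeParams, raw.get("generative", {}) or {}, "generative"),
        pipeline=_build(PipelineConfig, raw.get("pipeline", {}) or {}, "pipeline"),
        power=_build(PowerConfig, raw.get("power", {}) or {}, "power"),
    )
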