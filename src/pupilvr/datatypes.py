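"""Domain types shared by every pipeline stage.

Time convention (global): ``t_s`` is seconds relative to target-sentence onset.
The masker starts at -3.0 s; the analysed window is [-3.0, +4.2] s (7.2 s). All
pupil quantities are millimetres. Only the right eye is modelled; the ``eye``
column exists for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

__all__ = [
    "LOADS",
    "COPRESENCES",
    "CONDITIONS",
    "FEEDBACK_LEVELS",
    "ValidationError",
    "PupilSample",
    "PupilTrace",
    "CleanTrace",
    "TrialScore",
    "ParticipantCovariates",
    "ConditionSummary",
    "FeedbackBin",
    "EffectEstimate",
    "LRTResult",
    "CorrelationResult",
    "Study",
    "make_trial_uid",
]

LOADS = ("single", "dual")
COPRESENCES = ("distractors", "agents")
CONDITIONS = tuple((ld, cp) for ld in LOADS for cp in COPRESENCES)
FEEDBACK_LEVELS = ("none", "positive", "negative")
RATING_NAMES = ("effort", "performance", "engagement", "difficulty")


class ValidationError(ValueError):
    """Raised when input data violate a schema invariant."""


class PupilSample(NamedTuple):
    """One eye-tracker sample: time (s, sentence onset = 0), diameter (mm),
    eye-closed mark. Diameter may be NaN only while marked."""

    t_s: float
    diameter_mm: float
    marked: bool


def make_trial_uid(participant_id: str, load: str, copresence: str, trial_index: int) -> str:
    return f"{participant_id}:{load}:{copresence}:{trial_index:02d}"


@dataclass
class PupilTrace:
    """One trial's irregularly sampled right-eye pupil trace plus metadata."""

    participant_id: str
    trial_index: int
    load: str
    copresence: str
    sent_dur_left_s: float
    sent_dur_right_s: float
    feedback: str
    t_s: np.ndarray
    diameter_mm: np.ndarray
    marked: np.ndarray
    eye: str = "right"

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.diameter_mm = np.asarray(self.diameter_mm, dtype=float)
        self.marked = np.asarray(self.marked, dtype=bool)
        uid = self.trial_uid
        if self.load not in LOADS:
            raise ValidationError(f"{uid}: unknown load {self.load!r}")
        if self.copresence not in COPRESENCES:
            raise ValidationError(f"{uid}: unknown copresence {self.copresence!r}")
        if self.feedback not in FEEDBACK_LEVELS:
            raise ValidationError(f"{uid}: unknown feedback {self.feedback!r}")
        if not 1 <= self.trial_index <= 30:
            raise ValidationError(f"{uid}: trial_index must be in 1..30")
        if not (self.t_s.shape == self.diameter_mm.shape == self.marked.shape):
            raise ValidationError(f"{uid}: sample arrays differ in length")
        if self.t_s.size and np.any(np.diff(self.t_s) <= 0):
            raise ValidationError(f"{uid}: t_s must be strictly increasing")
        bad = ~self.marked & ~(self.diameter_mm > 0)
        if np.any(bad):
            raise ValidationError(
                f"{uid}: unmarked samples must carry a positive diameter")

    @property
    def trial_uid(self) -> str:
        return make_trial_uid(self.participant_id, self.load,
                              self.copresence, self.trial_index)

    @property
    def n_samples(self) -> int:
        return int(self.t_s.size)

    @property
    def marked_fraction(self) -> float:
        return float(self.marked.mean()) if self.t_s.size else 0.0

    @property
    def samples(self) -> Iterator[PupilSample]:
        for t, d, m in zip(self.t_s, self.diameter_mm, self.marked):
            yield PupilSample(float(t), float(d), bool(m))


@dataclass
class CleanTrace:
    """Uniform 60 Hz, gap-free, baseline-corrected trace on [-3.0, +4.2] s."""

    participant_id: str
    trial_index: int
    load: str
    copresence: str
    feedback: str
    grid_s: np.ndarray
    values_mm: np.ndarray
    bps_mm: float
    corrected: bool = True

    def __post_init__(self) -> None:
        self.grid_s = np.asarray(self.grid_s, dtype=float)
        self.values_mm = np.asarray(self.values_mm, dtype=float)
        if self.grid_s.shape != self.values_mm.shape:
            raise ValidationError(f"{self.trial_uid}: grid/values length mismatch")
        if np.any(~np.isfinite(self.values_mm)):
            raise ValidationError(f"{self.trial_uid}: clean trace has missing values")

    @property
    def trial_uid(self) -> str:
        return make_trial_uid(self.participant_id, self.load,
                              self.copresence, self.trial_index)


@dataclass(frozen=True)
class TrialScore:
    """Word-repetition score of one trial (left/right sentence)."""

    participant_id: str
    trial_index: int
    load: str
    copresence: str
    words_left_total: int
    words_left_correct: int
    words_right_total: int
    words_right_correct: int

    def __post_init__(self) -> None:
        for side in ("left", "right"):
            tot = getattr(self, f"words_{side}_total")
            cor = getattr(self, f"words_{side}_correct")
            if not 0 <= cor <= tot:
                raise ValidationError(
                    f"{self.trial_uid}: {side} correct {cor} outside 0..{tot}")

    @property
    def trial_uid(self) -> str:
        return make_trial_uid(self.participant_id, self.load,
                              self.copresence, self.trial_index)


@dataclass(frozen=True)
class ParticipantCovariates:
    """Questionnaire summaries and per-condition subjective ratings.

    ``ipq_score`` is the summed 14-item place-illusion questionnaire (14-70).
    ``agent_presence_score`` averages the two "agents felt present/real" items;
    ``agent_valence_score`` averages the three valence items (one reverse-scored);
    both on 1-7. ``ratings`` maps (load, copresence) to a dict of the four
    1-10 visual-analogue ratings.
    """

    participant_id: str
    ipq_score: float
    agent_presence_score: float
    agent_valence_score: float
    ratings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 14 <= self.ipq_score <= 70:
            raise ValidationError(
                f"{self.participant_id}: ipq_score {self.ipq_score} outside 14..70")
        for name, v in (("agent_presence_score", self.agent_presence_score),
                        ("agent_valence_score", self.agent_valence_score)):
            if not 1 <= v <= 7:
                raise ValidationError(f"{self.participant_id}: {name} outside 1..7")
        for cond, rd in self.ratings.items():
            for rn, rv in rd.items():
                if not 1.0 <= rv <= 10.0:
                    raise ValidationError(
                        f"{self.participant_id} {cond}: rating {rn}={rv} outside 1..10")


@dataclass
class ConditionSummary:
    """Per participant x condition reduction: mean trace, mean BPS, PPD."""

    participant_id: str
    load: str
    copresence: str
    n_trials_used: int
    grid_s: np.ndarray | None
    mean_trace_mm: np.ndarray | None
    bps_mm: float
    ppd_mm: float
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass
class FeedbackBin:
    """Trials of one participant x load binned by the previous trial's feedback."""

    participant_id: str
    load: str
    prev_feedback: str  # "positive" or "none"
    trial_uids: tuple
    summary: ConditionSummary | None
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass(frozen=True)
class EffectEstimate:
    """One fixed-effect term: estimate, 95% CI, Satterthwaite F-test."""

    term: str
    estimate: float
    ci_low: float
    ci_high: float
    se: float
    F: float
    df_num: int
    df_den: float
    p: float

    def __post_init__(self) -> None:
        if np.isfinite(self.ci_low) and not self.ci_low <= self.estimate <= self.ci_high:
            raise ValidationError(f"{self.term}: CI does not bracket the estimate")


@dataclass(frozen=True)
class LRTResult:
    """Log-likelihood-ratio test of nested full-ML fits."""

    chi_square: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if self.chi_square < 0:
            raise ValidationError("chi_square must be >= 0")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its t-statistic on n-2 df."""

    r: float
    t: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValidationError("|r| must be <= 1")


@dataclass
class Study:
    """A complete study: traces plus per-trial scores and per-participant
    covariates, keyed consistently by trial_uid / participant_id."""

    traces: list
    scores: dict
    covariates: dict

    @property
    def participant_ids(self) -> list:
        seen: dict = {}
        for tr in self.traces:
            seen.setdefault(tr.participant_id, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.traces)
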