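"""Synthetic-study generator.

Emulates the data-generating situation the analysis pipeline assumes: a 2x2
within-subject speech-in-noise design (task load: single vs dual sentence;
copresence: virtual agents vs visual distractors), 30 trials per condition, an
HMD eye tracker sampling at roughly 90 Hz with frame-rate jitter, blink-marked
gaps, a 3 s masker lead before sentence onset and a task-evoked dilation pulse
peaking 2.5-3 s after onset.

The pupil model per trial is

    diameter(t) = B_trial + A_trial * g(t) + measurement noise

with ``B_trial`` (baseline, mm) and ``A_trial`` (dilation amplitude, mm) each
drawn from a random-intercept linear model over the 2x2 design, and ``g`` a
gamma-density-shaped pulse, zero before sentence onset, normalised to unit peak
at ``t_peak`` so that amplitudes are interpretable in mm of peak dilation.

Randomness is fully reproducible: :func:`simulate_study` spawns one independent
substream per participant from the seed, so adding participants never perturbs
earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Effects4, GenerativeParams
from .datatypes import (CONDITIONS, ParticipantCovariates, PupilTrace, Study,
                        TrialScore, make_trial_uid)

__all__ = [
    "TrialPlan",
    "PlannedTrial",
    "make_schedule",
    "simulate_performance",
    "schedule_feedback",
    "pulse",
    "simulate_trace",
    "simulate_ratings",
    "simulate_covariates",
    "simulate_study",
    "simulate_condition_level",
    "design_row",
]


def design_row(load: str, copresence: str) -> np.ndarray:
    """Treatment-coded design row (1, load, copresence, load*copresence);
    reference cell is single-sentence load with distractors."""
    l = 1.0 if load == "dual" else 0.0
    c = 1.0 if copresence == "agents" else 0.0
    return np.array([1.0, l, c, l * c])


def _linpred(effects: Effects4, load: str, copresence: str) -> float:
    return float(np.dot(effects, design_row(load, copresence)))


@dataclass(frozen=True)
class PlannedTrial:
    trial_index: int
    load: str
    copresence: str
    sent_dur_left_s: float
    sent_dur_right_s: float
    words_left: int
    words_right: int


@dataclass(frozen=True)
class TrialPlan:
    """One participant's counterbalanced schedule: 4 conditions x 30 trials."""

    participant_id: str
    condition_order: tuple
    trials: tuple  # PlannedTrial, in presentation order

    def trials_of(self, load: str, copresence: str) -> list:
        return [t for t in self.trials if (t.load, t.copresence) == (load, copresence)]


# Balanced 4x4 Latin square (each condition once per position, first-order
# carryover balanced): row i is [i, i+1, i+3, i+2] mod 4.
_LATIN_OFFSETS = (0, 1, 3, 2)


def condition_order(participant_index: int) -> tuple:
    i = participant_index % 4
    return tuple(CONDITIONS[(i + off) % 4] for off in _LATIN_OFFSETS)


def make_schedule(participant_index: int, params: GenerativeParams,
                  rng: np.random.Generator,
                  participant_id: str | None = None) -> TrialPlan:
    """Draw one participant's trial plan.

    Sentence durations are uniform on the configured range (default 1.2-2.0 s),
    word counts uniform integers on 4..9, and the condition order follows a
    balanced Latin-square cycle keyed by ``participant_index``.
    """
    if participant_index < 0:
        raise ValueError("participant_index must be >= 0")
    pid = participant_id or f"P{participant_index + 1:02d}"
    order = condition_order(participant_index)
    lo, hi = params.sentence_dur_range_s
    wlo, whi = params.words_range
    trials = []
    for load, cop in order:
        for k in range(params.trials_per_condition):
            trials.append(PlannedTrial(
                trial_index=k + 1,
                load=load,
                copresence=cop,
                sent_dur_left_s=float(rng.uniform(lo, hi)),
                sent_dur_right_s=float(rng.uniform(lo, hi)),
                words_left=int(rng.integers(wlo, whi + 1)),
                words_right=int(rng.integers(wlo, whi + 1)),
            ))
    return TrialPlan(participant_id=pid, condition_order=order, trials=tuple(trials))


def simulate_performance(plan: TrialPlan, params: GenerativeParams,
                         rng: np.random.Generator) -> dict:
    """Per-word Bernoulli word-repetition scores, keyed by trial_uid.

    Single-sentence trials score only the attended (left) sentence near ceiling;
    dual-sentence trials score both, the prioritised left ear better than the
    right.
    """
    scores = {}
    for t in plan.trials:
        if t.load == "single":
            left = int(rng.binomial(t.words_left, params.p_word_single))
            right = 0  # right sentence is not attended or scored
        else:
            left = int(rng.binomial(t.words_left, params.p_word_dual_left))
            right = int(rng.binomial(t.words_right, params.p_word_dual_right))
        sc = TrialScore(
            participant_id=plan.participant_id, trial_index=t.trial_index,
            load=t.load, copresence=t.copresence,
            words_left_total=t.words_left, words_left_correct=left,
            words_right_total=t.words_right, words_right_correct=right,
        )
        scores[sc.trial_uid] = sc
    return scores


def _positive_eligible(t: PlannedTrial, sc: TrialScore) -> bool:
    if t.load == "single":
        return sc.words_left_correct == sc.words_left_total
    return sc.words_left_correct >= 2 and sc.words_right_correct >= 2


def schedule_feedback(plan: TrialPlan, scores: dict, params: GenerativeParams,
                      rng: np.random.Generator) -> dict:
    """Per-trial evaluative feedback from the two agents, keyed by trial_uid.

    Applies only in agent-copresence conditions. A fully correct single-sentence
    response (or >= 2 words from both sentences in dual) makes positive feedback
    eligible; anything else makes negative eligible. Each agent independently
    shows eligible feedback with probability 15% (80% for negative after an
    error in the single-sentence condition) and is capped at 3 negative and 5
    positive animations per condition. Distractor conditions receive none. If
    the two agents ever disagree the trial is scored negative (conservative).
    """
    fb = {uid: "none" for uid in scores}
    for load, cop in plan.condition_order:
        if cop != "agents":
            continue
        pos_left = [params.cap_positive, params.cap_positive]  # per agent
        neg_left = [params.cap_negative, params.cap_negative]
        for t in plan.trials_of(load, cop):
            sc = scores[make_trial_uid(plan.participant_id, load, cop, t.trial_index)]
            positive = _positive_eligible(t, sc)
            if positive:
                p_show = params.p_feedback
            elif load == "single":
                p_show = params.p_negative_after_error_single
            else:
                p_show = params.p_feedback
            shown = []
            for agent in range(2):
                if rng.random() >= p_show:
                    continue
                if positive and pos_left[agent] > 0:
                    pos_left[agent] -= 1
                    shown.append("positive")
                elif not positive and neg_left[agent] > 0:
                    neg_left[agent] -= 1
                    shown.append("negative")
            if "negative" in shown:
                fb[sc.trial_uid] = "negative"
            elif "positive" in shown:
                fb[sc.trial_uid] = "positive"
    return fb


def pulse(t: np.ndarray, t_peak_s: float, shape: float) -> np.ndarray:
    """Unimodal gamma-density-shaped dilation kernel.

    Zero for t <= 0, rises to exactly 1 at ``t_peak_s`` and decays; ``shape``
    controls the width (larger = narrower)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / t_peak_s
    out[pos] = x ** shape * np.exp(shape * (1.0 - x))
    return out


def simulate_trace(trial: PlannedTrial, params: GenerativeParams,
                   rng: np.random.Generator,
                   participant_id: str = "P01",
                   participant_bps_effect: float = 0.0,
                   participant_amp_effect: float = 0.0,
                   feedback: str = "none") -> PupilTrace:
    """Simulate one trial's pupil trace at jittered ~90 Hz with blink marks.

    Baseline and amplitude each combine the 2x2 fixed effects, the
    participant's random intercept and an independent trial-level deviation.
    Blink episodes (Poisson onsets, lognormal durations) mark contiguous
    samples; marked samples carry no diameter reading.
    """
    for name in ("participant_bps_effect", "participant_amp_effect"):
        v = locals()[name]
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite")
    b = (_linpred(params.bps_effects_mm, trial.load, trial.copresence)
         + participant_bps_effect + rng.normal(0.0, params.sigma_bps_mm))
    a = (_linpred(params.amp_effects_mm, trial.load, trial.copresence)
         + participant_amp_effect + rng.normal(0.0, params.sigma_amp_mm))

    t_end = max(trial.sent_dur_left_s, trial.sent_dur_right_s) + 3.0
    dt_nom = 1.0 / params.sample_rate_hz
    n_max = int(math.ceil((t_end + 3.0) / dt_nom)) + 16
    dts = dt_nom + rng.normal(0.0, params.jitter_sd_s, size=n_max)
    np.clip(dts, 0.25 * dt_nom, None, out=dts)
    t = -3.0 + np.concatenate(([0.0], np.cumsum(dts)))
    keep = np.searchsorted(t, t_end, side="left") + 1  # one sample at/past t_end
    t = t[:min(keep, t.size)]

    d = b + a * pulse(t, params.t_peak_s, params.pulse_shape)
    if params.sample_noise_mm > 0:
        d = d + rng.normal(0.0, params.sample_noise_mm, size=t.size)

    marked = np.zeros(t.size, dtype=bool)
    if params.blink_rate_hz > 0:
        pos = -3.0 + rng.exponential(1.0 / params.blink_rate_hz)
        mu = math.log(params.blink_mean_dur_s) - 0.5 * params.blink_sigma_log ** 2
        while pos < t[-1]:
            dur = rng.lognormal(mu, params.blink_sigma_log)
            marked |= (t >= pos) & (t <= pos + dur)
            pos += dur + rng.exponential(1.0 / params.blink_rate_hz)
    d = np.where(marked, np.nan, np.maximum(d, 1e-3))

    return PupilTrace(
        participant_id=participant_id, trial_index=trial.trial_index,
        load=trial.load, copresence=trial.copresence,
        sent_dur_left_s=trial.sent_dur_left_s,
        sent_dur_right_s=trial.sent_dur_right_s,
        feedback=feedback, t_s=t, diameter_mm=d, marked=marked,
    )


def simulate_ratings(params: GenerativeParams, rng: np.random.Generator) -> dict:
    """Per-condition subjective ratings from linear models, clipped to [1, 10]."""
    effects = {"effort": params.effort_effects,
               "performance": params.performance_effects,
               "engagement": params.engagement_effects,
               "difficulty": params.difficulty_effects}
    intercepts = {rn: rng.normal(0.0, params.rating_tau) for rn in effects}
    out = {}
    for load, cop in CONDITIONS:
        cell = {}
        for rn, eff in effects.items():
            v = (_linpred(eff, load, cop) + intercepts[rn]
                 + rng.normal(0.0, params.rating_sigma))
            v = float(np.clip(v, 1.0, 10.0))
            if params.round_ratings:
                v = round(v, 1)
            cell[rn] = v
        out[(load, cop)] = cell
    return out


def simulate_covariates(participant_id: str, params: GenerativeParams,
                        rng: np.random.Generator,
                        ratings: dict | None = None) -> ParticipantCovariates:
    ipq = float(np.clip(round(rng.normal(params.ipq_mean, params.ipq_sd)), 14, 70))
    pres = float(np.clip(rng.normal(params.agent_presence_mean,
                                    params.agent_presence_sd), 1, 7))
    val = float(np.clip(rng.normal(params.agent_valence_mean,
                                   params.agent_valence_sd), 1, 7))
    return ParticipantCovariates(
        participant_id=participant_id, ipq_score=ipq,
        agent_presence_score=pres, agent_valence_score=val,
        ratings=ratings or {},
    )


def simulate_study(params: GenerativeParams, n_participants: int,
                   seed: int) -> Study:
    """Simulate a complete study (traces + scores + covariates).

    Deterministic given ``seed``. Each participant draws from an independent
    spawned substream, so extending ``n_participants`` leaves earlier
    participants' data untouched.
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    seqs = np.random.SeedSequence(seed).spawn(n_participants)
    traces = []
    scores = {}
    covariates = {}
    for i, seq in enumerate(seqs):
        rng = np.random.default_rng(seq)
        pid = f"P{i + 1:02d}"
        b_bps = rng.normal(0.0, params.tau_bps_mm)
        b_amp = rng.normal(0.0, params.tau_amp_mm)
        plan = make_schedule(i, params, rng, participant_id=pid)
        psc = simulate_performance(plan, params, rng)
        fb = schedule_feedback(plan, psc, params, rng)
        for t in plan.trials:
            uid = make_trial_uid(pid, t.load, t.copresence, t.trial_index)
            traces.append(simulate_trace(
                t, params, rng, participant_id=pid,
                participant_bps_effect=b_bps, participant_amp_effect=b_amp,
                feedback=fb[uid]))
        scores.update(psc)
        ratings = simulate_ratings(params, rng)
        covariates[pid] = simulate_covariates(pid, params, rng, ratings=ratings)
    return Study(traces=traces, scores=scores, covariates=covariates)


def simulate_condition_level(effects: Effects4, tau: float, sigma: float,
                             n_participants: int, rng: np.random.Generator,
                             interaction: bool = True) -> pd.DataFrame:
    """Simulate one condition-level outcome per participant x condition.

    The workhorse of parameter-recovery and power simulations: a balanced 2x2
    random-intercept model, ``value = x'beta + b_participant + eps``. With
    ``interaction=False`` the interaction coefficient is forced to zero
    (the no-interaction assumption of the power analysis).
    """
    rows = []
    eff = np.asarray(effects, dtype=float)
    if not interaction:
        eff = eff.copy()
        eff[3] = 0.0
    b = rng.normal(0.0, tau, size=n_participants)
    for i in range(n_participants):
        for load, cop in CONDITIONS:
            y = float(np.dot(eff, design_row(load, cop)) + b[i]
                      + rng.normal(0.0, sigma))
            rows.append((f"P{i + 1:02d}", load, cop, y))
    return pd.DataFrame(rows, columns=["participant_id", "load", "copresence", "value"])
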