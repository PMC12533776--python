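"""Outcome measures from clean traces.

Per participant x condition the retained trials are reduced to a single
baseline-corrected mean trace; the condition's BPS is the mean of the per-trial
BPS values and its PPD (peak pupil dilation) is the maximum of the mean trace
over the full 7.2 s window (earliest time point on ties). Word-repetition
performance pools words over the sentences the participant had to repeat.
An exploratory re-binning groups agent-condition trials by the feedback shown
on the immediately preceding trial (negative-preceded trials are discarded and
bins with fewer than six traces excluded).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (ConditionSummary, FeedbackBin, Study, TrialScore,
                        ValidationError, make_trial_uid)

__all__ = [
    "aggregate_condition",
    "condition_summaries",
    "percent_correct",
    "performance_table",
    "rebin_by_prev_feedback",
    "summaries_to_frame",
    "bins_to_frame",
]

MIN_BIN_TRACES = 6  # feedback bins below this are excluded


def aggregate_condition(clean_traces: list, participant_id: str | None = None,
                        load: str | None = None, copresence: str | None = None,
                        ) -> ConditionSummary:
    """Reduce one participant x condition's clean traces to its summary.

    Empty input yields an excluded summary (the condition fell to QC)."""
    if not clean_traces:
        return ConditionSummary(
            participant_id=participant_id or "", load=load or "",
            copresence=copresence or "", n_trials_used=0, grid_s=None,
            mean_trace_mm=None, bps_mm=float("nan"), ppd_mm=float("nan"),
            excluded=True, exclusion_reason="condition_qc")
    first = clean_traces[0]
    stack = np.vstack([ct.values_mm for ct in clean_traces])
    mean_trace = stack.mean(axis=0)
    bps = float(np.mean([ct.bps_mm for ct in clean_traces]))
    peak_idx = int(np.argmax(mean_trace))  # first occurrence on ties
    return ConditionSummary(
        participant_id=first.participant_id, load=first.load,
        copresence=first.copresence, n_trials_used=len(clean_traces),
        grid_s=first.grid_s, mean_trace_mm=mean_trace,
        bps_mm=bps, ppd_mm=float(mean_trace[peak_idx]),
    )


def condition_summaries(cells: dict) -> list:
    """Aggregate every (participant, load, copresence) cell from
    :func:`pupilvr.preprocess.preprocess_study`."""
    out = []
    for (pid, load, cop), traces in sorted(cells.items()):
        out.append(aggregate_condition(traces, participant_id=pid,
                                       load=load, copresence=cop))
    return out


def percent_correct(score: TrialScore) -> float:
    """Percentage of words repeated correctly: one sentence in the
    single-sentence condition, words pooled over both sentences in dual."""
    if score.load == "single":
        tot, cor = score.words_left_total, score.words_left_correct
    else:
        tot = score.words_left_total + score.words_right_total
        cor = score.words_left_correct + score.words_right_correct
    if tot <= 0:
        raise ValidationError(f"{score.trial_uid}: word total must be positive")
    return 100.0 * cor / tot


def performance_table(study: Study) -> pd.DataFrame:
    """Per-trial performance rows (participant, condition, percent correct,
    per-ear percentages for dual trials)."""
    rows = []
    for uid, sc in study.scores.items():
        left = 100.0 * sc.words_left_correct / sc.words_left_total
        right = (100.0 * sc.words_right_correct / sc.words_right_total
                 if sc.load == "dual" else np.nan)
        rows.append((sc.participant_id, sc.load, sc.copresence, sc.trial_index,
                     percent_correct(sc), left, right))
    return pd.DataFrame(rows, columns=[
        "participant_id", "load", "copresence", "trial_index",
        "percent_correct", "percent_left", "percent_right"])


def rebin_by_prev_feedback(clean_traces: list, feedback_log: dict,
                           min_traces: int = MIN_BIN_TRACES) -> list:
    """Re-bin agent-condition trials by the previous trial's feedback.

    ``feedback_log`` maps trial_uid to the feedback shown on that trial
    ("none"/"positive"/"negative"). A trial joins the "positive" or "none" bin
    according to trial ``t-1`` of the same condition; trials following negative
    feedback are dropped, the first trial of a condition has no predecessor and
    is never binned, and bins with fewer than ``min_traces`` traces are
    excluded. Bins are per participant x load (the two agent conditions).
    """
    bins: dict = {}
    dropped: dict = {}
    for ct in clean_traces:
        if ct.copresence != "agents":
            continue
        if ct.trial_index < 2:
            continue  # no predecessor
        prev_uid = make_trial_uid(ct.participant_id, ct.load, ct.copresence,
                                  ct.trial_index - 1)
        prev_fb = feedback_log.get(prev_uid)
        if prev_fb is None:
            continue
        if prev_fb == "negative":
            dropped.setdefault((ct.participant_id, ct.load), []).append(ct.trial_uid)
            continue
        key = (ct.participant_id, ct.load, prev_fb)
        bins.setdefault(key, []).append(ct)

    out = []
    for (pid, load, prev_fb), members in sorted(bins.items()):
        if len(members) < min_traces:
            out.append(FeedbackBin(
                participant_id=pid, load=load, prev_feedback=prev_fb,
                trial_uids=tuple(m.trial_uid for m in members), summary=None,
                excluded=True,
                exclusion_reason=f"only {len(members)} traces < {min_traces}"))
            continue
        out.append(FeedbackBin(
            participant_id=pid, load=load, prev_feedback=prev_fb,
            trial_uids=tuple(m.trial_uid for m in members),
            summary=aggregate_condition(members)))
    return out


def summaries_to_frame(summaries: list) -> pd.DataFrame:
    """Long outcome rows for the 2x2 mixed models (excluded cells dropped)."""
    rows = [(s.participant_id, s.load, s.copresence, s.bps_mm, s.ppd_mm)
            for s in summaries if not s.excluded]
    return pd.DataFrame(rows, columns=["participant_id", "load", "copresence",
                                       "bps", "ppd"])


def bins_to_frame(bins: list) -> pd.DataFrame:
    """Long rows for the feedback mixed models (excluded bins dropped)."""
    rows = [(b.participant_id, b.load, b.prev_feedback,
             b.summary.bps_mm, b.summary.ppd_mm)
            for b in bins if not b.excluded]
    return pd.DataFrame(rows, columns=["participant_id", "load",
                                       "prev_feedback", "bps", "ppd"])
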