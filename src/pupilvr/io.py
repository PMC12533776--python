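"""Plain-CSV persistence for studies and results.

Three files describe a study:

* ``samples.csv`` (long): participant_id, trial_uid, t_s, diameter_mm, marked, eye.
  The diameter field is empty for marked (eye-closed) samples without a reading.
* ``metadata.csv``: one row per trial with condition, trial index, sentence
  durations, word scores and the agent feedback shown on that trial.
* ``covariates.csv``: one row per participant with questionnaire summaries and
  the per-condition subjective ratings (columns ``<rating>__<load>_<copresence>``).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (COPRESENCES, FEEDBACK_LEVELS, LOADS, RATING_NAMES,
                        ConditionSummary, EffectEstimate, ParticipantCovariates,
                        PupilTrace, Study, TrialScore, ValidationError)

__all__ = ["read_study", "write_study", "write_outputs", "read_outputs", "FormatError"]

log = logging.getLogger("pupilvr")

SAMPLE_COLS = ["participant_id", "trial_uid", "t_s", "diameter_mm", "marked", "eye"]
METADATA_COLS = [
    "participant_id", "trial_uid", "load", "copresence", "trial_index",
    "sent_dur_left_s", "sent_dur_right_s",
    "words_left_total", "words_left_correct",
    "words_right_total", "words_right_correct", "feedback",
]


class FormatError(ValueError):
    """Raised when a CSV lacks required columns or is otherwise malformed."""


def _require_cols(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def read_study(samples_path: str | Path, metadata_path: str | Path,
               covariates_path: str | Path | None = None) -> Study:
    """Read a study from the long samples CSV plus trial metadata.

    Every metadata row must match exactly one trace in the samples file;
    unmatched rows are reported in the log. Traces with non-monotone time
    stamps raise :class:`ValidationError` naming the trial.
    """
    samples = pd.read_csv(samples_path, dtype={"participant_id": str},
                          float_precision="round_trip")
    meta = pd.read_csv(metadata_path, dtype={"participant_id": str},
                       float_precision="round_trip")
    _require_cols(samples, SAMPLE_COLS, samples_path)
    _require_cols(meta, METADATA_COLS, metadata_path)

    if len(samples) == 0:
        log.warning("read_study: samples file %s is empty", samples_path)
    by_uid = {uid: grp for uid, grp in samples.groupby("trial_uid", sort=False)}

    traces: list[PupilTrace] = []
    scores: dict[str, TrialScore] = {}
    unmatched = []
    for row in meta.itertuples(index=False):
        idx = int(row.trial_index)
        if not 1 <= idx <= 30:
            raise ValidationError(
                f"{row.trial_uid}: trial_index {idx} outside 1..30")
        grp = by_uid.pop(row.trial_uid, None)
        if grp is None:
            unmatched.append(row.trial_uid)
            continue
        diam = grp["diameter_mm"].to_numpy(dtype=float)
        marked = grp["marked"].to_numpy(dtype=int).astype(bool)
        traces.append(PupilTrace(
            participant_id=str(row.participant_id),
            trial_index=idx,
            load=str(row.load),
            copresence=str(row.copresence),
            sent_dur_left_s=float(row.sent_dur_left_s),
            sent_dur_right_s=float(row.sent_dur_right_s),
            feedback=str(row.feedback),
            t_s=grp["t_s"].to_numpy(dtype=float),
            diameter_mm=diam,
            marked=marked,
            eye=str(grp["eye"].iloc[0]),
        ))
        scores[traces[-1].trial_uid] = TrialScore(
            participant_id=str(row.participant_id),
            trial_index=idx,
            load=str(row.load),
            copresence=str(row.copresence),
            words_left_total=int(row.words_left_total),
            words_left_correct=int(row.words_left_correct),
            words_right_total=int(row.words_right_total),
            words_right_correct=int(row.words_right_correct),
        )
    if unmatched:
        log.warning("read_study: %d metadata row(s) without samples: %s",
                    len(unmatched), unmatched[:5])
    if by_uid:
        log.warning("read_study: %d trace(s) without metadata ignored", len(by_uid))

    covariates: dict[str, ParticipantCovariates] = {}
    if covariates_path is not None:
        covariates = _read_covariates(covariates_path)
    return Study(traces=traces, scores=scores, covariates=covariates)


def _rating_col(rating: str, load: str, cop: str) -> str:
    return f"{rating}__{load}_{cop}"


def _read_covariates(path: str | Path) -> dict[str, ParticipantCovariates]:
    df = pd.read_csv(path, dtype={"participant_id": str},
                     float_precision="round_trip")
    _require_cols(df, ["participant_id", "ipq_score", "agent_presence_score",
                       "agent_valence_score"], path)
    out = {}
    for row in df.itertuples(index=False):
        ratings = {}
        for load in LOADS:
            for cop in COPRESENCES:
                cell = {}
                for rn in RATING_NAMES:
                    col = _rating_col(rn, load, cop)
                    if col in df.columns:
                        cell[rn] = float(getattr(row, col))
                if cell:
                    ratings[(load, cop)] = cell
        out[str(row.participant_id)] = ParticipantCovariates(
            participant_id=str(row.participant_id),
            ipq_score=float(row.ipq_score),
            agent_presence_score=float(row.agent_presence_score),
            agent_valence_score=float(row.agent_valence_score),
            ratings=ratings,
        )
    return out


def write_study(study: Study, out_dir: str | Path) -> dict[str, Path]:
    """Write samples/metadata/covariates CSVs; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    srows = []
    mrows = []
    for tr in study.traces:
        uid = tr.trial_uid
        diam = tr.diameter_mm.astype(object)
        diam[np.isnan(tr.diameter_mm)] = ""  # marked samples may lack a reading
        for t, d, m in zip(tr.t_s, diam, tr.marked.astype(int)):
            srows.append((tr.participant_id, uid, repr(float(t)),
                          d if d == "" else repr(float(d)), m, tr.eye))
        sc = study.scores[uid]
        mrows.append((tr.participant_id, uid, tr.load, tr.copresence, tr.trial_index,
                      tr.sent_dur_left_s, tr.sent_dur_right_s,
                      sc.words_left_total, sc.words_left_correct,
                      sc.words_right_total, sc.words_right_correct, tr.feedback))
    paths = {
        "samples": out / "samples.csv",
        "metadata": out / "metadata.csv",
        "covariates": out / "covariates.csv",
    }
    pd.DataFrame(srows, columns=SAMPLE_COLS).to_csv(paths["samples"], index=False)
    # %.17g round-trips doubles exactly
    pd.DataFrame(mrows, columns=METADATA_COLS).to_csv(
        paths["metadata"], index=False, float_format="%.17g")

    crows = []
    for pid, cov in study.covariates.items():
        row = {"participant_id": pid, "ipq_score": cov.ipq_score,
               "agent_presence_score": cov.agent_presence_score,
               "agent_valence_score": cov.agent_valence_score}
        for (load, cop), cell in cov.ratings.items():
            for rn, rv in cell.items():
                row[_rating_col(rn, load, cop)] = rv
        crows.append(row)
    pd.DataFrame(crows).to_csv(paths["covariates"], index=False,
                               float_format="%.17g")
    return paths


SUMMARY_COLS = ["participant_id", "load", "copresence", "n_trials_used",
                "bps_mm", "ppd_mm", "excluded", "exclusion_reason"]
ESTIMATE_COLS = ["outcome", "term", "estimate", "ci_low", "ci_high", "se",
                 "F", "df_num", "df_den", "p"]


def write_outputs(out_dir: str | Path,
                  summaries: list[ConditionSummary] | None = None,
                  estimates: dict[str, list[EffectEstimate]] | None = None,
                  ) -> dict[str, Path]:
    """Write condition summaries and/or effect estimates as documented CSVs.

    ``estimates`` maps an outcome label (e.g. ``"bps"``) to its term estimates.
    Confidence intervals are mandatory: a non-finite CI bound raises.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if summaries is not None:
        rows = [(s.participant_id, s.load, s.copresence, s.n_trials_used,
                 s.bps_mm, s.ppd_mm, int(s.excluded), s.exclusion_reason)
                for s in summaries]
        paths["summaries"] = out / "condition_summaries.csv"
        pd.DataFrame(rows, columns=SUMMARY_COLS).to_csv(paths["summaries"], index=False)
        wide_rows = []
        for s in summaries:
            if s.mean_trace_mm is not None:
                wide_rows.append([s.participant_id, s.load, s.copresence,
                                  *s.mean_trace_mm])
        if wide_rows:
            grid = next(s.grid_s for s in summaries if s.grid_s is not None)
            cols = ["participant_id", "load", "copresence"] + [f"t{t:+.4f}" for t in grid]
            paths["mean_traces"] = out / "mean_traces.csv"
            pd.DataFrame(wide_rows, columns=cols).to_csv(paths["mean_traces"], index=False)
    if estimates is not None:
        rows = []
        for outcome, ests in estimates.items():
            for e in ests:
                if not (np.isfinite(e.ci_low) and np.isfinite(e.ci_high)):
                    raise ValidationError(
                        f"{outcome}/{e.term}: confidence interval is mandatory")
                rows.append((outcome, e.term, e.estimate, e.ci_low, e.ci_high,
                             e.se, e.F, e.df_num, e.df_den, e.p))
        paths["estimates"] = out / "effect_estimates.csv"
        pd.DataFrame(rows, columns=ESTIMATE_COLS).to_csv(paths["estimates"], index=False)
    return paths


def read_outputs(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Re-read whatever output CSVs exist under ``out_dir``."""
    out = Path(out_dir)
    frames = {}
    for key, name in (("summaries", "condition_summaries.csv"),
                      ("mean_traces", "mean_traces.csv"),
                      ("estimates", "effect_estimates.csv")):
        p = out / name
        if p.exists():
            frames[key] = pd.read_csv(p)
    return frames
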