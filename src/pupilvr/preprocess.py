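"""Trace-cleaning chain for HMD pupillometry.

Order of operations per participant x condition:

1. QC: exclude any trace whose raw eye-closed mark fraction exceeds 20%;
   exclude the whole condition when 6 or more of its traces are excluded.
2. Blink margins: widen every marked run by 83 ms before / 133 ms after, in
   continuous time, to absorb eyelid open/close artifacts.
3. Regrid to a uniform 60 Hz grid starting at masker onset (-3.0 s); a grid
   point is marked iff either bracketing source sample is marked.
4. Replace marked runs by linear interpolation between the nearest unmarked
   neighbours (edge runs hold the nearest unmarked value).
5. Baseline pupil size (BPS): mean diameter over the last second of masker
   noise, [-1.0, 0.0) s; subtract it from every sample.
6. Smooth with a centred 11-point moving average (window shrinks symmetrically
   at the edges so length is preserved).
7. Drop the first four trials of the condition (task-adjustment instability).
8. Crop to the 7.2 s analysis window [-3.0, +4.2] s.

The whole module is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .datatypes import CleanTrace, PupilTrace

__all__ = [
    "TraceUnusableError",
    "GriddedTrace",
    "QCReport",
    "qc_flag_trace",
    "qc_flag_condition",
    "extend_blink_margins",
    "regrid_60hz",
    "interpolate_marked",
    "compute_bps",
    "baseline_correct",
    "smooth_moving_average",
    "drop_first_trials",
    "crop_window",
    "preprocess_condition",
    "preprocess_study",
]

_EPS = 1e-6  # time comparison slack, far below half a 60 Hz step


class TraceUnusableError(ValueError):
    """Raised when a trace cannot be cleaned (e.g. no unmarked samples)."""


@dataclass
class GriddedTrace:
    """Intermediate product: uniform-grid trace with (possibly) marked points."""

    source: PupilTrace
    grid_s: np.ndarray
    values_mm: np.ndarray
    marked: np.ndarray
    bps_mm: float | None = None
    corrected: bool = False


@dataclass
class QCReport:
    """Per-condition log of exclusions and processing outcomes."""

    participant_id: str
    load: str
    copresence: str
    n_input: int = 0
    n_qc_excluded: int = 0
    condition_excluded: bool = False
    entries: list = field(default_factory=list)  # (trial_uid, stage, reason)

    def add(self, trial_uid: str, stage: str, reason: str) -> None:
        self.entries.append((trial_uid, stage, reason))


def qc_flag_trace(trace: PupilTrace, config: PipelineConfig) -> bool:
    """True iff the trace is kept: marked fraction strictly above the
    threshold (default 20%) excludes it, counted on raw marks before any
    margin extension."""
    if trace.n_samples < 1:
        raise TraceUnusableError(f"{trace.trial_uid}: empty trace")
    return trace.marked_fraction <= config.qc_marked_fraction


def qc_flag_condition(keep_decisions: list, config: PipelineConfig) -> bool:
    """True iff the condition is kept: six or more excluded traces drop it."""
    n_bad = sum(1 for k in keep_decisions if not k)
    return n_bad < config.condition_min_bad


def extend_blink_margins(trace: PupilTrace, config: PipelineConfig) -> PupilTrace:
    """Widen every maximal marked run by the pre/post blink margins.

    Margins are applied in continuous time (83 ms before the run start, 133 ms
    after its end) then mapped back to samples, so the rule is independent of
    the sampling rate. The marked set only grows; runs at the trace boundary
    are clipped there."""
    marked = trace.marked
    if not marked.any():
        return trace
    pre = config.blink_pre_ms / 1000.0
    post = config.blink_post_ms / 1000.0
    t = trace.t_s
    out = marked.copy()
    # maximal runs of True
    dm = np.diff(marked.astype(np.int8))
    starts = np.flatnonzero(dm == 1) + 1
    ends = np.flatnonzero(dm == -1)
    if marked[0]:
        starts = np.concatenate(([0], starts))
    if marked[-1]:
        ends = np.concatenate((ends, [marked.size - 1]))
    for s, e in zip(starts, ends):
        out |= (t >= t[s] - pre - _EPS) & (t <= t[e] + post + _EPS)
    new = PupilTrace(
        participant_id=trace.participant_id, trial_index=trace.trial_index,
        load=trace.load, copresence=trace.copresence,
        sent_dur_left_s=trace.sent_dur_left_s,
        sent_dur_right_s=trace.sent_dur_right_s,
        feedback=trace.feedback, t_s=t, diameter_mm=trace.diameter_mm,
        marked=out, eye=trace.eye,
    )
    return new


def regrid_60hz(trace: PupilTrace, config: PipelineConfig) -> GriddedTrace:
    """Resample onto the uniform analysis grid starting at masker onset.

    The grid runs from -3.0 s in steps of 1/60 s up to the last source sample.
    Unmarked grid values come from linear interpolation between the bracketing
    source samples; a grid point is marked iff either bracketing sample is
    marked (an exact time hit inherits that sample's mark)."""
    if (~trace.marked).sum() < 2:
        raise TraceUnusableError(f"{trace.trial_uid}: fewer than 2 unmarked samples")
    t = trace.t_s
    step = 1.0 / config.resample_hz
    start = config.window_start_s
    if t[0] > start + _EPS:
        raise TraceUnusableError(
            f"{trace.trial_uid}: trace starts at {t[0]:.3f} s, after masker onset")
    n_grid = int(np.floor((t[-1] - start) / step + _EPS)) + 1
    grid = start + step * np.arange(n_grid)

    left = np.clip(np.searchsorted(t, grid + _EPS, side="right") - 1, 0, t.size - 1)
    exact = np.abs(t[left] - grid) <= _EPS
    right = np.clip(left + 1, 0, t.size - 1)
    marked = np.where(exact, trace.marked[left],
                      trace.marked[left] | trace.marked[right])
    values = np.interp(grid, t, trace.diameter_mm)
    values = np.where(marked, np.nan, values)
    return GriddedTrace(source=trace, grid_s=grid, values_mm=values, marked=marked)


def interpolate_marked(gridded: GriddedTrace) -> GriddedTrace:
    """Fill marked runs: straight line between the nearest unmarked values on
    either side; leading/trailing runs hold the nearest unmarked value."""
    ok = ~gridded.marked
    if not ok.any():
        raise TraceUnusableError(f"{gridded.source.trial_uid}: all samples marked")
    values = np.interp(gridded.grid_s, gridded.grid_s[ok], gridded.values_mm[ok])
    return GriddedTrace(source=gridded.source, grid_s=gridded.grid_s,
                        values_mm=values,
                        marked=np.zeros_like(gridded.marked),
                        bps_mm=gridded.bps_mm, corrected=gridded.corrected)


def compute_bps(gridded: GriddedTrace, config: PipelineConfig) -> float:
    """Mean pupil size over the baseline window [-1.0, 0.0) s (half-open:
    the sentence-onset sample is excluded)."""
    b0, b1 = config.baseline_window_s
    t = gridded.grid_s
    mask = (t >= b0 - _EPS) & (t < b1 - _EPS)
    if not mask.any():
        raise TraceUnusableError(
            f"{gridded.source.trial_uid}: baseline window empty")
    return float(gridded.values_mm[mask].mean())


def baseline_correct(gridded: GriddedTrace, bps_mm: float) -> GriddedTrace:
    """Subtract the trace's own BPS from every sample (guarded against being
    applied twice)."""
    if gridded.corrected:
        raise ValueError(f"{gridded.source.trial_uid}: already baseline-corrected")
    return GriddedTrace(source=gridded.source, grid_s=gridded.grid_s,
                        values_mm=gridded.values_mm - bps_mm,
                        marked=gridded.marked, bps_mm=bps_mm, corrected=True)


def smooth_moving_average(values: np.ndarray, smooth_points: int) -> np.ndarray:
    """Centred moving average; the window shrinks symmetrically at the edges so
    output length equals input length."""
    if smooth_points % 2 == 0 or smooth_points < 1:
        raise ValueError("smooth_points must be a positive odd integer")
    v = np.asarray(values, dtype=float)
    n = v.size
    h = smooth_points // 2
    idx = np.arange(n)
    hw = np.minimum(h, np.minimum(idx, n - 1 - idx))
    csum = np.concatenate(([0.0], np.cumsum(v)))
    lo = idx - hw
    hi = idx + hw + 1
    return (csum[hi] - csum[lo]) / (hi - lo)


def drop_first_trials(traces: list, config: PipelineConfig) -> list:
    """Remove trials with trial_index <= drop_first_n (task-adjustment
    instability), independent of QC outcomes."""
    return [tr for tr in traces if _trial_index(tr) > config.drop_first_n]


def _trial_index(obj) -> int:
    return obj.source.trial_index if isinstance(obj, GriddedTrace) else obj.trial_index


def crop_window(gridded: GriddedTrace, config: PipelineConfig) -> GriddedTrace:
    """Restrict to the analysis window [-3.0, +4.2] s (7.2 s, closed ends on
    the grid)."""
    t = gridded.grid_s
    end = config.window_end_s
    if t[-1] < end - _EPS:
        raise TraceUnusableError(
            f"{gridded.source.trial_uid}: trace ends at {t[-1]:.3f} s, "
            f"before the {config.analysis_window_s:.1f} s window")
    mask = (t >= config.window_start_s - _EPS) & (t <= end + _EPS)
    return GriddedTrace(source=gridded.source, grid_s=t[mask],
                        values_mm=gridded.values_mm[mask],
                        marked=gridded.marked[mask],
                        bps_mm=gridded.bps_mm, corrected=gridded.corrected)


def _finalize(gridded: GriddedTrace) -> CleanTrace:
    src = gridded.source
    return CleanTrace(
        participant_id=src.participant_id, trial_index=src.trial_index,
        load=src.load, copresence=src.copresence, feedback=src.feedback,
        grid_s=gridded.grid_s, values_mm=gridded.values_mm,
        bps_mm=float(gridded.bps_mm), corrected=gridded.corrected,
    )


def preprocess_condition(traces: list, config: PipelineConfig,
                         ) -> tuple[list, QCReport]:
    """Run the full cleaning chain on one participant x condition.

    Returns the retained :class:`CleanTrace` list and a QC report listing every
    exclusion with its stage and reason. An excluded condition yields an empty
    list with the report flagged, not an exception.
    """
    if not traces:
        raise ValueError("preprocess_condition needs at least one trace")
    first = traces[0]
    report = QCReport(participant_id=first.participant_id,
                      load=first.load, copresence=first.copresence,
                      n_input=len(traces))
    keep = []
    for tr in traces:
        ok = qc_flag_trace(tr, config)
        keep.append(ok)
        if not ok:
            report.add(tr.trial_uid, "trace_qc",
                       f"marked fraction {tr.marked_fraction:.3f} > "
                       f"{config.qc_marked_fraction:.2f}")
    report.n_qc_excluded = sum(1 for k in keep if not k)
    if not qc_flag_condition(keep, config):
        report.condition_excluded = True
        report.add("*", "condition_qc",
                   f"{report.n_qc_excluded} traces excluded >= "
                   f"{config.condition_min_bad}")
        return [], report

    retained = [tr for tr, k in zip(traces, keep) if k]
    cleaned = []
    for tr in retained:
        try:
            g = regrid_60hz(extend_blink_margins(tr, config), config)
            g = interpolate_marked(g)
            bps = compute_bps(g, config)
            g = baseline_correct(g, bps)
            g.values_mm = smooth_moving_average(g.values_mm, config.smooth_points)
            cleaned.append(g)
        except TraceUnusableError as exc:
            report.add(tr.trial_uid, "cleaning", str(exc))
    kept = drop_first_trials(cleaned, config)
    for g in cleaned:
        if g not in kept:
            report.add(g.source.trial_uid, "drop_first",
                       f"trial_index <= {config.drop_first_n}")
    cleaned = kept
    out = []
    for g in cleaned:
        try:
            out.append(_finalize(crop_window(g, config)))
        except TraceUnusableError as exc:
            report.add(g.source.trial_uid, "crop", str(exc))
    report.add("*", "retained", f"{len(out)} of {report.n_input}")
    return out, report


def preprocess_study(study, config: PipelineConfig) -> tuple[dict, list]:
    """Clean every participant x condition cell of a study.

    Returns ``(cells, reports)`` where ``cells`` maps
    ``(participant_id, load, copresence)`` to a list of clean traces (empty if
    the condition was excluded)."""
    by_cell: dict = {}
    for tr in study.traces:
        by_cell.setdefault((tr.participant_id, tr.load, tr.copresence), []).append(tr)
    cells = {}
    reports = []
    for key, trs in by_cell.items():
        trs = sorted(trs, key=lambda t: t.trial_index)
        clean, rep = preprocess_condition(trs, config)
        cells[key] = clean
        reports.append(rep)
    return cells, reports
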