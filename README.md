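# pupilvr

Pupillometry analysis for virtual-reality speech-in-noise (SiN) listening-effort
studies.

## The problem

Listening effort is commonly indexed by the task-evoked pupil response: when a
masked sentence must be understood, the pupil dilates, peaking roughly 2.5–3 s
after sentence onset. Two metrics summarise a trial block:

* **BPS** (baseline pupil size) — mean diameter over the last second of masker
  noise before sentence onset; indexes anticipatory arousal.
* **PPD** (peak pupil dilation) — maximum of the baseline-corrected,
  condition-averaged trace; indexes listening effort.

`pupilvr` implements the full analysis chain for a 2×2 within-subject design —
task load (repeat one vs. both of two dichotically presented sentences) ×
virtual copresence (evaluative virtual agents vs. inert visual distractors) —
as measured with an eye tracker inside a VR head-mounted display sampling at
roughly 90 Hz:

1. **Synthetic studies** (`pupilvr.synth`) — trial schedules, word-repetition
   scores, agent feedback with caps, and pupil traces
   `d(t) = B + A·g(t) + noise` with random participant intercepts, blink gaps
   and frame-rate jitter, so the whole pipeline is testable without any
   recording.
2. **Trace cleaning** (`pupilvr.preprocess`) — >20 % marked-sample QC (≥6 bad
   traces drop the condition), 83/133 ms blink margins, 60 Hz regridding,
   linear de-blinking, BPS baseline correction, 11-point moving average, first
   four trials dropped, 7.2 s analysis window [−3.0, +4.2] s.
3. **Metrics** (`pupilvr.metrics`) — per-condition mean trace, BPS, PPD,
   pooled word-repetition percentages, and re-binning by the previous trial's
   feedback (bins under six traces excluded).
4. **Inference** (`pupilvr.inference`) — the linear mixed model
   `y ~ load * copresence + (1 | participant)` under treatment coding, fitted
   by REML with F-tests on Satterthwaite denominator degrees of freedom
   (validated against lmerTest), plus paired t-tests, Pearson correlations and
   4-df log-likelihood covariate tests.
5. **Power** (`pupilvr.power`) — simulation-based power for the 2×2 PPD design
   (load effect 0.20 mm, copresence effect 0.025 mm, α = 0.05, target 80 %).

## Worked example

```python
import pandas as pd
from pupilvr import (load_config, simulate_study, preprocess_study,
                     condition_summaries, fit_lmm_2x2)
from pupilvr.metrics import summaries_to_frame

cfg = load_config(None)                      # study defaults
study = simulate_study(cfg.generative, 33, seed=1)
cells, reports = preprocess_study(study, cfg.pipeline)
rows = summaries_to_frame(condition_summaries(cells))
print(fit_lmm_2x2(rows, outcome="ppd").summary())
```

prints

```
Random-intercept LMM (REML), 132 obs / 33 participants
participant var 0.0236, residual var 0.001093, loglik 176.263
           term  estimate  ci_low  ci_high      se         F  df_num   df_den       p
      intercept    0.2909  0.2373   0.3445  0.0274  113.1162       1  34.2353  0.0000
           load    0.1708  0.1549   0.1868  0.0081  440.5414       1  95.9881  0.0000
     copresence   -0.0310 -0.0469  -0.0150  0.0081   14.4778       1  95.9881  0.0002
load:copresence    0.0017 -0.0209   0.0243  0.0115    0.0219       1  95.9881  0.8827
```

The load row is the change in PPD from single- to dual-sentence load
(≈ 0.17 mm here — dual-task listening dilates the pupil more), with its Wald
95 % CI and a Satterthwaite F-test; the copresence row is the change from
distractors to agents. The same call with `outcome="bps"` models baseline
pupil size.

The shell pipeline mirrors this: `pupilvr run-all --seed 1 --n 33 --out-dir out/`
(stages `simulate`, `preprocess`, `metrics`, `fit`, `power` also run
individually; see `pupilvr --help`).

## Layout

```
src/pupilvr/      config, datatypes, io, synth, preprocess, metrics,
                  inference, power, cli
tests/            unit, property and end-to-end scientific tests
docs/methods.md   model, assumptions, parameter defaults, limitations
```
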