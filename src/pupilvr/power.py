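"""Simulation-based power analysis for the 2x2 within-subject PPD design.

For each candidate participant count ``n`` the procedure simulates replicate
studies of condition-level peak pupil dilation from the random-intercept
generative model — a strong load effect (default 0.20 mm), a weak copresence
effect (default 0.025 mm) and no interaction — fits the same 2x2 mixed model
used for the real analysis, and records the fraction of replicates in which
each effect's Satterthwaite F-test rejects at alpha. Simulation runs at the
condition-summary level (one PPD per participant x condition, the unit the
analysis models); the trial residual is shrunk by sqrt(n_trials_averaged)
because a condition PPD is read off a mean over trials.

Because no variance components are published for the original calculation, the
defaults are calibrated (see docs/methods.md) and the minimum n is reported
together with its Monte-Carlo standard error rather than asserted against any
particular target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PowerConfig
from .inference import fit_lmm_2x2
from .synth import simulate_condition_level

__all__ = ["PowerCurve", "MinNResult", "estimate_power", "min_n_for_power"]

EFFECT_TERMS = ("load", "copresence")


@dataclass
class PowerCurve:
    """Estimated power per (n, effect) with Monte-Carlo standard errors."""

    frame: pd.DataFrame  # columns: n, effect, power, mc_se
    config: PowerConfig

    def power(self, n: int, effect: str) -> float:
        f = self.frame
        row = f[(f["n"] == n) & (f["effect"] == effect)]
        if row.empty:
            raise KeyError((n, effect))
        return float(row["power"].iloc[0])


@dataclass(frozen=True)
class MinNResult:
    """Smallest grid n reaching the target for every requested effect."""

    n: int | None
    reached: bool
    target_power: float
    per_effect: dict  # effect -> (power at n, mc_se) or at the largest grid n

    def __str__(self) -> str:
        if self.reached:
            body = ", ".join(f"{e}: {p:.3f} (±{se:.3f})"
                             for e, (p, se) in self.per_effect.items())
            return f"min n = {self.n} for power >= {self.target_power} [{body}]"
        return f"target power {self.target_power} not reached on the grid"


def estimate_power(config: PowerConfig, seed: int = 0,
                   effects: tuple = EFFECT_TERMS) -> PowerCurve:
    """Monte-Carlo power curve over ``config.n_grid``.

    Deterministic given ``seed``; each (n, replicate) cell draws from an
    independent spawned substream so the grid can be extended without
    perturbing existing cells.
    """
    gen_effects = (config.intercept_mm, config.effect_load_mm,
                   config.effect_copresence_mm, 0.0)
    sigma = config.sigma_condition_mm
    rows = []
    root = np.random.SeedSequence(seed)
    for n in config.n_grid:
        streams = root.spawn(config.replicates)
        rej = {e: 0 for e in effects}
        for rep_seq in streams:
            rng = np.random.default_rng(rep_seq)
            df = simulate_condition_level(gen_effects, config.tau_mm, sigma,
                                          n, rng, interaction=False)
            res = fit_lmm_2x2(df)
            for e in effects:
                if res[e].p < config.alpha:
                    rej[e] += 1
        for e in effects:
            p = rej[e] / config.replicates
            rows.append((n, e, p, float(np.sqrt(p * (1 - p) / config.replicates))))
    return PowerCurve(frame=pd.DataFrame(rows, columns=["n", "effect", "power",
                                                        "mc_se"]),
                      config=config)


def min_n_for_power(curve: PowerCurve, config: PowerConfig | None = None,
                    effects: tuple = EFFECT_TERMS) -> MinNResult:
    """Smallest grid n whose estimated power meets the target for every
    requested effect; explicit "not reached" result otherwise."""
    config = config or curve.config
    f = curve.frame
    for n in sorted(f["n"].unique()):
        sub = f[f["n"] == n].set_index("effect")
        if all(sub.loc[e, "power"] >= config.target_power for e in effects):
            return MinNResult(
                n=int(n), reached=True, target_power=config.target_power,
                per_effect={e: (float(sub.loc[e, "power"]),
                                float(sub.loc[e, "mc_se"])) for e in effects})
    n_max = int(f["n"].max())
    sub = f[f["n"] == n_max].set_index("effect")
    return MinNResult(
        n=None, reached=False, target_power=config.target_power,
        per_effect={e: (float(sub.loc[e, "power"]),
                        float(sub.loc[e, "mc_se"])) for e in effects})
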