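"""Simulation-based power analysis for the trial x moderator interaction.

The target effect is expressed as a correlation r between the (z-scored)
moderator and a participant's extinction slope.  With the moderator
standardized, an interaction coefficient b = r * sd_slope and a residual
slope SD of sd_slope * sqrt(1 - r^2) produce exactly that correlation while
holding the marginal slope variance at sd_slope^2.  Each replicate simulates
a study, fits the moderated ordered beta model, and rejects when the
one-sided 95% credible interval for the interaction excludes 0 in the
hypothesized direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .inference import SamplerSettings, fit_model, summarize
from .core_model import ModelSpec
from .synthetic_data import GeneratingParams, ParadigmConfig, simulate_study

__all__ = ["PowerResult", "r_to_coefficient", "estimate_power"]


@dataclass(frozen=True)
class PowerResult:
    n_participants: int
    r: float
    coefficient: float
    replicates: int
    rejections: int
    failures: int
    power: float
    power_ci: tuple[float, float]
    seed: int


def r_to_coefficient(r: float, params: GeneratingParams) -> float:
    """Interaction coefficient giving correlation r between the z-scored
    moderator and the participant-level trial slope: b = r * sd_slope."""
    if not (-1.0 < r < 1.0):
        raise ValueError("r must lie strictly inside (-1, 1)")
    if params.sd_participant_slope <= 0:
        raise ValueError("sd_participant_slope must be > 0 to map r onto a slope")
    return r * params.sd_participant_slope


def _wilson_ci(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def estimate_power(
    n_participants: int,
    r: float,
    params: GeneratingParams = GeneratingParams(),
    n_reps: int = 100,
    seed: int = 0,
    config: ParadigmConfig = ParadigmConfig(),
    settings: SamplerSettings = SamplerSettings(chains=2, warmup=400, draws=400),
    moderator: str = "iu_total",
    direction: str = "greater",
) -> PowerResult:
    """Monte-Carlo power for detecting a trial x moderator interaction.

    ``direction`` is the hypothesized sign of the interaction ("greater"
    for a positive coefficient, i.e. slower extinction with higher
    moderator scores).  Fit failures are counted separately, never silently
    dropped; power is rejections / successful replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    b = r_to_coefficient(r, params)
    sim_params = replace(
        params,
        b_trial_moderator=b,
        sd_participant_slope=params.sd_participant_slope * math.sqrt(1.0 - r**2),
    )
    spec = ModelSpec.named("moderated", moderator=moderator)
    rng = np.random.default_rng(seed)
    rejections = failures = done = 0
    for _ in range(n_reps):
        rep_seed = int(rng.integers(2**31 - 1))
        table = simulate_study(
            n_participants, config=config, params=sim_params, seed=rep_seed,
            phases=("extinction",),
        )
        table = table[table["cs_type"] == "cs_plus"].reset_index(drop=True)
        try:
            fit = fit_model(
                table, spec, settings=settings, seed=rep_seed, check_convergence=False
            )
        except Exception:
            failures += 1
            continue
        done += 1
        row = summarize(fit, one_sided={"b_trial_x_moderator": direction}).loc[
            "b_trial_x_moderator"
        ]
        if direction == "greater":
            rejections += int(row["ci_low"] > 0)
        else:
            rejections += int(row["ci_high"] < 0)
    power = rejections / done if done else float("nan")
    return PowerResult(
        n_participants=n_participants,
        r=r,
        coefficient=b,
        replicates=done,
        rejections=rejections,
        failures=failures,
        power=power,
        power_ci=_wilson_ci(rejections, done),
        seed=seed,
    )
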