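"""Paradigm-faithful synthetic data for the VR fear-conditioning design.

The emulated paradigm: pre-acquisition (2 presentations per CS, no
reinforcement), acquisition (10 per CS, 60% CS+ reinforcement, first trial a
reinforced CS+, no more than two same-CS trials in a row, reinforced trials
get distinct spider paths), one reinforced reacquisition CS+ trial on path 5,
then extinction (20 per CS, never reinforced).

Ratings are drawn from the zero-inflated ordered beta generative model with
crossed random effects: a bivariate participant (intercept, trial-slope)
deviation and a per-trial intercept, combined into the logit-scale predictor
zeta and pushed through the likelihood in :mod:`extbeta.core_model`.  Default
generating values define the package's reference extinction scenario
(intercept 1.88, trial slope -0.24, threshold -2.35, participant SDs
1.04 / 0.19 with correlation -0.49, trial SD 0.20, log-precision log 5):
expectancies start near 0.85 on the response scale, decline
logistically, and the fraction of exact-zero answers grows across the
phase — the signature of instructed fear extinction under a medium
reinforcement rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import CSType, Phase, TRIAL_TABLE_COLUMNS

__all__ = [
    "ParadigmConfig",
    "GeneratingParams",
    "generate_preacquisition_schedule",
    "generate_acquisition_schedule",
    "generate_extinction_schedule",
    "simulate_study",
    "simulate_vas_ratings",
    "save_simulation",
]


@dataclass(frozen=True)
class ParadigmConfig:
    """Trial-schedule constants of the conditioning paradigm."""

    n_pre: int = 2
    n_acq: int = 10
    n_reinforced: int = 6
    n_ext: int = 20
    n_paths: int = 6
    reacq_path: int = 5
    max_run: int = 2

    def __post_init__(self) -> None:
        if self.n_reinforced > self.n_acq:
            raise ValueError("n_reinforced cannot exceed n_acq")
        if self.max_run < 1:
            raise ValueError("max_run must be >= 1")
        if self.n_reinforced > self.n_paths:
            raise ValueError(
                "cannot assign distinct spider paths: n_reinforced > n_paths"
            )
        if not (1 <= self.reacq_path <= self.n_paths):
            raise ValueError("reacq_path must be one of the available paths")


@dataclass(frozen=True)
class GeneratingParams:
    """Ground-truth parameters for the ordered beta generative model."""

    intercept: float = 1.88
    b_trial: float = -0.24
    b_cs: float = 0.0
    b_trial_cs: float = 0.0
    b_moderator: float = 0.0
    b_trial_moderator: float = 0.0
    # threshold on the zero side: theta = sigma(zeta - gamma), so a strongly
    # negative gamma means almost no zeros while expectancies are high and a
    # growing zero fraction as the predictor declines across extinction
    gamma: float = -2.35
    phi: float = math.log(5.0)
    sd_participant_intercept: float = 1.04
    sd_participant_slope: float = 0.19
    cor_intercept_slope: float = -0.49
    sd_trial_intercept: float = 0.20
    moderator_mean: float = 29.70
    moderator_sd: float = 7.28

    def __post_init__(self) -> None:
        for name in ("sd_participant_intercept", "sd_participant_slope", "sd_trial_intercept"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (-1.0 < self.cor_intercept_slope < 1.0):
            raise ValueError("cor_intercept_slope must lie in (-1, 1)")
        if self.moderator_sd < 0:
            raise ValueError("moderator_sd must be >= 0")


# ---------------------------------------------------------------------------
# schedules


def _interleave(rng: np.random.Generator, n_each: int, max_run: int, first_plus: bool) -> list[CSType]:
    """Rejection-sample a CS+/CS- interleaving obeying the run-length rule.

    Uniform over valid sequences: propose a uniformly random shuffle of the
    multiset and accept iff the constraints hold.
    """
    base = np.array([1] * n_each + [0] * n_each)
    for _ in range(100_000):
        seq = rng.permutation(base)
        if first_plus and seq[0] != 1:
            continue
        # longest same-CS run
        runs = np.diff(np.flatnonzero(np.concatenate(([True], np.diff(seq) != 0, [True]))))
        if runs.max() > max_run:
            continue
        return [CSType.CS_PLUS if s else CSType.CS_MINUS for s in seq]
    raise ValueError("no schedule satisfying the constraints was found")


def _stub(phase, trial_index, cs_type, reinforced, spider_path=None) -> dict:
    return {
        "phase": phase.value,
        "trial_index": trial_index,
        "cs_type": cs_type.value,
        "reinforced": reinforced,
        "spider_path": spider_path,
    }


def generate_preacquisition_schedule(config: ParadigmConfig = ParadigmConfig(), seed: int = 0) -> list[dict]:
    """Pre-acquisition: n_pre presentations per CS, no reinforcement."""
    rng = np.random.default_rng(seed)
    seq = _interleave(rng, config.n_pre, config.max_run, first_plus=False)
    counters = {CSType.CS_PLUS: 0, CSType.CS_MINUS: 0}
    out = []
    for cs in seq:
        out.append(_stub(Phase.PRE_ACQUISITION, counters[cs], cs, False))
        counters[cs] += 1
    return out


def generate_acquisition_schedule(config: ParadigmConfig = ParadigmConfig(), seed: int = 0) -> list[dict]:
    """Acquisition: n_acq per CS; first trial a reinforced CS+; 60% default
    reinforcement with distinct spider paths; same-CS runs capped at max_run."""
    rng = np.random.default_rng(seed)
    seq = _interleave(rng, config.n_acq, config.max_run, first_plus=True)
    # first CS+ trial always reinforced; remaining reinforcements drawn at random
    extra = rng.choice(np.arange(1, config.n_acq), size=config.n_reinforced - 1, replace=False)
    reinforced_plus = {0} | {int(i) for i in extra}
    paths = rng.permutation(np.arange(1, config.n_paths + 1))[: config.n_reinforced]
    counters = {CSType.CS_PLUS: 0, CSType.CS_MINUS: 0}
    out, path_i = [], 0
    for cs in seq:
        idx = counters[cs]
        if cs is CSType.CS_PLUS and idx in reinforced_plus:
            out.append(_stub(Phase.ACQUISITION, idx, cs, True, int(paths[path_i])))
            path_i += 1
        else:
            out.append(_stub(Phase.ACQUISITION, idx, cs, False))
        counters[cs] += 1
    return out


def generate_extinction_schedule(config: ParadigmConfig = ParadigmConfig(), seed: int = 0) -> list[dict]:
    """One reinforced reacquisition CS+ trial (fixed spider path) followed by
    n_ext unreinforced presentations per CS."""
    rng = np.random.default_rng(seed)
    out = [_stub(Phase.REACQUISITION, 0, CSType.CS_PLUS, True, config.reacq_path)]
    seq = _interleave(rng, config.n_ext, config.max_run, first_plus=False)
    counters = {CSType.CS_PLUS: 0, CSType.CS_MINUS: 0}
    for cs in seq:
        out.append(_stub(Phase.EXTINCTION, counters[cs], cs, False))
        counters[cs] += 1
    return out


# ---------------------------------------------------------------------------
# ratings


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def _draw_ratings(
    rng: np.random.Generator,
    zeta: np.ndarray,
    gamma: float,
    phi: float,
) -> np.ndarray:
    """Sample unit-interval ratings from the zero-inflated beta model."""
    theta = 1.0 / (1.0 + np.exp(-(zeta - gamma)))
    mu = 1.0 / (1.0 + np.exp(-zeta))
    tau = math.exp(phi)
    cont = rng.beta(mu * tau, (1.0 - mu) * tau)
    # keep continuous draws strictly inside (0, 1): with extreme shape
    # parameters the sampler can round to the boundary in floating point
    cont = np.clip(cont, 1e-9, 1.0 - 1e-9)
    return np.where(rng.random(zeta.shape) < theta, cont, 0.0)


def simulate_study(
    n_participants: int,
    config: ParadigmConfig = ParadigmConfig(),
    params: GeneratingParams = GeneratingParams(),
    seed: int = 0,
    phases: Sequence[str] = ("pre_acquisition", "acquisition", "reacquisition", "extinction"),
) -> pd.DataFrame:
    """Simulate a long-format trial table for ``n_participants``.

    Per participant: a bivariate (intercept, slope) deviation with the given
    SDs and correlation, and one moderator score.  Per phase and trial index:
    a trial-intercept deviation shared across participants.  Per record:
    zeta = intercept + b_trial*t + b_cs*cs + b_trial_cs*t*cs
         + (b_moderator + b_trial_moderator*t) * z-scored moderator
         + u_i0 + u_i1*t + w_t,
    then a rating is drawn from the zero-inflated beta likelihood.  Ratings
    are stored as unit values (``rating_unit``) and as raw integer percents
    (``rating_raw`` = round-half-up of unit*101, clipped to [0, 100]).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    phases = tuple(phases)
    rng = np.random.default_rng(seed)

    # explicit Cholesky construction (robust to zero SDs)
    rho = params.cor_intercept_slope
    z = rng.standard_normal((n_participants, 2))
    u = np.empty_like(z)
    u[:, 0] = params.sd_participant_intercept * z[:, 0]
    u[:, 1] = params.sd_participant_slope * (
        rho * z[:, 0] + math.sqrt(1.0 - rho * rho) * z[:, 1]
    )
    moderator = rng.normal(params.moderator_mean, params.moderator_sd, size=n_participants)
    if n_participants > 1 and np.std(moderator, ddof=1) > 0:
        mod_z = (moderator - moderator.mean()) / np.std(moderator, ddof=1)
    else:
        mod_z = np.zeros(n_participants)
    # plausible questionnaire scores for the remaining columns
    iu_inhib = rng.normal(13.46, 3.82, size=n_participants)
    iu_prosp = rng.normal(16.24, 4.44, size=n_participants)
    stai = rng.normal(41.00, 8.05, size=n_participants)
    spq = rng.normal(18.82, 3.59, size=n_participants)

    rows = []
    for i in range(n_participants):
        pid = f"P{i + 1:03d}"
        schedule: list[dict] = []
        if "pre_acquisition" in phases:
            schedule += generate_preacquisition_schedule(config, seed=int(rng.integers(2**31)))
        if "acquisition" in phases:
            schedule += generate_acquisition_schedule(config, seed=int(rng.integers(2**31)))
        if "reacquisition" in phases or "extinction" in phases:
            ext = generate_extinction_schedule(config, seed=int(rng.integers(2**31)))
            if "reacquisition" not in phases:
                ext = [s for s in ext if s["phase"] != Phase.REACQUISITION.value]
            if "extinction" not in phases:
                ext = [s for s in ext if s["phase"] != Phase.EXTINCTION.value]
            schedule += ext
        for stub in schedule:
            rows.append(
                {
                    "participant_id": pid,
                    **stub,
                    "iu_total": moderator[i],
                    "iu_inhibitory": iu_inhib[i],
                    "iu_prospective": iu_prosp[i],
                    "stai_t": stai[i],
                    "spq": spq[i],
                    "_u0": u[i, 0],
                    "_u1": u[i, 1],
                    "_mod_z": mod_z[i],
                }
            )
    table = pd.DataFrame(rows)

    # per-(phase, trial-index) intercept deviations, shared across participants
    w = {}
    for key in sorted(set(zip(table["phase"], table["trial_index"]))):
        w[key] = rng.normal(0.0, params.sd_trial_intercept)
    table["_w"] = [w[k] for k in zip(table["phase"], table["trial_index"])]

    t = table["trial_index"].to_numpy(dtype=float)
    cs = np.where(table["cs_type"] == CSType.CS_PLUS.value, 0.5, -0.5)
    m = table["_mod_z"].to_numpy()
    zeta = (
        params.intercept
        + params.b_trial * t
        + params.b_cs * cs
        + params.b_trial_cs * t * cs
        + (params.b_moderator + params.b_trial_moderator * t) * m
        + table["_u0"].to_numpy()
        + table["_u1"].to_numpy() * t
        + table["_w"].to_numpy()
    )
    unit = _draw_ratings(rng, zeta, params.gamma, params.phi)
    table["rating_unit"] = unit
    table["rating_raw"] = np.clip(_round_half_up(unit * 101), 0, 100).astype(int)
    table = table.drop(columns=["_u0", "_u1", "_mod_z", "_w"])
    return table[TRIAL_TABLE_COLUMNS + ["rating_unit"]]


def simulate_vas_ratings(
    n_participants: int,
    seed: int = 0,
    means: Optional[dict] = None,
    sds: Optional[dict] = None,
) -> pd.DataFrame:
    """Simple normal draws of post-acquisition CS+/CS- VAS ratings (0-10 scales),
    clipped to the scale, for exercising the manipulation-check statistics."""
    default_means = {
        "cs_plus_fear": 6.46, "cs_minus_fear": 1.51,
        "cs_plus_disgust": 4.83, "cs_minus_disgust": 1.01,
        "cs_plus_valence": 6.33, "cs_minus_valence": 2.09,
    }
    default_sds = {
        "cs_plus_fear": 3.00, "cs_minus_fear": 2.12,
        "cs_plus_disgust": 3.26, "cs_minus_disgust": 1.86,
        "cs_plus_valence": 3.00, "cs_minus_valence": 2.21,
    }
    means = {**default_means, **(means or {})}
    sds = {**default_sds, **(sds or {})}
    rng = np.random.default_rng(seed)
    out = {"participant_id": [f"P{i + 1:03d}" for i in range(n_participants)]}
    for col in default_means:
        out[col] = np.clip(rng.normal(means[col], sds[col], size=n_participants), 0, 10)
    return pd.DataFrame(out)


def save_simulation(
    table: pd.DataFrame,
    path: str | Path,
    config: ParadigmConfig,
    params: GeneratingParams,
    seed: int,
) -> Path:
    """Write the trial table as CSV plus a JSON sidecar with full provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[TRIAL_TABLE_COLUMNS].to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"config": asdict(config), "params": asdict(params), "seed": int(seed)},
            indent=2,
        )
    )
    return sidecar
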