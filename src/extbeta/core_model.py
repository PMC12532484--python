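"""Ordered beta likelihood, link functions, rating preprocessing, and design matrices.

The response model for US-expectancy ratings is a zero-inflated ("ordered")
beta distribution.  A single logit-scale linear predictor ``zeta`` drives both
the probability of a non-zero rating and the mean of the continuous branch:

    theta = sigma(zeta - gamma)        P(rating > 0)
    mu    = sigma(zeta)                mean of the Beta branch
    y = 0             with prob 1 - theta
    y ~ Beta(mu, tau) with prob theta,   tau = exp(phi)

where ``Beta(mu, tau)`` is the mean-precision parameterization
(shape1 = mu*tau, shape2 = (1-mu)*tau) and ``gamma`` is a threshold that
shifts how much probability mass lands on exact zeros.  Raw integer percent
ratings in [0, 100] are mapped to the unit interval by dividing by 101, so no
observation can ever equal 1 and the family needs no one-inflation component.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "Phase",
    "CSType",
    "Rating",
    "OrderedBetaParams",
    "TrialRecord",
    "PriorSet",
    "ModelSpec",
    "TRIAL_TABLE_COLUMNS",
    "logistic",
    "preprocess_ratings",
    "ordered_beta_logdensity",
    "expected_rating",
    "build_linear_predictor",
    "build_design",
    "cs_code",
]

#: column order of the long-format trial table (CSV interface)
TRIAL_TABLE_COLUMNS = [
    "participant_id",
    "phase",
    "trial_index",
    "cs_type",
    "reinforced",
    "spider_path",
    "rating_raw",
    "iu_total",
    "iu_inhibitory",
    "iu_prospective",
    "stai_t",
    "spq",
]

RATING_DIVISOR = 101


class Phase(str, enum.Enum):
    PRE_ACQUISITION = "pre_acquisition"
    ACQUISITION = "acquisition"
    REACQUISITION = "reacquisition"
    EXTINCTION = "extinction"


class CSType(str, enum.Enum):
    CS_PLUS = "cs_plus"
    CS_MINUS = "cs_minus"


def cs_code(cs_type: CSType | str) -> float:
    """Effects coding of the CS: +0.5 for CS+, -0.5 for CS-."""
    cs = CSType(cs_type)
    return 0.5 if cs is CSType.CS_PLUS else -0.5


@dataclass(frozen=True)
class Rating:
    """A single US-expectancy rating, raw percent and unit-interval value.

    ``unit`` is always ``raw / 101`` so that the transformed value is strictly
    below 1; a raw 0 maps to an exact unit 0 (the zero-inflated mass).
    """

    raw: int

    def __post_init__(self) -> None:
        if not (0 <= int(self.raw) <= 100):
            raise ValueError(f"rating_raw must be in [0, 100], got {self.raw!r}")

    @property
    def unit(self) -> float:
        return self.raw / RATING_DIVISOR


@dataclass(frozen=True)
class OrderedBetaParams:
    """Likelihood parameters for one observation.

    zeta : logit-scale linear predictor
    gamma : threshold separating zero vs continuous responses
    phi : log of the Beta precision (precision tau = exp(phi))
    """

    zeta: float
    gamma: float
    phi: float

    def __post_init__(self) -> None:
        for name in ("zeta", "gamma", "phi"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")

    @property
    def theta(self) -> float:
        return float(logistic(self.zeta - self.gamma))

    @property
    def mu(self) -> float:
        return float(logistic(self.zeta))

    @property
    def precision(self) -> float:
        return math.exp(self.phi)


@dataclass(frozen=True)
class TrialRecord:
    """One CS presentation: who, which phase, which trial, CS type, outcome."""

    participant_id: str
    phase: Phase
    trial_index: int
    cs_type: CSType
    reinforced: bool
    rating: Rating
    spider_path: Optional[int] = None
    moderators: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trial_index < 0:
            raise ValueError("trial_index must be non-negative")
        if self.reinforced and self.cs_type is not CSType.CS_PLUS:
            raise ValueError("only CS+ trials can be reinforced")
        if self.phase is Phase.EXTINCTION and self.reinforced:
            raise ValueError("extinction trials are never reinforced")
        if self.spider_path is not None and not (1 <= self.spider_path <= 6):
            raise ValueError("spider_path must be in 1..6")

    @property
    def cs_code(self) -> float:
        return cs_code(self.cs_type)


@dataclass(frozen=True)
class PriorSet:
    """Weakly informative priors on the logit / unit scales.

    All scales are standard deviations and must be strictly positive.  The
    correlation prior is an LKJ concentration applied to the 2x2
    intercept-slope correlation matrix.
    """

    intercept_scale: float = 5.0
    coef_scale: float = 2.5
    gamma_scale: float = 2.5
    phi_scale: float = 2.0
    re_sd_scale: float = 2.5
    lkj_concentration: float = 2.0
    resid_sd_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "intercept_scale",
            "coef_scale",
            "gamma_scale",
            "phi_scale",
            "re_sd_scale",
            "lkj_concentration",
            "resid_sd_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


FIXED_TERMS = ("intercept", "trial", "cs_type", "trial_x_cs", "moderator", "trial_x_moderator")


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect design, random-effect structure, family, and priors.

    Named model specs mirror the analysis pipeline:

    - ``acquisition``: trial + CS type + interaction, both CS types.
    - ``baseline``: trial only, CS+ trials only (extinction).
    - ``moderated``: baseline + moderator main effect + trial x moderator.
    - ``linear``: baseline design under a normal likelihood instead of the
      ordered beta (the model-comparison foil); gamma/phi are replaced by a
      residual SD.
    """

    family: str = "ordered_beta"
    fixed_terms: tuple[str, ...] = ("intercept", "trial")
    moderator_name: Optional[str] = None
    random_participant: tuple[str, ...] = ("intercept", "trial", "correlation")
    random_trial: bool = True
    priors: PriorSet = field(default_factory=PriorSet)

    def __post_init__(self) -> None:
        if self.family not in ("ordered_beta", "linear_normal"):
            raise ValueError(f"unknown family {self.family!r}")
        unknown = set(self.fixed_terms) - set(FIXED_TERMS)
        if unknown:
            raise ValueError(f"unknown fixed terms: {sorted(unknown)}")
        needs_mod = {"moderator", "trial_x_moderator"} & set(self.fixed_terms)
        if needs_mod and self.moderator_name is None:
            raise ValueError("moderator terms require moderator_name")
        if "trial_x_moderator" in self.fixed_terms and "moderator" not in self.fixed_terms:
            raise ValueError("trial_x_moderator requires the moderator main effect")

    @classmethod
    def named(cls, name: str, moderator: Optional[str] = None, priors: Optional[PriorSet] = None) -> "ModelSpec":
        priors = priors or PriorSet()
        if name == "acquisition":
            return cls(fixed_terms=("intercept", "trial", "cs_type", "trial_x_cs"), priors=priors)
        if name == "baseline":
            return cls(fixed_terms=("intercept", "trial"), priors=priors)
        if name == "moderated":
            return cls(
                fixed_terms=("intercept", "trial", "moderator", "trial_x_moderator"),
                moderator_name=moderator or "iu_total",
                priors=priors,
            )
        if name == "linear":
            return cls(family="linear_normal", fixed_terms=("intercept", "trial"), priors=priors)
        raise ValueError(f"unknown model spec name {name!r}")


# ---------------------------------------------------------------------------
# link functions and the likelihood


def logistic(z):
    """Numerically stable logistic function sigma(z) = 1 / (1 + exp(-z))."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("logistic requires finite input")
    out = special.expit(z)
    return float(out) if out.ndim == 0 else out


def preprocess_ratings(raw_ratings: Sequence[int]) -> np.ndarray:
    """Map raw percent ratings in [0, 100] to the unit interval via /101.

    Zeros are preserved exactly; the maximum attainable value is 100/101, so
    the transformed data never reach the upper bound and the likelihood needs
    no one-inflation part.
    """
    raw = np.asarray(raw_ratings, dtype=float)
    bad = ~((raw >= 0) & (raw <= 100))
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"rating out of range at position {idx}: {raw[idx]!r} (must be in [0, 100])"
        )
    return raw / RATING_DIVISOR


# smallest continuous rating the likelihood will evaluate; any realizable
# transformed rating (>= 1/101) is far above this clamp
_Y_EPS = 1e-12


def ordered_beta_logdensity(y, params: OrderedBetaParams):
    """Log-density of the zero-inflated beta at ``y`` in [0, 1).

    y = 0 contributes log(1 - theta); continuous y contributes
    log theta + log Beta(y; mu*tau, (1-mu)*tau).
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y >= 1)):
        raise ValueError("y must lie in [0, 1); the model has no one-inflation part")
    zeta, gamma, phi = params.zeta, params.gamma, params.phi
    # log theta = -softplus(gamma - zeta); log(1-theta) = -softplus(zeta - gamma)
    log_theta = -np.logaddexp(0.0, gamma - zeta)
    log_1m_theta = -np.logaddexp(0.0, zeta - gamma)
    mu = special.expit(zeta)
    tau = math.exp(phi)
    a, b = mu * tau, (1.0 - mu) * tau
    yc = np.clip(y, _Y_EPS, 1.0 - _Y_EPS)
    beta_logpdf = (a - 1.0) * np.log(yc) + (b - 1.0) * np.log1p(-yc) - special.betaln(a, b)
    out = np.where(y == 0.0, log_1m_theta, log_theta + beta_logpdf)
    return float(out) if out.ndim == 0 else out


def expected_rating(params: OrderedBetaParams) -> float:
    """Mean of the zero-inflated distribution on the response scale: theta * mu."""
    return params.theta * params.mu


# ---------------------------------------------------------------------------
# design construction


def moderator_zscore(table: pd.DataFrame, name: str) -> pd.Series:
    """Z-standardize a per-participant moderator across participants.

    Scores are constant within participant; the mean/SD are taken over the
    participant-level values so that repeated trials do not reweight them.
    """
    per_p = table.groupby("participant_id")[name].first()
    if per_p.isna().any():
        missing = per_p[per_p.isna()].index[0]
        raise ValueError(f"moderator {name!r} missing for participant {missing!r}")
    sd = per_p.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"moderator {name!r} has zero variance across participants")
    z = (per_p - per_p.mean()) / sd
    return table["participant_id"].map(z)


def build_design(table: pd.DataFrame, spec: ModelSpec) -> dict:
    """Assemble the arrays a fit needs from a long-format trial table.

    Returns a dict with the fixed-effect matrix ``X`` (n x p, column order =
    spec.fixed_terms), response ``y`` on the unit scale, participant / trial
    integer codes, and the trial covariate used by the random slope.  Trials
    are coded 0-based within phase so the intercept is the expected logit
    rating on the first modeled trial.
    """
    table = table.reset_index(drop=True)
    if "rating_unit" in table.columns:
        # continuous VAS ratings, already on the unit scale (e.g. straight from
        # the simulator) — use them exactly
        y = table["rating_unit"].to_numpy(dtype=float)
        if np.any((y < 0) | (y >= 1)):
            raise ValueError("rating_unit values must lie in [0, 1)")
    else:
        y = preprocess_ratings(table["rating_raw"].to_numpy())
    trial = table["trial_index"].to_numpy(dtype=float)
    cols = []
    for term in spec.fixed_terms:
        if term == "intercept":
            cols.append(np.ones(len(table)))
        elif term == "trial":
            cols.append(trial)
        elif term == "cs_type":
            cols.append(np.array([cs_code(c) for c in table["cs_type"]]))
        elif term == "trial_x_cs":
            cols.append(trial * np.array([cs_code(c) for c in table["cs_type"]]))
        elif term == "moderator":
            cols.append(moderator_zscore(table, spec.moderator_name).to_numpy(dtype=float))
        elif term == "trial_x_moderator":
            cols.append(trial * moderator_zscore(table, spec.moderator_name).to_numpy(dtype=float))
    X = np.column_stack(cols)
    pid_codes, pid_levels = pd.factorize(table["participant_id"], sort=True)
    tid_codes, tid_levels = pd.factorize(table["trial_index"], sort=True)
    return {
        "X": X,
        "y": y,
        "terms": list(spec.fixed_terms),
        "pid": pid_codes.astype(np.int64),
        "participants": list(pid_levels),
        "tid": tid_codes.astype(np.int64),
        "trials": [int(t) for t in tid_levels],
        "trial_cov": trial,
    }


def build_linear_predictor(
    record: TrialRecord,
    spec: ModelSpec,
    fixed: Mapping[str, float],
    participant_effects: Mapping[str, tuple[float, float]],
    trial_effects: Mapping[int, float],
) -> float:
    """Linear predictor zeta for one trial record.

    zeta = sum of fixed-term contributions + participant intercept
    + participant trial-slope x trial index + trial intercept.  CS type enters
    with effects coding (-0.5 / +0.5); the trial covariate is the 0-based
    within-phase index, uncentered, for both the fixed and random slope.
    """
    missing = [t for t in spec.fixed_terms if t not in fixed]
    if missing:
        raise ValueError(f"missing fixed coefficients: {missing}")
    trial = float(record.trial_index)
    zeta = 0.0
    for term in spec.fixed_terms:
        b = fixed[term]
        if term == "intercept":
            zeta += b
        elif term == "trial":
            zeta += b * trial
        elif term == "cs_type":
            zeta += b * record.cs_code
        elif term == "trial_x_cs":
            zeta += b * trial * record.cs_code
        elif term in ("moderator", "trial_x_moderator"):
            if spec.moderator_name not in record.moderators:
                raise ValueError(
                    f"record lacks moderator {spec.moderator_name!r} required by the spec"
                )
            m = record.moderators[spec.moderator_name]
            zeta += b * m * (trial if term == "trial_x_moderator" else 1.0)
    if record.participant_id not in participant_effects:
        raise ValueError(f"no random effects for participant {record.participant_id!r}")
    if record.trial_index not in trial_effects:
        raise ValueError(f"no random effect for trial {record.trial_index!r}")
    u0, u1 = participant_effects[record.participant_id]
    zeta += u0 + u1 * trial + trial_effects[record.trial_index]
    return float(zeta)
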