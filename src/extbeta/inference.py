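"""Bayesian fitting of ordered beta and linear-normal mixed models.

Models share one logit-scale (or identity-scale, for the normal family)
linear predictor

    zeta = X b + u_i0 + u_i1 * trial + w_t

with a bivariate participant deviation (intercept, trial slope; optional
correlation) and a crossed per-trial intercept.  Sampling uses the package's
Hamiltonian Monte Carlo engine on a fully unconstrained, non-centered
parameterization: random effects enter as standard-normal innovations scaled
inside the model, SDs are log-transformed, and the intercept-slope
correlation is tanh-transformed with an LKJ prior.

Weakly informative default priors (logit / unit scale): Normal(0, 5) on the
intercept, Normal(0, 2.5) on other coefficients and the threshold gamma,
Normal(0, 2) on the log-precision phi, half-Normal(0, 2.5) on random-effect
SDs, LKJ(2) on the correlation, half-Normal(0, 1) on the linear family's
residual SD.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import special

from ._hmc import sample_hmc
from .core_model import ModelSpec, build_design

__all__ = [
    "DiagnosticError",
    "PosteriorFit",
    "SamplerSettings",
    "fit_model",
    "summarize",
    "filter_extinction_cs_plus",
]


class DiagnosticError(RuntimeError):
    """Raised when MCMC diagnostics indicate the posterior was not reached."""


@dataclass(frozen=True)
class SamplerSettings:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.85


def filter_extinction_cs_plus(table: pd.DataFrame) -> pd.DataFrame:
    """CS+ extinction trials only — the analysis set for the baseline and
    moderated extinction models."""
    m = (table["phase"] == "extinction") & (table["cs_type"] == "cs_plus")
    return table.loc[m].reset_index(drop=True)


def _softplus(x):
    return np.logaddexp(0.0, x)


def _clamped_tanh(u: float) -> float:
    # keep the correlation strictly inside (-1, 1) so its Cholesky factor
    # and the LKJ density stay finite during extreme trajectories
    return max(-1.0 + 1e-9, min(1.0 - 1e-9, math.tanh(u)))


class _ModelCore:
    """Parameter packing, joint log density, gradient, and predictions."""

    def __init__(self, design: dict, spec: ModelSpec):
        self.spec = spec
        self.X = np.ascontiguousarray(design["X"])
        self.y = np.ascontiguousarray(design["y"])
        self.pid = design["pid"]
        self.tid = design["tid"]
        self.tcov = np.ascontiguousarray(design["trial_cov"])
        self.terms = design["terms"]
        self.n, self.p = self.X.shape
        self.n_p = int(self.pid.max()) + 1 if self.n else 0
        self.n_t = int(self.tid.max()) + 1 if self.n else 0
        self.ordered = spec.family == "ordered_beta"
        rp = spec.random_participant
        self.has_p_int = "intercept" in rp
        self.has_p_slope = "trial" in rp
        self.has_corr = "correlation" in rp and self.has_p_int and self.has_p_slope
        self.has_t = spec.random_trial
        self.zero = self.y == 0.0
        self.pos = ~self.zero
        self.log_y = np.where(self.pos, np.log(np.clip(self.y, 1e-300, None)), 0.0)
        self.log_1my = np.where(self.pos, np.log1p(-self.y), 0.0)

        names = [f"b_{t}" for t in self.terms]
        if self.ordered:
            names += ["gamma", "phi"]
        else:
            names += ["sigma_resid"]
        if self.has_p_int:
            names.append("sd_participant_intercept")
        if self.has_p_slope:
            names.append("sd_participant_slope")
        if self.has_corr:
            names.append("cor_intercept_slope")
        if self.has_t:
            names.append("sd_trial_intercept")
        self.scalar_names = names

        dim = len(names)
        self.off_z0 = dim if self.has_p_int else None
        if self.has_p_int:
            dim += self.n_p
        self.off_z1 = dim if self.has_p_slope else None
        if self.has_p_slope:
            dim += self.n_p
        self.off_zt = dim if self.has_t else None
        if self.has_t:
            dim += self.n_t
        self.dim = dim

        pr = spec.priors
        self.beta_scales = np.array(
            [pr.intercept_scale if t == "intercept" else pr.coef_scale for t in self.terms]
        )

    # -- unpacking helpers ---------------------------------------------------

    def _scalar_slots(self, x):
        """Return dict of scalar unconstrained values by role."""
        out = {"beta": x[: self.p]}
        i = self.p
        if self.ordered:
            out["gamma"], out["phi"] = x[i], x[i + 1]
            i += 2
        else:
            out["log_sigma"] = x[i]
            i += 1
        for flag, key in (
            (self.has_p_int, "log_sd0"),
            (self.has_p_slope, "log_sd1"),
            (self.has_corr, "u_rho"),
            (self.has_t, "log_sdt"),
        ):
            if flag:
                out[key] = x[i]
                i += 1
        return out

    def _random_effects(self, x, s):
        """Constrained participant / trial effects for one draw."""
        u0 = u1 = w = None
        if self.has_p_int:
            z0 = x[self.off_z0 : self.off_z0 + self.n_p]
            u0 = math.exp(s["log_sd0"]) * z0
        if self.has_p_slope:
            z1 = x[self.off_z1 : self.off_z1 + self.n_p]
            sd1 = math.exp(s["log_sd1"])
            if self.has_corr:
                rho = _clamped_tanh(s["u_rho"])
                c = math.sqrt(1.0 - rho * rho)
                z0 = x[self.off_z0 : self.off_z0 + self.n_p]
                u1 = sd1 * (rho * z0 + c * z1)
            else:
                u1 = sd1 * z1
        if self.has_t:
            w = math.exp(s["log_sdt"]) * x[self.off_zt : self.off_zt + self.n_t]
        return u0, u1, w

    def zeta(self, x, include_random: bool = True):
        s = self._scalar_slots(x)
        zeta = self.X @ s["beta"]
        if include_random:
            u0, u1, w = self._random_effects(x, s)
            if u0 is not None:
                zeta = zeta + u0[self.pid]
            if u1 is not None:
                zeta = zeta + u1[self.pid] * self.tcov
            if w is not None:
                zeta = zeta + w[self.tid]
        return zeta

    # -- likelihood ----------------------------------------------------------

    def loglik_pointwise(self, x):
        s = self._scalar_slots(x)
        zeta = self.zeta(x)
        if self.ordered:
            gamma, phi = s["gamma"], s["phi"]
            tau = math.exp(phi)
            mu = special.expit(zeta)
            a, b = mu * tau, (1.0 - mu) * tau
            ll = np.where(
                self.zero,
                -_softplus(zeta - gamma),
                -_softplus(gamma - zeta)
                + (a - 1.0) * self.log_y
                + (b - 1.0) * self.log_1my
                - special.betaln(a, b),
            )
        else:
            sigma = math.exp(s["log_sigma"])
            r = self.y - zeta
            ll = -0.5 * math.log(2 * math.pi) - s["log_sigma"] - 0.5 * (r / sigma) ** 2
        return ll

    def predict(self, x, include_random: bool = True):
        """Response-scale predictions: theta*mu for ordered beta, zeta for linear."""
        s = self._scalar_slots(x)
        zeta = self.zeta(x, include_random=include_random)
        if self.ordered:
            return special.expit(zeta - s["gamma"]) * special.expit(zeta)
        return zeta

    # -- joint log density and gradient ---------------------------------------

    def logpost_and_grad(self, x):
        s = self._scalar_slots(x)
        # bail out of runaway trajectories before exp() can overflow
        extremes = [v for k, v in s.items() if k != "beta"]
        if extremes and max(abs(v) for v in extremes) > 100.0:
            return -np.inf, np.zeros(self.dim)
        beta = s["beta"]
        grad = np.zeros(self.dim)
        lp = 0.0

        # random effects (track pieces for the chain rule)
        u0 = u1 = w = None
        if self.has_p_int:
            z0 = x[self.off_z0 : self.off_z0 + self.n_p]
            sd0 = math.exp(s["log_sd0"])
            u0 = sd0 * z0
        if self.has_p_slope:
            z1 = x[self.off_z1 : self.off_z1 + self.n_p]
            sd1 = math.exp(s["log_sd1"])
            if self.has_corr:
                rho = _clamped_tanh(s["u_rho"])
                c = math.sqrt(1.0 - rho * rho)
                u1 = sd1 * (rho * z0 + c * z1)
            else:
                u1 = sd1 * z1
        if self.has_t:
            zt = x[self.off_zt : self.off_zt + self.n_t]
            sdt = math.exp(s["log_sdt"])
            w = sdt * zt

        zeta = self.X @ beta
        if u0 is not None:
            zeta = zeta + u0[self.pid]
        if u1 is not None:
            zeta = zeta + u1[self.pid] * self.tcov
        if w is not None:
            zeta = zeta + w[self.tid]

        # likelihood and d lp / d zeta
        if self.ordered:
            gamma, phi = s["gamma"], s["phi"]
            tau = math.exp(phi)
            theta = special.expit(zeta - gamma)
            mu = special.expit(zeta)
            a, b = mu * tau, (1.0 - mu) * tau
            ll_zero = -_softplus(zeta - gamma)
            ll_pos = (
                -_softplus(gamma - zeta)
                + (a - 1.0) * self.log_y
                + (b - 1.0) * self.log_1my
                - special.betaln(a, b)
            )
            lp += float(np.sum(np.where(self.zero, ll_zero, ll_pos)))
            dig_ab = special.digamma(a + b)
            ga = np.where(self.pos, self.log_y - special.digamma(a) + dig_ab, 0.0)
            gb = np.where(self.pos, self.log_1my - special.digamma(b) + dig_ab, 0.0)
            dzeta = np.where(
                self.zero,
                -theta,
                (1.0 - theta) + (ga - gb) * tau * mu * (1.0 - mu),
            )
            dgamma = float(np.sum(np.where(self.zero, theta, -(1.0 - theta))))
            dphi = float(np.sum((ga * mu + gb * (1.0 - mu)) * tau))
        else:
            log_sigma = s["log_sigma"]
            sigma = math.exp(log_sigma)
            r = self.y - zeta
            lp += float(
                np.sum(-0.5 * math.log(2 * math.pi) - log_sigma - 0.5 * (r / sigma) ** 2)
            )
            dzeta = r / sigma**2
            dlog_sigma = float(np.sum((r / sigma) ** 2 - 1.0))

        # backprop through the linear predictor
        grad[: self.p] += self.X.T @ dzeta
        i = self.p
        if self.ordered:
            grad[i] += dgamma
            grad[i + 1] += dphi
            i += 2
        else:
            grad[i] += dlog_sigma
            i += 1
        scalar_idx = {}
        for flag, key in (
            (self.has_p_int, "log_sd0"),
            (self.has_p_slope, "log_sd1"),
            (self.has_corr, "u_rho"),
            (self.has_t, "log_sdt"),
        ):
            if flag:
                scalar_idx[key] = i
                i += 1

        if self.has_p_int or self.has_p_slope:
            if self.has_p_int:
                du0 = np.bincount(self.pid, weights=dzeta, minlength=self.n_p)
                grad[self.off_z0 : self.off_z0 + self.n_p] += sd0 * du0
                grad[scalar_idx["log_sd0"]] += float(np.sum(du0 * u0))
            if self.has_p_slope:
                du1 = np.bincount(self.pid, weights=dzeta * self.tcov, minlength=self.n_p)
                grad[scalar_idx["log_sd1"]] += float(np.sum(du1 * u1))
                if self.has_corr:
                    grad[self.off_z0 : self.off_z0 + self.n_p] += sd1 * rho * du1
                    grad[self.off_z1 : self.off_z1 + self.n_p] += sd1 * c * du1
                    drho = sd1 * float(np.sum(du1 * (z0 - (rho / c) * z1)))
                    grad[scalar_idx["u_rho"]] += drho * (1.0 - rho * rho)
                else:
                    grad[self.off_z1 : self.off_z1 + self.n_p] += sd1 * du1
        if self.has_t:
            dw = np.bincount(self.tid, weights=dzeta, minlength=self.n_t)
            grad[self.off_zt : self.off_zt + self.n_t] += sdt * dw
            grad[scalar_idx["log_sdt"]] += float(np.sum(dw * w))

        # priors
        pr = self.spec.priors
        lp += float(np.sum(-0.5 * (beta / self.beta_scales) ** 2))
        grad[: self.p] += -beta / self.beta_scales**2
        j = self.p
        if self.ordered:
            lp += -0.5 * (s["gamma"] / pr.gamma_scale) ** 2
            grad[j] += -s["gamma"] / pr.gamma_scale**2
            lp += -0.5 * (s["phi"] / pr.phi_scale) ** 2
            grad[j + 1] += -s["phi"] / pr.phi_scale**2
        else:
            # half-Normal on sigma, log parameterization (jacobian term included)
            lp += -0.5 * (sigma / pr.resid_sd_scale) ** 2 + log_sigma
            grad[j] += -(sigma / pr.resid_sd_scale) ** 2 + 1.0
        for key, sd_val in (
            ("log_sd0", math.exp(s["log_sd0"]) if self.has_p_int else None),
            ("log_sd1", math.exp(s["log_sd1"]) if self.has_p_slope else None),
            ("log_sdt", math.exp(s["log_sdt"]) if self.has_t else None),
        ):
            if sd_val is not None:
                lp += -0.5 * (sd_val / pr.re_sd_scale) ** 2 + s[key]
                grad[scalar_idx[key]] += -((sd_val / pr.re_sd_scale) ** 2) + 1.0
        if self.has_corr:
            # LKJ(conc) density on rho plus the tanh jacobian
            lp += pr.lkj_concentration * math.log1p(-(rho * rho))
            grad[scalar_idx["u_rho"]] += -2.0 * pr.lkj_concentration * rho
        for off, size in ((self.off_z0, self.n_p), (self.off_z1, self.n_p), (self.off_zt, self.n_t)):
            if off is not None:
                z = x[off : off + size]
                lp += float(np.sum(-0.5 * z * z))
                grad[off : off + size] += -z
        return lp, grad

    def constrain_scalars(self, x) -> dict:
        """Named, constrained scalar parameter values for one draw."""
        s = self._scalar_slots(x)
        out = {}
        for name, val in zip([f"b_{t}" for t in self.terms], s["beta"]):
            out[name] = float(val)
        if self.ordered:
            out["gamma"], out["phi"] = float(s["gamma"]), float(s["phi"])
        else:
            out["sigma_resid"] = math.exp(s["log_sigma"])
        if self.has_p_int:
            out["sd_participant_intercept"] = math.exp(s["log_sd0"])
        if self.has_p_slope:
            out["sd_participant_slope"] = math.exp(s["log_sd1"])
        if self.has_corr:
            out["cor_intercept_slope"] = _clamped_tanh(s["u_rho"])
        if self.has_t:
            out["sd_trial_intercept"] = math.exp(s["log_sdt"])
        return out


@dataclass
class PosteriorFit:
    """Posterior draws, diagnostics, and everything model comparison needs."""

    spec: ModelSpec
    draws: dict                      # scalar name -> (chains, draws)
    participant_effects: dict        # name -> (chains, draws, n_participants)
    trial_effects: Optional[np.ndarray]  # (chains, draws, n_trials) or None
    unconstrained: np.ndarray        # (chains, draws, dim)
    log_lik: np.ndarray              # (chains, draws, n_obs)
    diagnostics: dict
    n_divergent: int
    seed: int
    data_fingerprint: str
    settings: SamplerSettings
    _core: _ModelCore = field(repr=False)

    @property
    def y(self) -> np.ndarray:
        return self._core.y

    @property
    def n_obs(self) -> int:
        return self._core.n

    @property
    def param_names(self) -> list:
        return list(self._core.scalar_names)

    def stacked(self, name: str) -> np.ndarray:
        """All draws of a scalar parameter, chains flattened."""
        return self.draws[name].reshape(-1)

    def logpost(self, x: np.ndarray) -> float:
        """Unnormalized joint log density (likelihood x priors, unconstrained
        scale, jacobians included) — the bridge-sampling target."""
        return self._core.logpost_and_grad(np.asarray(x, dtype=float))[0]

    def flat_unconstrained(self) -> np.ndarray:
        return self.unconstrained.reshape(-1, self.unconstrained.shape[-1])

    def predictions(self, include_random: bool = True) -> np.ndarray:
        """(total draws, n_obs) response-scale predictions."""
        flat = self.flat_unconstrained()
        return np.stack([self._core.predict(x, include_random) for x in flat])

    def to_inference_data(self):
        import arviz as az

        posterior = {k: v for k, v in self.draws.items()}
        return az.from_dict(
            posterior=posterior,
            log_likelihood={"y": self.log_lik},
        )


def _initial_point(core: _ModelCore, rng: np.random.Generator) -> np.ndarray:
    x0 = rng.normal(0.0, 0.1, size=core.dim)
    i = core.p
    if core.ordered:
        x0[i + 1] = math.log(5.0) + rng.normal(0, 0.1)  # phi
        i += 2
    else:
        x0[i] = math.log(0.3) + rng.normal(0, 0.1)  # residual SD
        i += 1
    # start RE SDs modest so early trajectories stay stable; correlation near 0
    for flag, is_corr in (
        (core.has_p_int, False),
        (core.has_p_slope, False),
        (core.has_corr, True),
        (core.has_t, False),
    ):
        if flag:
            x0[i] = rng.normal(0.0, 0.1) if is_corr else math.log(0.5) + rng.normal(0, 0.1)
            i += 1
    return x0


def fit_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    settings: SamplerSettings = SamplerSettings(),
    seed: int = 0,
    check_convergence: bool = True,
) -> PosteriorFit:
    """Fit a model spec to a long-format trial table by HMC.

    Retains the per-observation log-likelihood matrix (for PSIS-LOO) and the
    unconstrained draws (for bridge sampling).  Raises
    :class:`DiagnosticError` when split-R-hat exceeds 1.05 on any fixed
    effect; warns on divergences or low effective sample size.
    """
    if len(data) == 0:
        raise ValueError("data is empty")
    design = build_design(data, spec)
    if np.any((design["y"] < 0) | (design["y"] >= 1)):
        raise ValueError("preprocessed ratings must lie in [0, 1)")
    core = _ModelCore(design, spec)
    rng = np.random.default_rng(seed)
    chain_seeds = rng.integers(0, 2**31 - 1, size=settings.chains)

    chains_samples = []
    n_div = 0
    for cs in chain_seeds:
        crng = np.random.default_rng(int(cs))
        x0 = _initial_point(core, crng)
        res = sample_hmc(
            core.logpost_and_grad,
            x0,
            n_warmup=settings.warmup,
            n_samples=settings.draws,
            seed=int(cs),
            target_accept=settings.target_accept,
        )
        chains_samples.append(res.samples)
        n_div += int(res.divergent.sum())
    unconstrained = np.stack(chains_samples)  # (chains, draws, dim)

    # constrained scalar draws
    draws: dict[str, np.ndarray] = {
        name: np.empty((settings.chains, settings.draws)) for name in core.scalar_names
    }
    log_lik = np.empty((settings.chains, settings.draws, core.n))
    u0_draws = np.empty((settings.chains, settings.draws, core.n_p)) if core.has_p_int else None
    u1_draws = np.empty((settings.chains, settings.draws, core.n_p)) if core.has_p_slope else None
    w_draws = np.empty((settings.chains, settings.draws, core.n_t)) if core.has_t else None
    for c in range(settings.chains):
        for d in range(settings.draws):
            x = unconstrained[c, d]
            for name, val in core.constrain_scalars(x).items():
                draws[name][c, d] = val
            log_lik[c, d] = core.loglik_pointwise(x)
            s = core._scalar_slots(x)
            u0, u1, w = core._random_effects(x, s)
            if u0_draws is not None:
                u0_draws[c, d] = u0
            if u1_draws is not None:
                u1_draws[c, d] = u1
            if w_draws is not None:
                w_draws[c, d] = w

    participant_effects = {}
    if u0_draws is not None:
        participant_effects["intercept"] = u0_draws
    if u1_draws is not None:
        participant_effects["trial_slope"] = u1_draws

    fixed_names = [f"b_{t}" for t in core.terms]
    diagnostics = _diagnose(draws, fixed_names, settings.chains)
    fp = hashlib.sha256(core.y.tobytes() + core.X.tobytes()).hexdigest()[:16]

    fit = PosteriorFit(
        spec=spec,
        draws=draws,
        participant_effects=participant_effects,
        trial_effects=w_draws,
        unconstrained=unconstrained,
        log_lik=log_lik,
        diagnostics=diagnostics,
        n_divergent=n_div,
        seed=seed,
        data_fingerprint=fp,
        settings=settings,
        _core=core,
    )
    if n_div > 0:
        warnings.warn(f"{n_div} divergent transitions after warmup", RuntimeWarning)
    low_ess = {k: v for k, v in diagnostics["ess"].items() if v < 100}
    if low_ess:
        warnings.warn(f"low effective sample size: {low_ess}", RuntimeWarning)
    if check_convergence and settings.chains >= 2:
        bad = {
            k: round(v, 3)
            for k, v in diagnostics["rhat"].items()
            if k in fixed_names and v > 1.05
        }
        if bad:
            raise DiagnosticError(f"split R-hat > 1.05 for fixed effects: {bad}")
    return fit


def _diagnose(draws: dict, fixed_names: list, chains: int) -> dict:
    import arviz as az

    rhat, ess = {}, {}
    for name, arr in draws.items():
        da = az.convert_to_dataset({name: arr})
        if chains >= 2:
            rhat[name] = float(az.rhat(da)[name].values)
        else:
            rhat[name] = float("nan")
        ess[name] = float(az.ess(da)[name].values)
    return {"rhat": rhat, "ess": ess}


def summarize(
    fit: PosteriorFit,
    one_sided: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Posterior means and 95% intervals for the scalar parameters.

    ``one_sided`` maps parameter names to "greater" ([5th pct, inf)) or
    "less" ((-inf, 95th pct]); all other parameters get central two-sided
    intervals.  ``excludes_zero`` flags intervals not containing 0.
    """
    one_sided = dict(one_sided or {})
    unknown = set(one_sided) - set(fit.param_names)
    if unknown:
        raise ValueError(f"unknown parameters in direction map: {sorted(unknown)}")
    rows = []
    for name in fit.param_names:
        x = fit.stacked(name)
        direction = one_sided.get(name)
        if direction == "greater":
            lo, hi = float(np.quantile(x, 0.05)), math.inf
        elif direction == "less":
            lo, hi = -math.inf, float(np.quantile(x, 0.95))
        elif direction is None:
            lo, hi = (float(q) for q in np.quantile(x, [0.025, 0.975]))
        else:
            raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
        rows.append(
            {
                "parameter": name,
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)),
                "ci_low": lo,
                "ci_high": hi,
                "excludes_zero": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
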