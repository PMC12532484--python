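"""Model-comparison machinery: Bayesian R-squared, PSIS-LOO, Bayes factors,
and posterior predictive density overlays.

R-squared uses the residual-based Bayesian formulation
``var(pred) / (var(pred) + var(y - pred))`` per posterior draw, which is
defined for any response family.  Conditional R2 includes the fitted random
effects in the predictions; marginal R2 uses the fixed effects only.

LOO comes from arviz's Pareto-smoothed importance sampling on the retained
per-observation log-likelihood matrix.  Bayes factors are ratios of marginal
likelihoods estimated by iterative (Meng-Wong optimal) bridge sampling with
a moment-matched multivariate-normal proposal on the unconstrained scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from scipy.stats import gaussian_kde

from .inference import DiagnosticError, PosteriorFit, SamplerSettings, fit_model

__all__ = [
    "R2Result",
    "LooResult",
    "BridgeResult",
    "PPCOverlay",
    "ComparisonReport",
    "bayes_r2",
    "elpd_loo",
    "compare_elpd",
    "exact_loo",
    "log_marginal_likelihood",
    "bayes_factor",
    "ppc_overlay",
    "compare_models",
]


@dataclass(frozen=True)
class R2Result:
    mean: float
    ci_low: float
    ci_high: float
    draws: np.ndarray

    def __repr__(self) -> str:  # keep the draws out of the console
        return f"R2Result(mean={self.mean:.3f}, ci=[{self.ci_low:.3f}, {self.ci_high:.3f}])"


@dataclass(frozen=True)
class LooResult:
    elpd: float
    se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray

    @property
    def n_high_k(self) -> int:
        return int(np.sum(self.pareto_k > 0.7))


@dataclass(frozen=True)
class BridgeResult:
    log_ml: float
    error: float
    n_iterations: int


@dataclass(frozen=True)
class PPCOverlay:
    grid: np.ndarray
    empirical_density: np.ndarray
    replicate_densities: np.ndarray   # (n_draws, len(grid))
    replicates: np.ndarray            # (n_draws, n_obs)
    empirical_zero_fraction: float
    replicate_zero_fractions: np.ndarray


@dataclass(frozen=True)
class ComparisonReport:
    r2_conditional_a: R2Result
    r2_marginal_a: R2Result
    r2_conditional_b: R2Result
    r2_marginal_b: R2Result
    delta_elpd: float
    delta_elpd_se: float
    bayes_factor_ab: float
    log_bayes_factor_ab: float


def bayes_r2(fit: PosteriorFit, include_random: bool = True) -> R2Result:
    """Residual-based Bayesian R2, mean and central 95% interval over draws."""
    pred = fit.predictions(include_random=include_random)  # (S, n)
    resid = fit.y[None, :] - pred
    var_pred = pred.var(axis=1)
    var_resid = resid.var(axis=1)
    denom = var_pred + var_resid
    if np.all(denom == 0):
        raise ValueError("R2 undefined: predictions and residuals have zero variance")
    r2 = np.where(denom > 0, var_pred / np.where(denom > 0, denom, 1.0), 0.0)
    lo, hi = np.quantile(r2, [0.025, 0.975])
    return R2Result(float(r2.mean()), float(lo), float(hi), r2)


def elpd_loo(fit: PosteriorFit) -> LooResult:
    """PSIS-LOO expected log pointwise predictive density (higher is better)."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(fit.to_inference_data(), pointwise=True)
    return LooResult(
        elpd=float(res.elpd_loo),
        se=float(res.se),
        pointwise=np.asarray(res.loo_i.values),
        pareto_k=np.asarray(res.pareto_k.values),
    )


def compare_elpd(fit_a: PosteriorFit, fit_b: PosteriorFit) -> tuple[float, float]:
    """Pairwise ELPD difference (a minus b) with its paired standard error."""
    if fit_a.n_obs != fit_b.n_obs or not np.allclose(fit_a.y, fit_b.y):
        raise ValueError("fits must be on identical observations")
    da = elpd_loo(fit_a).pointwise
    db = elpd_loo(fit_b).pointwise
    diff = da - db
    n = diff.size
    return float(diff.sum()), float(math.sqrt(n * diff.var(ddof=1))) if n > 1 else 0.0


def exact_loo(
    data,
    spec,
    settings: SamplerSettings = SamplerSettings(chains=2, warmup=400, draws=400),
    seed: int = 0,
) -> float:
    """Brute-force leave-one-out elpd: refit the model without each
    observation and average the held-out predictive density over the draws.
    Only feasible for small data sets; the oracle against which PSIS-LOO is
    validated."""
    data = data.reset_index(drop=True)
    n = len(data)
    total = 0.0
    for i in range(n):
        rest = data.drop(index=i)
        fit = fit_model(rest, spec, settings=settings, seed=seed + i, check_convergence=False)
        held = data.iloc[[i]]
        # evaluate the held-out log predictive density under each draw
        from .core_model import build_design

        design_i = build_design(held, spec)
        lls = _held_out_loglik(fit, design_i)
        total += float(logsumexp(lls) - math.log(lls.size))
    return total


def _held_out_loglik(fit: PosteriorFit, design_i: dict) -> np.ndarray:
    """Log-likelihood of one held-out observation under every posterior draw.

    Supports designs without random-effect lookup for new units only when the
    fit itself has no random effects (the exact-LOO oracle runs on flat
    models); with random effects the held-out unit's effect would be unknown.
    """
    core = fit._core
    if core.has_p_int or core.has_p_slope or core.has_t:
        raise ValueError("exact LOO oracle supports fixed-effects-only specs")
    y = design_i["y"]
    X = design_i["X"]
    from scipy import special as sp

    flat = fit.flat_unconstrained()
    out = np.empty(flat.shape[0])
    for j, x in enumerate(flat):
        s = core._scalar_slots(x)
        zeta = float((X @ s["beta"])[0])
        if core.ordered:
            tau = math.exp(s["phi"])
            mu = sp.expit(zeta)
            if y[0] == 0.0:
                out[j] = -np.logaddexp(0.0, zeta - s["gamma"])
            else:
                a, b = mu * tau, (1 - mu) * tau
                out[j] = (
                    -np.logaddexp(0.0, s["gamma"] - zeta)
                    + (a - 1) * math.log(y[0])
                    + (b - 1) * math.log1p(-y[0])
                    - sp.betaln(a, b)
                )
        else:
            sigma = math.exp(s["log_sigma"])
            out[j] = -0.5 * math.log(2 * math.pi) - s["log_sigma"] - 0.5 * ((y[0] - zeta) / sigma) ** 2
    return out


# ---------------------------------------------------------------------------
# bridge sampling


def log_marginal_likelihood(
    fit: PosteriorFit,
    n_proposal: Optional[int] = None,
    seed: int = 0,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> BridgeResult:
    """Marginal likelihood by iterative bridge sampling.

    Posterior draws are split in half: the first half moment-matches a
    multivariate-normal proposal, the second half enters the bridge
    estimator together with fresh proposal samples.  All arithmetic is on
    the log scale.  The error estimate is the spread of the estimator over
    split-half recomputations.
    """
    rng = np.random.default_rng(seed)
    draws = fit.flat_unconstrained()
    S = draws.shape[0]
    half = S // 2
    perm = rng.permutation(S)
    fit_half, est_half = draws[perm[:half]], draws[perm[half:]]

    mean = fit_half.mean(axis=0)
    cov = np.cov(fit_half.T)
    cov = np.atleast_2d(cov) + 1e-8 * np.eye(mean.size)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        chol = np.diag(np.sqrt(np.clip(np.diag(cov), 1e-12, None)))
    n2 = n_proposal or est_half.shape[0]
    prop = mean + rng.standard_normal((n2, mean.size)) @ chol.T

    logdet = 2.0 * np.sum(np.log(np.diag(chol)))

    def log_q(xs):
        diff = xs - mean
        sol = solve_triangular(chol, diff.T, lower=True).T
        return -0.5 * (mean.size * math.log(2 * math.pi) + logdet + np.sum(sol**2, axis=1))

    l1 = np.array([fit.logpost(x) for x in est_half]) - log_q(est_half)   # posterior draws
    l2 = np.array([fit.logpost(x) for x in prop]) - log_q(prop)           # proposal draws

    log_r, n_it = _bridge_iterate(l1, l2, tol, max_iter)
    if n_it >= max_iter:
        raise DiagnosticError("bridge sampling did not converge")

    # split-half error estimate
    halves = []
    for sl in (slice(0, l1.size // 2), slice(l1.size // 2, None)):
        lr, _ = _bridge_iterate(l1[sl], l2[sl], tol, max_iter)
        halves.append(lr)
    err = float(abs(halves[0] - halves[1]) / 2.0)
    return BridgeResult(float(log_r), err, n_it)


def _bridge_iterate(l1: np.ndarray, l2: np.ndarray, tol: float, max_iter: int):
    n1, n2 = l1.size, l2.size
    ls1, ls2 = math.log(n1 / (n1 + n2)), math.log(n2 / (n1 + n2))
    log_r = (np.median(l1) + np.median(l2)) / 2.0  # warm start between the two
    for it in range(max_iter):
        num = logsumexp(l2 - np.logaddexp(ls1 + l2, ls2 + log_r)) - math.log(n2)
        den = logsumexp(-np.logaddexp(ls1 + l1, ls2 + log_r)) - math.log(n1)
        log_r_new = num - den
        if abs(log_r_new - log_r) < tol:
            return float(log_r_new), it + 1
        log_r = log_r_new
    return float(log_r), max_iter


def bayes_factor(fit_a: PosteriorFit, fit_b: PosteriorFit, seed: int = 0) -> tuple[float, BridgeResult, BridgeResult]:
    """Bayes factor of model A over model B via bridge-sampled marginal
    likelihoods; returns (BF_AB, bridge_a, bridge_b)."""
    ml_a = log_marginal_likelihood(fit_a, seed=seed)
    ml_b = log_marginal_likelihood(fit_b, seed=seed + 1)
    return math.exp(ml_a.log_ml - ml_b.log_ml), ml_a, ml_b


# ---------------------------------------------------------------------------
# posterior predictive overlays


def ppc_overlay(fit: PosteriorFit, n_draws: int = 100, seed: int = 0, grid_size: int = 256) -> PPCOverlay:
    """Density overlay data: the empirical marginal rating density and
    ``n_draws`` posterior predictive replicates of the full data set.

    Replicates condition on the fitted random effects (the observed sample's
    participants and trials).  Ordered beta replicates live in [0, 1);
    linear-normal replicates can fall outside the scale, which is part of
    what the overlay is meant to show.
    """
    flat = fit.flat_unconstrained()
    S = flat.shape[0]
    if n_draws > S:
        raise ValueError(f"n_draws={n_draws} exceeds available posterior draws ({S})")
    rng = np.random.default_rng(seed)
    pick = rng.choice(S, size=n_draws, replace=False)
    core = fit._core
    reps = np.empty((n_draws, core.n))
    for k, idx in enumerate(pick):
        x = flat[idx]
        s = core._scalar_slots(x)
        zeta = core.zeta(x)
        if core.ordered:
            from scipy.special import expit

            theta = expit(zeta - s["gamma"])
            mu = expit(zeta)
            tau = math.exp(s["phi"])
            # keep continuous draws strictly inside (0, 1); extreme shapes can
            # round to the boundary in floating point
            cont = np.clip(rng.beta(mu * tau, (1 - mu) * tau), 1e-9, 1 - 1e-9)
            reps[k] = np.where(rng.random(core.n) < theta, cont, 0.0)
        else:
            sigma = math.exp(s["log_sigma"])
            reps[k] = rng.normal(zeta, sigma)
    lo = min(0.0, reps.min()) - 0.05
    hi = max(1.0, reps.max()) + 0.05
    grid = np.linspace(lo, hi, grid_size)
    emp_density = gaussian_kde(fit.y)(grid)
    rep_density = np.stack([gaussian_kde(r)(grid) for r in reps])
    return PPCOverlay(
        grid=grid,
        empirical_density=emp_density,
        replicate_densities=rep_density,
        replicates=reps,
        empirical_zero_fraction=float(np.mean(fit.y == 0)),
        replicate_zero_fractions=np.mean(reps == 0, axis=1),
    )


def compare_models(fit_a: PosteriorFit, fit_b: PosteriorFit, seed: int = 0) -> ComparisonReport:
    """Full pairwise comparison: R2 (conditional and marginal), paired
    ELPD difference, and the bridge-sampling Bayes factor of A over B."""
    d_elpd, d_se = compare_elpd(fit_a, fit_b)
    bf, ml_a, ml_b = bayes_factor(fit_a, fit_b, seed=seed)
    return ComparisonReport(
        r2_conditional_a=bayes_r2(fit_a, include_random=True),
        r2_marginal_a=bayes_r2(fit_a, include_random=False),
        r2_conditional_b=bayes_r2(fit_b, include_random=True),
        r2_marginal_b=bayes_r2(fit_b, include_random=False),
        delta_elpd=d_elpd,
        delta_elpd_se=d_se,
        bayes_factor_ab=bf,
        log_bayes_factor_ab=ml_a.log_ml - ml_b.log_ml,
    )
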