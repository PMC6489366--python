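"""Hierarchical Bayesian inference of PSK model parameters from loss curves.

The generative model: each replicate r has its own parameters on
transformed scales,

    logit(lambda_r) = mu_lam + sigma_lam * z_lam_r,    z ~ N(0, 1)
    log(gamma_r)    = mu_gam + sigma_gam * z_gam_r
    logit(omega_r)  = mu_om  + sigma_om  * z_om_r      (TA / bacteriocin)

(a non-centered parameterization), population means carry weakly
informative normal priors and population scales half-normal priors.
Observed per-passage fractions are scored under a Beta observation model
with mean equal to the deterministic model fraction and an inferred
precision phi, which absorbs day-to-day overdispersion beyond counting
noise.  Observed fractions of exactly 0 or 1 are mapped into the open
interval by eps = 1/(2 * n_events).

Because a loss curve constrains only the exponent gap 1 - gamma(1-lambda)
and the surviving influx lambda*gamma*(1-omega), the posterior carries a
long curved ridge between the loss probability and the killing efficacy.
Sampling therefore uses adaptive parallel tempering (several independent
tempered replicas, each with a ladder of likelihood-tempered rungs and
neighbour swaps): the near-prior rungs traverse the ridge freely and feed
de-correlated states to the cold rung.  Convergence is assessed by the
potential scale reduction factor across replicas and parameter
identifiability by the prior-posterior overlap coefficient (high overlap =
the data carried little information, as for the loss probability when no
loss is observed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betainc, betaln, expit, logit

from .model import Mechanism, PSKParams
from .passaging import LossCurve, PassagingProtocol, simulate_loss_curve

__all__ = [
    "PriorSpec",
    "SamplerSettings",
    "PosteriorSummary",
    "log_likelihood",
    "fit_hierarchical",
    "fit_competition",
    "posterior_predictive",
]

#: prior-posterior overlap above this flags a parameter as non-identifiable
OVERLAP_THRESHOLD = 0.35

#: potential-scale-reduction threshold for accepting convergence
RHAT_THRESHOLD = 1.01

_F_FLOOR = 1e-12  # numerical floor for model fractions


@dataclass(frozen=True)
class PriorSpec:
    """Priors on the transformed scales (location, scale) / half-scales.

    Defaults are weakly informative: logit lambda centred at -6 (a loss
    probability of ~2.5e-3, between low- and high-copy plasmids) and wide;
    log gamma centred at 0 (no burden); logit omega centred at 0 (killing a
    coin flip); log precision centred at ~150 events-worth of noise.
    """

    lambda_mean: tuple[float, float] = (-6.0, 2.5)
    lambda_scale: float = 1.0
    gamma_mean: tuple[float, float] = (0.0, 0.5)
    gamma_scale: float = 0.3
    # killing efficacies of interest span survival probabilities from ~0.5
    # down to below 1e-4 (logit omega ~ 10), so the population-mean prior
    # must be wide on the logit scale to avoid excluding strong killers
    omega_mean: tuple[float, float] = (0.0, 4.0)
    omega_scale: float = 1.0
    log_precision: tuple[float, float] = (5.0, 2.0)

    def __post_init__(self) -> None:
        for loc, scale in (self.lambda_mean, self.gamma_mean, self.omega_mean, self.log_precision):
            if scale <= 0:
                raise ValueError("prior scales must be > 0")
        if min(self.lambda_scale, self.gamma_scale, self.omega_scale) <= 0:
            raise ValueError("half-normal scales must be > 0")


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC effort settings.

    ``n_chains`` independent tempered replicas are run; ``n_steps`` sets
    the overall sampling effort (each unit corresponds to roughly twenty
    tempering sweeps, a scale chosen so the defaults behave like a
    conventional per-chain step count) and ``n_burn`` its warm-up share.
    """

    n_chains: int = 4
    n_steps: int = 1500
    n_burn: int = 500

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.n_burn >= self.n_steps:
            raise ValueError("n_burn must be < n_steps")


@dataclass
class PosteriorSummary:
    """Posterior draws, summaries and diagnostics for one fit."""

    mechanism: Mechanism
    n_replicates: int
    draws: dict[str, np.ndarray]  # name -> (chain, draw)
    summary: pd.DataFrame  # per-parameter median, CI, rhat, ess, overlap, flag
    replicate_summary: pd.DataFrame
    converged: bool
    max_rhat: float
    seed: int | None
    settings: SamplerSettings
    priors: PriorSpec
    protocol: PassagingProtocol | None = None
    acceptance_fraction: float = float("nan")

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        d = self.draws[name].ravel()
        a = (1.0 - level) / 2.0
        return float(np.quantile(d, a)), float(np.quantile(d, 1.0 - a))

    def median(self, name: str) -> float:
        return float(np.median(self.draws[name]))

    def non_identifiable(self) -> list[str]:
        s = self.summary
        return list(s.loc[~s["identifiable"], "parameter"])


# ---------------------------------------------------------------------------
# forward model and likelihood
# ---------------------------------------------------------------------------


def _model_fractions(
    lam: np.ndarray,
    gam: np.ndarray,
    om: np.ndarray,
    mechanism: Mechanism,
    tau_grid: np.ndarray,
    initial_fraction: float,
) -> np.ndarray:
    """Vectorised model fraction at each cumulative time in ``tau_grid``.

    lam/gam/om broadcast together (e.g. (n_walkers, R)); returns an array of
    shape broadcast_shape + (len(tau_grid),).  Works with the plasmid-free
    to plasmid-bearing ratio, which is stable for long times.
    """
    a_plus = gam * (1.0 - lam)
    if mechanism is Mechanism.BACTERIOCIN:
        a_minus = 1.0 - 2.0 * om
        b = lam * gam
    else:
        a_minus = np.ones_like(a_plus)
        b = lam * gam * (1.0 - om)
    delta = (a_minus - a_plus)[..., None]
    bb = b[..., None]
    tau = tau_grid.reshape((1,) * (delta.ndim - 1) + (-1,))
    r0 = (1.0 - initial_fraction) / max(initial_fraction, _F_FLOOR)
    small = np.abs(delta) < 1e-10
    with np.errstate(over="ignore", invalid="ignore"):
        edt = np.exp(delta * tau)
        ratio = r0 * edt + bb * (edt - 1.0) / np.where(small, 1.0, delta)
    ratio = np.where(np.broadcast_to(small, ratio.shape), r0 + bb * tau, ratio)
    ratio = np.where(np.isnan(ratio), np.inf, ratio)
    with np.errstate(over="ignore"):
        frac = 1.0 / (1.0 + ratio)
    if initial_fraction <= _F_FLOOR:
        frac = np.zeros_like(frac)
    return frac


def _clip_eps(n_events: np.ndarray | None) -> np.ndarray | float:
    if n_events is None:
        return 1e-4
    n = np.asarray(n_events, dtype=float)
    return np.where(n > 0, 1.0 / (2.0 * np.maximum(n, 1.0)), 1e-4)


def _prepare_observations(curves: list[LossCurve]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack curves into (R, P) arrays of fractions and boundary epsilons."""
    passages = curves[0].passage
    for c in curves[1:]:
        if not np.array_equal(c.passage, passages):
            raise ValueError("all curves must share the same passage grid")
    obs = np.stack([c.fraction for c in curves])
    eps = np.stack(
        [
            np.broadcast_to(np.asarray(_clip_eps(c.n_events), dtype=float), c.fraction.shape)
            for c in curves
        ]
    )
    return np.asarray(passages, dtype=float), obs, eps


class _CensoredBetaCache:
    """Precomputed censoring layout for repeated Beta-likelihood evaluation.

    A fraction estimated from n events cannot resolve values closer to the
    boundary than eps = 1/(2n), so observations at or beyond [eps, 1 - eps]
    are scored as interval-censored tail probabilities (Beta CDF/SF at the
    bound) rather than as exact interior values; interior observations are
    scored by the Beta log-density.
    """

    def __init__(self, obs: np.ndarray, eps: np.ndarray):
        eps_b = np.broadcast_to(eps, obs.shape)
        self.lo = obs <= eps_b
        self.hi = obs >= 1.0 - eps_b
        self.mid = ~(self.lo | self.hi)
        obs_m = obs[self.mid]
        self.log_obs_m = np.log(obs_m)
        self.log1m_obs_m = np.log1p(-obs_m)
        self.eps_lo = eps_b[self.lo]
        self.eps_hi = eps_b[self.hi]
        self.any_lo = bool(self.lo.any())
        self.any_hi = bool(self.hi.any())

    def loglik(self, f_model: np.ndarray, phi) -> np.ndarray:
        """Censored Beta(F*phi, (1-F)*phi) log probability, summed per row.

        ``f_model`` has the observation array's shape with extra leading
        axes; phi broadcasts over those leading axes.
        """
        f = np.clip(f_model, _F_FLOOR, 1.0 - _F_FLOOR)
        alpha = f * phi
        beta = (1.0 - f) * phi
        a_m, b_m = alpha[..., self.mid], beta[..., self.mid]
        total = (
            (a_m - 1.0) * self.log_obs_m
            + (b_m - 1.0) * self.log1m_obs_m
            - betaln(a_m, b_m)
        ).sum(axis=-1)
        if self.any_lo:
            cdf = betainc(alpha[..., self.lo], beta[..., self.lo], self.eps_lo)
            total = total + np.log(np.maximum(cdf, 1e-300)).sum(axis=-1)
        if self.any_hi:
            # P(X >= 1 - eps) = P(Beta(beta, alpha) <= eps)
            sf = betainc(beta[..., self.hi], alpha[..., self.hi], self.eps_hi)
            total = total + np.log(np.maximum(sf, 1e-300)).sum(axis=-1)
        return total


def _beta_loglik(obs: np.ndarray, eps: np.ndarray, f_model: np.ndarray, phi) -> np.ndarray:
    """One-shot censored Beta log probability (see _CensoredBetaCache)."""
    return _CensoredBetaCache(obs, eps).loglik(f_model, phi)


def log_likelihood(
    curves: list[LossCurve],
    replicate_params: list[PSKParams],
    protocol: PassagingProtocol,
    noise_precision: float,
) -> float:
    """Log probability of observed loss curves given per-replicate parameters.

    Each replicate's deterministic curve is the model forward simulation
    under ``protocol``; each observed fraction is scored under
    Beta(F * phi, (1 - F) * phi) with F the model fraction and
    phi = ``noise_precision``.  Fractions within eps = 1/(2 n_events) of 0
    or 1 (the resolution limit of an n-event sample) are scored as
    censored at that bound.
    """
    if len(curves) != len(replicate_params):
        raise ValueError("need exactly one parameter set per curve")
    if noise_precision <= 0:
        raise ValueError("noise_precision must be > 0")
    total = 0.0
    for curve, params in zip(curves, replicate_params):
        sim = simulate_loss_curve(params, protocol)
        idx = np.asarray(curve.passage)
        if np.any(idx > protocol.n_passages):
            raise ValueError("curve contains passages beyond the protocol")
        f_model = sim.fraction[idx][None, :]
        eps = np.broadcast_to(
            np.asarray(_clip_eps(curve.n_events), dtype=float), curve.fraction.shape
        )
        total += float(_beta_loglik(curve.fraction, eps, f_model, noise_precision)[0])
    return total


# ---------------------------------------------------------------------------
# hierarchical posterior
# ---------------------------------------------------------------------------


def _norm_logpdf(x, loc, scale):
    return -0.5 * ((x - loc) / scale) ** 2 - math.log(scale) - 0.5 * math.log(2 * math.pi)


class _HierarchicalPosterior:
    """Vectorised log-posterior over walkers for the hierarchical model.

    Parameter vector (fit_omega=True):
        [mu_lam, log_sig_lam, mu_gam, log_sig_gam, mu_om, log_sig_om,
         log_phi, z_lam(R), z_gam(R), z_om(R)]
    For mechanism NONE the omega block is absent and omega is fixed at 0.

    All three blocks are non-centered (z-scores on the transformed scales),
    which keeps every prior factor Gaussian — the geometry the tempered
    sampler's near-prior rungs rely on to traverse the ridge between the
    loss probability and the killing efficacy.
    """

    def __init__(
        self,
        curves: list[LossCurve],
        protocol: PassagingProtocol,
        priors: PriorSpec,
        mechanism: Mechanism,
    ):
        self.mechanism = mechanism
        self.priors = priors
        self.R = len(curves)
        self.fit_omega = mechanism is not Mechanism.NONE
        passages, self.obs, self.eps = _prepare_observations(curves)
        self._beta_cache = _CensoredBetaCache(self.obs, self.eps)
        self.tau_grid = passages * protocol.tau_per_passage
        self.initial_fraction = protocol.initial_fraction
        self.n_pop = 7 if self.fit_omega else 5
        self.ndim = self.n_pop + (3 if self.fit_omega else 2) * self.R

    def unpack(self, theta: np.ndarray):
        """theta (nw, ndim) -> per-replicate params (nw, R) and phi (nw,)."""
        R = self.R
        mu_l, ls_l = theta[:, 0], theta[:, 1]
        mu_g, ls_g = theta[:, 2], theta[:, 3]
        if self.fit_omega:
            mu_o, ls_o = theta[:, 4], theta[:, 5]
            log_phi = theta[:, 6]
            z = theta[:, 7:]
            z_l, z_g, z_o = z[:, :R], z[:, R : 2 * R], z[:, 2 * R :]
        else:
            log_phi = theta[:, 4]
            z = theta[:, 5:]
            z_l, z_g = z[:, :R], z[:, R:]
        L_lam = mu_l[:, None] + np.exp(np.clip(ls_l, -30, 10))[:, None] * z_l
        L_gam = np.clip(
            mu_g[:, None] + np.exp(np.clip(ls_g, -30, 10))[:, None] * z_g, -20, 20
        )
        lam = expit(L_lam)
        gam = np.exp(L_gam)
        if self.fit_omega:
            om = expit(mu_o[:, None] + np.exp(np.clip(ls_o, -30, 10))[:, None] * z_o)
        else:
            om = np.zeros_like(lam)
        return lam, gam, om, np.exp(np.clip(log_phi, -10, 25))

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        """Prior terms that do not depend on the transformed omega block."""
        p = self.priors
        R = self.R
        lp = _norm_logpdf(theta[:, 0], *p.lambda_mean)
        lp += self._half_normal(theta[:, 1], p.lambda_scale)
        lp += _norm_logpdf(theta[:, 2], *p.gamma_mean)
        lp += self._half_normal(theta[:, 3], p.gamma_scale)
        if self.fit_omega:
            lp += _norm_logpdf(theta[:, 4], *p.omega_mean)
            lp += self._half_normal(theta[:, 5], p.omega_scale)
            lp += _norm_logpdf(theta[:, 6], *p.log_precision)
            z = theta[:, 7:]
        else:
            lp += _norm_logpdf(theta[:, 4], *p.log_precision)
            z = theta[:, 5:]
        lp += (-0.5 * z**2).sum(axis=1) - 0.5 * z.shape[1] * math.log(2 * math.pi)
        return lp

    @staticmethod
    def _half_normal(log_sigma: np.ndarray, half_scale: float) -> np.ndarray:
        # half-normal prior on sigma, sampled as log(sigma): include Jacobian
        sigma = np.exp(np.clip(log_sigma, -20, 10))
        return -0.5 * (sigma / half_scale) ** 2 + log_sigma

    def components(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(log prior, log likelihood) per row; -inf prior marks invalid states."""
        theta = np.atleast_2d(theta)
        lp = self.log_prior(theta)
        lam, gam, om, phi = self.unpack(theta)
        lp[~np.isfinite(lp)] = -np.inf
        ok = np.isfinite(lp)
        ll = np.zeros(theta.shape[0])
        if np.any(ok):
            f = _model_fractions(
                lam[ok], gam[ok], om[ok], self.mechanism,
                self.tau_grid, self.initial_fraction,
            )
            ll_ok = self._beta_cache.loglik(f, phi[ok, None, None])
            ll_ok[~np.isfinite(ll_ok)] = -np.inf
            ll[ok] = ll_ok
        return lp, ll

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        lp, ll = self.components(theta)
        out = lp + ll
        out[~np.isfinite(out)] = -np.inf
        return out

    def initial_walkers(self, n_walkers: int, rng: np.random.Generator) -> np.ndarray:
        """Draw walkers from a mildly shrunken version of the prior."""
        p = self.priors
        cols = [
            p.lambda_mean[0] + 0.5 * p.lambda_mean[1] * rng.standard_normal(n_walkers),
            np.log(0.3 * p.lambda_scale * np.abs(rng.standard_normal(n_walkers)) + 0.02),
            p.gamma_mean[0] + 0.5 * p.gamma_mean[1] * rng.standard_normal(n_walkers),
            np.log(0.3 * p.gamma_scale * np.abs(rng.standard_normal(n_walkers)) + 0.02),
        ]
        if self.fit_omega:
            cols += [
                p.omega_mean[0] + 0.5 * p.omega_mean[1] * rng.standard_normal(n_walkers),
                np.log(0.3 * p.omega_scale * np.abs(rng.standard_normal(n_walkers)) + 0.02),
            ]
        cols.append(p.log_precision[0] + 0.5 * p.log_precision[1] * rng.standard_normal(n_walkers))
        n_z = (3 if self.fit_omega else 2) * self.R
        z = 0.3 * rng.standard_normal((n_walkers, n_z))
        return np.column_stack(cols + [z])


def _locate_mode(problem, rng: np.random.Generator, n_starts: int = 4) -> list[np.ndarray]:
    """High-posterior anchor states used to initialise the cold rungs.

    Each replicate curve is first fitted by least squares on the logit
    scale (independent of the noise precision), the hierarchy is assembled
    around those fits, and the population block is polished under the full
    posterior.
    """
    from scipy.optimize import minimize

    R = getattr(problem, "R", 0)
    n_pop = getattr(problem, "n_pop", problem.ndim)

    def neg_full(th):
        v = float(problem(th[None])[0])
        return -v if np.isfinite(v) else 1e12

    if R == 0:
        # low-dimensional (competition) posterior: optimise directly
        best_x, best_f = None, np.inf
        for _ in range(n_starts):
            x0 = problem.initial_walkers(1, rng)[0]
            res = minimize(neg_full, x0, method="Nelder-Mead",
                           options={"maxiter": 3000, "xatol": 1e-7, "fatol": 1e-7})
            if res.fun < best_f:
                best_f, best_x = res.fun, res.x
        return [best_x]

    # stage 1: fit each replicate curve by least squares on the logit scale
    # (independent of the noise precision, which breaks the degeneracy
    # between a sloppy shared fit with tiny phi and tight per-replicate fits)
    fit_omega = problem.fit_omega
    obs = problem.obs
    tau_grid = problem.tau_grid
    eps_floor = np.minimum(problem.eps, 1e-3)
    g_obs = logit(np.clip(obs, eps_floor, 1.0 - eps_floor))

    def rep_obj(x, r):
        lam = expit(np.clip(x[0], -40, 0))
        gam = math.exp(np.clip(x[1], -3, 3))
        om = expit(np.clip(x[2], -40, 40)) if fit_omega else 0.0
        f = _model_fractions(
            np.array([lam]), np.array([gam]), np.array([om]),
            problem.mechanism, tau_grid, problem.initial_fraction,
        )[0]
        g_f = logit(np.clip(f, eps_floor[r], 1.0 - eps_floor[r]))
        return float(np.sum((g_obs[r] - g_f) ** 2))

    per_rep = np.zeros((R, 3))
    for r in range(R):
        best = None
        for _ in range(n_starts):
            x0 = np.array([
                -6.0 + 2.0 * rng.standard_normal(),
                0.2 * rng.standard_normal(),
                2.0 * rng.standard_normal() if fit_omega else 0.0,
            ])
            res = minimize(rep_obj, x0, args=(r,), method="Nelder-Mead",
                           options={"maxiter": 1500})
            if best is None or res.fun < best.fun:
                best = res
        # store the values the objective actually used (Nelder-Mead can
        # wander far beyond the clip bounds on flat no-loss objectives)
        per_rep[r, 0] = np.clip(best.x[0], -40.0, -0.5)
        per_rep[r, 1] = np.clip(best.x[1], -3.0, 3.0)
        per_rep[r, 2] = np.clip(best.x[2], -40.0, 40.0)

    def assemble(rep_fit: np.ndarray) -> np.ndarray:
        """Hierarchy state (theta vector) matching a set of replicate fits."""
        mu = rep_fit.mean(axis=0)
        sd = np.maximum(rep_fit.std(axis=0), 0.05)
        z = (rep_fit - mu) / sd
        lam = expit(rep_fit[:, 0])
        gam = np.exp(rep_fit[:, 1])
        om = expit(rep_fit[:, 2]) if fit_omega else np.zeros(R)
        f_hat = _model_fractions(lam, gam, om, problem.mechanism, tau_grid,
                                 problem.initial_fraction)
        resid2 = (obs - np.clip(f_hat, problem.eps, 1 - problem.eps)) ** 2
        v = np.clip(f_hat, 1e-3, 1 - 1e-3)
        phi_hat = float(
            np.clip(np.median(v * (1 - v) / np.maximum(resid2, 1e-12)), 2.0, 1e5)
        )
        th = np.zeros(problem.ndim)
        th[0], th[1] = mu[0], math.log(sd[0])
        th[2], th[3] = mu[1], math.log(sd[1])
        if fit_omega:
            th[4], th[5] = mu[2], math.log(sd[2])
            th[6] = math.log(phi_hat)
            th[7 : 7 + R] = z[:, 0]
            th[7 + R : 7 + 2 * R] = z[:, 1]
            th[7 + 2 * R :] = z[:, 2]
        else:
            th[4] = math.log(phi_hat)
            th[5 : 5 + R] = z[:, 0]
            th[5 + R :] = z[:, 1]
        return th

    # polish the population block under the full posterior
    pop_idx = np.arange(n_pop)

    def polish(th, maxiter=1500):
        def neg_pop(pop):
            t = th.copy()
            t[pop_idx] = pop
            return neg_full(t)

        res = minimize(neg_pop, th[pop_idx], method="Nelder-Mead",
                       options={"maxiter": maxiter})
        th[pop_idx] = res.x
        return th

    central = polish(assemble(per_rep))
    return [central]


def _run_ensembles(
    problem, ndim: int, settings: SamplerSettings, seed: int | None
) -> tuple[np.ndarray, float]:
    """Sample the posterior with adaptive parallel tempering.

    ``settings.n_chains`` independent tempered replicas are run; within
    each replica a geometric ladder of inverse temperatures spans the
    posterior (beta = 1) down to a near-prior distribution, with adaptive
    random-walk proposals per rung (Haario-style covariance, frozen after
    burn-in) and state swaps between neighbouring rungs.  The near-prior
    rungs traverse the weakly identified ridge between the loss
    probability and the killing efficacy freely and feed de-correlated
    states down to the cold rung — a regime in which single-temperature
    samplers stall on this geometry.  If the cross-replica potential scale
    reduction of the population coordinates is still above 1.05 after the
    configured sweeps, sampling continues (up to two extensions) before
    summarising.

    Returns cold-rung draws of shape (chain, draw, ndim) and the mean
    cold-rung acceptance rate.
    """
    C = settings.n_chains
    n_pop = getattr(problem, "n_pop", ndim)
    ss = np.random.SeedSequence(
        seed if seed is not None else int(np.random.randint(2**31))
    )
    rng = np.random.default_rng(ss)
    anchors = _locate_mode(problem, np.random.default_rng(ss.spawn(1)[0]))

    K = 8
    betas = np.geomspace(1.0, 0.04, K)  # likelihood tempering; prior intact
    # one sweep updates every rung of every replica in a single vectorised
    # posterior evaluation, so sweeps are cheap relative to ensemble steps
    base_sweeps = max(20 * settings.n_steps, 12_000)
    burn_frac = min(max(settings.n_burn / settings.n_steps, 0.25), 0.75)
    burn = int(base_sweeps * burn_frac)

    # --- initial states: cold rungs at the anchors, hotter rungs blended
    # toward independent prior draws so the ladder starts dispersed
    state = np.empty((C, K, ndim))
    scale0 = np.full(ndim, 0.05)
    scale0[n_pop:] = 0.2
    for c in range(C):
        base = anchors[c % len(anchors)]
        for k in range(K):
            frac_hot = k / (K - 1)
            prior_draw = problem.initial_walkers(1, rng)[0]
            mix = (1.0 - frac_hot) * base + frac_hot * prior_draw
            x = mix + scale0 * rng.standard_normal(ndim)
            tries = 0
            while not np.isfinite(problem(x[None])[0]) and tries < 80:
                blend = max(0.0, frac_hot - 0.1 * tries)
                mix = (1.0 - blend) * base + blend * prior_draw
                x = mix + 0.8**tries * scale0 * rng.standard_normal(ndim)
                tries += 1
            if not np.isfinite(problem(x[None])[0]):
                raise RuntimeError(
                    "could not initialise sampler: the prior is inconsistent "
                    "with the data (e.g. all-zero fractions with "
                    "loss-probability mass at 0)"
                )
            state[c, k] = x

    lp, ll = problem.components(state.reshape(C * K, ndim))
    lp = lp.reshape(C, K)
    ll = ll.reshape(C, K)
    beta_row = betas[None, :]

    log_step = np.full((C, K), math.log(2.38 / math.sqrt(ndim)))
    run_mean = state.copy()
    run_cov = np.tile(np.eye(ndim) * 1e-4, (C, K, 1, 1))
    chol = np.tile(np.eye(ndim) * 0.05, (C, K, 1, 1))
    n_adapt = 0
    acc_window = np.zeros((C, K))
    acc_count = 0
    cold_acc: list[float] = []
    draws: list[np.ndarray] = []
    keep_every = max(1, (base_sweeps - burn) // 4000)

    def do_sweeps(n_sweeps: int, adapting: bool, start_sweep: int) -> None:
        nonlocal state, lp, ll, n_adapt, acc_count, chol
        for sweep in range(start_sweep, start_sweep + n_sweeps):
            step = np.exp(log_step)[..., None]
            z = rng.standard_normal((C, K, ndim))
            prop = state + step * np.einsum("ckij,ckj->cki", chol, z)
            lp_p, ll_p = problem.components(prop.reshape(C * K, ndim))
            lp_p = lp_p.reshape(C, K)
            ll_p = ll_p.reshape(C, K)
            logr = (lp_p + beta_row * ll_p) - (lp + beta_row * ll)
            accept = np.log(rng.uniform(size=(C, K))) < logr
            state[accept] = prop[accept]
            lp[accept] = lp_p[accept]
            ll[accept] = ll_p[accept]
            acc_window[:] += accept
            acc_count += 1

            # neighbour swaps, alternating parity
            for par in (sweep % 2, 1 - sweep % 2):
                ks = np.arange(par, K - 1, 2)
                if len(ks) == 0:
                    continue
                d_beta = betas[ks] - betas[ks + 1]
                logs = d_beta[None, :] * (ll[:, ks + 1] - ll[:, ks])
                do = np.log(rng.uniform(size=logs.shape)) < logs
                for j, k in enumerate(ks):
                    rows = np.where(do[:, j])[0]
                    if len(rows) == 0:
                        continue
                    state[rows, k], state[rows, k + 1] = (
                        state[rows, k + 1].copy(), state[rows, k].copy()
                    )
                    ll[rows, k], ll[rows, k + 1] = (
                        ll[rows, k + 1].copy(), ll[rows, k].copy()
                    )
                    lp[rows, k], lp[rows, k + 1] = (
                        lp[rows, k + 1].copy(), lp[rows, k].copy()
                    )

            if adapting:
                n_adapt += 1
                delta = state - run_mean
                run_mean[:] += delta / n_adapt
                run_cov[:] += (
                    np.einsum("cki,ckj->ckij", delta, state - run_mean) - run_cov
                ) / max(n_adapt, 2)
                if acc_count >= 50:
                    log_step[:] += 0.3 * (acc_window / acc_count - 0.234)
                    acc_window[:] = 0.0
                    acc_count = 0
                if n_adapt >= 500 and n_adapt % 250 == 0:
                    try:
                        chol = np.linalg.cholesky(run_cov + 1e-8 * np.eye(ndim))
                    except np.linalg.LinAlgError:
                        pass
            else:
                if acc_count >= 200:
                    cold_acc.append(float(np.mean(acc_window[:, 0] / acc_count)))
                    acc_window[:] = 0.0
                    acc_count = 0
                if sweep % keep_every == 0:
                    draws.append(state[:, 0, :].copy())

    do_sweeps(burn, adapting=True, start_sweep=0)
    acc_window[:] = 0.0
    acc_count = 0
    do_sweeps(base_sweeps - burn, adapting=False, start_sweep=burn)

    total = base_sweeps
    for _extension in range(1):
        if settings.n_chains < 2:
            break
        chains = np.stack(draws, axis=1)
        pop_rhat = max(_diagnostics(chains[:, :, i])[0] for i in range(n_pop))
        if pop_rhat < 1.05:
            break
        do_sweeps(base_sweeps - burn, adapting=False, start_sweep=total)
        total += base_sweeps - burn

    chains = np.stack(draws, axis=1)  # (C, n_kept, ndim)
    acc = float(np.mean(cold_acc)) if cold_acc else float("nan")
    return chains, acc


def _overlap_coefficient(prior_loc: float, prior_scale: float, draws: np.ndarray) -> float:
    """Overlap coefficient between a normal prior and the posterior draws.

    OVL = integral of min(prior pdf, posterior pdf); estimated with a
    Gaussian KDE of the draws on a grid spanning both distributions.
    """
    from scipy.stats import gaussian_kde, norm

    d = draws.ravel()
    if len(d) > 5000:
        d = d[:: len(d) // 5000]
    if np.ptp(d) < 1e-12:
        return 0.0
    lo = min(prior_loc - 5 * prior_scale, d.min())
    hi = max(prior_loc + 5 * prior_scale, d.max())
    grid = np.linspace(lo, hi, 1024)
    post = gaussian_kde(d)(grid)
    prior = norm.pdf(grid, prior_loc, prior_scale)
    return float(np.trapezoid(np.minimum(prior, post), grid))


def _diagnostics(draws_cd: np.ndarray) -> tuple[float, float]:
    """(rhat, bulk ess) across independent chains for one parameter."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = float(az.rhat(draws_cd))
        ess = float(az.ess(draws_cd))
    return rhat, ess


def _summarize(
    mechanism: Mechanism,
    R: int,
    chains: np.ndarray,
    priors: PriorSpec,
    fit_omega: bool,
    hierarchical: bool,
) -> tuple[dict[str, np.ndarray], pd.DataFrame, pd.DataFrame]:
    """Build natural-scale draws and the summary tables."""
    n_chain = chains.shape[0]

    def col(i):
        return chains[:, :, i]

    draws: dict[str, np.ndarray] = {}
    prior_map: dict[str, tuple[float, float]] = {}
    if hierarchical:
        draws["mu_logit_lambda"] = col(0)
        draws["sigma_logit_lambda"] = np.exp(col(1))
        draws["mu_log_gamma"] = col(2)
        draws["sigma_log_gamma"] = np.exp(col(3))
        draws["lambda_loss"] = expit(col(0))
        draws["gamma"] = np.exp(col(2))
        prior_map["lambda_loss"] = priors.lambda_mean
        prior_map["gamma"] = priors.gamma_mean
        if fit_omega:
            draws["mu_logit_omega"] = col(4)
            draws["sigma_logit_omega"] = np.exp(col(5))
            draws["omega"] = expit(col(4))
            draws["survival_prob"] = 1.0 - draws["omega"]
            draws["phi"] = np.exp(col(6))
            prior_map["omega"] = priors.omega_mean
        else:
            draws["phi"] = np.exp(col(4))
    else:
        draws["lambda_loss"] = expit(col(0))
        draws["gamma"] = np.exp(col(1))
        prior_map["lambda_loss"] = priors.lambda_mean
        prior_map["gamma"] = priors.gamma_mean
        if fit_omega:
            draws["omega"] = expit(col(2))
            draws["survival_prob"] = 1.0 - draws["omega"]
            draws["phi"] = np.exp(col(3))
            prior_map["omega"] = priors.omega_mean
        else:
            draws["phi"] = np.exp(col(2))

    # transformed-scale draws used for the overlap diagnostic
    transformed = {
        "lambda_loss": logit(np.clip(draws["lambda_loss"], 1e-300, 1 - 1e-16)),
        "gamma": np.log(draws["gamma"]),
    }
    if fit_omega:
        transformed["omega"] = logit(np.clip(draws["omega"], 1e-300, 1 - 1e-16))

    rows = []
    for name, d in draws.items():
        rhat, ess = _diagnostics(d)
        if name in prior_map:
            ovl = _overlap_coefficient(*prior_map[name], transformed[name])
        else:
            ovl = float("nan")
        rows.append(
            {
                "parameter": name,
                "median": float(np.median(d)),
                "q2.5": float(np.quantile(d, 0.025)),
                "q97.5": float(np.quantile(d, 0.975)),
                "rhat": rhat,
                "ess_bulk": ess,
                "prior_posterior_overlap": ovl,
                "identifiable": bool(np.isnan(ovl) or ovl <= OVERLAP_THRESHOLD),
            }
        )
    summary = pd.DataFrame(rows)

    rep_rows = []
    if hierarchical and R > 0:
        n_pop = 7 if fit_omega else 5
        for r in range(R):
            L_lam = col(0) + np.exp(col(1)) * col(n_pop + r)
            L_gam = np.clip(col(2) + np.exp(col(3)) * col(n_pop + R + r), -30, 30)
            row = {
                "replicate": r,
                "lambda_loss": float(np.median(expit(L_lam))),
                "gamma": float(np.median(np.exp(L_gam))),
            }
            if fit_omega:
                L_om = col(4) + np.exp(col(5)) * col(n_pop + 2 * R + r)
                row["omega"] = float(np.median(expit(L_om)))
            rep_rows.append(row)
    replicate_summary = pd.DataFrame(rep_rows)
    return draws, summary, replicate_summary


def fit_hierarchical(
    curves: list[LossCurve],
    protocol: PassagingProtocol,
    priors: PriorSpec | None = None,
    mechanism: Mechanism = Mechanism.TA,
    settings: SamplerSettings | None = None,
    seed: int | None = None,
) -> PosteriorSummary:
    """Sample the hierarchical posterior of (lambda, gamma, omega) from loss curves.

    Population-level means and scales plus per-replicate non-centered
    deviations are sampled with ``settings.n_chains`` independent ensemble
    runs.  The fit is marked converged only when every parameter's
    potential scale reduction factor is below 1.01; otherwise the summary
    is returned flagged, not discarded.
    """
    if not curves:
        raise ValueError("need at least one curve")
    if any(len(c) < 2 for c in curves):
        raise ValueError("each curve needs at least 2 recorded passages")
    priors = priors or PriorSpec()
    settings = settings or SamplerSettings()
    problem = _HierarchicalPosterior(curves, protocol, priors, mechanism)
    chains, acc = _run_ensembles(problem, problem.ndim, settings, seed)
    draws, summary, rep_summary = _summarize(
        mechanism, problem.R, chains, priors, problem.fit_omega, hierarchical=True
    )
    max_rhat = float(np.nanmax(summary["rhat"]))
    return PosteriorSummary(
        mechanism=mechanism,
        n_replicates=problem.R,
        draws=draws,
        summary=summary,
        replicate_summary=rep_summary,
        converged=max_rhat < RHAT_THRESHOLD,
        max_rhat=max_rhat,
        seed=seed,
        settings=settings,
        priors=priors,
        protocol=protocol,
        acceptance_fraction=acc,
    )


# ---------------------------------------------------------------------------
# competition (single-passage dilution series)
# ---------------------------------------------------------------------------


class _CompetitionPosterior:
    """Non-hierarchical posterior for the dilution-series competition assay.

    theta = [logit lambda, log gamma, (logit omega,) log phi].
    """

    def __init__(self, f0, f1, priors: PriorSpec, mechanism: Mechanism, tau: float):
        self.f0 = np.asarray(f0, dtype=float)
        self.f1 = np.asarray(f1, dtype=float)
        if np.any((self.f0 < 0) | (self.f0 > 1)) or np.any((self.f1 < 0) | (self.f1 > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        self.priors = priors
        self.mechanism = mechanism
        self.tau = tau
        self.fit_omega = mechanism is not Mechanism.NONE
        self.ndim = 4 if self.fit_omega else 3
        self.eps = np.full_like(self.f1, 1e-4)
        self._beta_cache = _CensoredBetaCache(self.f1, self.eps)
        self.R = 0

    def components(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        theta = np.atleast_2d(theta)
        p = self.priors
        lam = expit(theta[:, 0])
        gam = np.exp(np.clip(theta[:, 1], -20, 20))
        lp = _norm_logpdf(theta[:, 0], *p.lambda_mean) + _norm_logpdf(theta[:, 1], *p.gamma_mean)
        if self.fit_omega:
            om = expit(theta[:, 2])
            log_phi = theta[:, 3]
            lp += _norm_logpdf(theta[:, 2], *p.omega_mean)
        else:
            om = np.zeros_like(lam)
            log_phi = theta[:, 2]
        lp += _norm_logpdf(log_phi, *p.log_precision)
        phi = np.exp(np.clip(log_phi, -10, 25))

        # per-dilution-point model fraction after tau
        a_plus = gam * (1.0 - lam)
        if self.mechanism is Mechanism.BACTERIOCIN:
            a_minus = 1.0 - 2.0 * om
            b = lam * gam
        else:
            a_minus = np.ones_like(a_plus)
            b = lam * gam * (1.0 - om)
        delta = (a_minus - a_plus)[:, None]
        bb = b[:, None]
        f0 = np.clip(self.f0, _F_FLOOR, 1.0)[None, :]
        r0 = (1.0 - f0) / f0
        small = np.abs(delta) < 1e-10
        with np.errstate(over="ignore", invalid="ignore"):
            edt = np.exp(delta * self.tau)
            ratio = r0 * edt + bb * (edt - 1.0) / np.where(small, 1.0, delta)
        ratio = np.where(np.broadcast_to(small, ratio.shape), r0 + bb * self.tau, ratio)
        ratio = np.where(np.isnan(ratio), np.inf, ratio)
        f_model = 1.0 / (1.0 + ratio)

        ll = self._beta_cache.loglik(f_model, phi[:, None])
        lp[~np.isfinite(lp)] = -np.inf
        ll[~np.isfinite(ll)] = -np.inf
        return lp, ll

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        lp, ll = self.components(theta)
        out = lp + ll
        out[~np.isfinite(out)] = -np.inf
        return out

    def initial_walkers(self, n_walkers: int, rng: np.random.Generator) -> np.ndarray:
        p = self.priors
        cols = [
            p.lambda_mean[0] + 0.5 * p.lambda_mean[1] * rng.standard_normal(n_walkers),
            p.gamma_mean[0] + 0.5 * p.gamma_mean[1] * rng.standard_normal(n_walkers),
        ]
        if self.fit_omega:
            cols.append(p.omega_mean[0] + 0.5 * p.omega_mean[1] * rng.standard_normal(n_walkers))
        cols.append(p.log_precision[0] + 0.5 * p.log_precision[1] * rng.standard_normal(n_walkers))
        return np.column_stack(cols)


def fit_competition(
    observed: list[tuple[float, float]] | np.ndarray,
    priors: PriorSpec | None = None,
    mechanism: Mechanism = Mechanism.BACTERIOCIN,
    tau: float = math.log(1000.0),
    settings: SamplerSettings | None = None,
    seed: int | None = None,
) -> PosteriorSummary:
    """Posterior over (lambda, gamma, omega) from a single-passage dilution series.

    ``observed`` holds (initial fraction, fraction after one passage) pairs
    from the competition design in which plasmid-bearing cultures are
    diluted with plasmid-free cells at several ratios and sampled after one
    regrowth period of model time ``tau``.
    """
    arr = np.asarray(observed, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (initial, final) dilution points")
    priors = priors or PriorSpec()
    settings = settings or SamplerSettings()
    problem = _CompetitionPosterior(arr[:, 0], arr[:, 1], priors, mechanism, tau)
    chains, acc = _run_ensembles(problem, problem.ndim, settings, seed)
    draws, summary, rep_summary = _summarize(
        mechanism, 0, chains, priors, problem.fit_omega, hierarchical=False
    )
    max_rhat = float(np.nanmax(summary["rhat"]))
    return PosteriorSummary(
        mechanism=mechanism,
        n_replicates=0,
        draws=draws,
        summary=summary,
        replicate_summary=rep_summary,
        converged=max_rhat < RHAT_THRESHOLD,
        max_rhat=max_rhat,
        seed=seed,
        settings=settings,
        priors=priors,
        protocol=None,
        acceptance_fraction=acc,
    )


# ---------------------------------------------------------------------------
# posterior predictive
# ---------------------------------------------------------------------------


def posterior_predictive(
    summary: PosteriorSummary,
    protocol: PassagingProtocol,
    n_draws: int = 500,
    seed: int | None = None,
    include_noise: bool = True,
    force: bool = False,
) -> pd.DataFrame:
    """Pointwise mean and 95% envelope of predicted loss curves.

    For each posterior draw a new replicate is generated from the
    population distribution (population mean + scale * fresh deviate) and
    its deterministic curve simulated; with ``include_noise`` the Beta
    observation noise at the drawn precision is added, so the envelope is a
    predictive band for observed fractions, not just the latent curve.
    """
    if not summary.converged and not force:
        warnings.warn(
            f"posterior not converged (max rhat {summary.max_rhat:.3f}); "
            "envelope computed anyway",
            stacklevel=2,
        )
    flat = {k: v.ravel() for k, v in summary.draws.items()}
    n_avail = len(flat["lambda_loss"])
    if n_draws > n_avail:
        raise ValueError(f"n_draws={n_draws} exceeds available draws ({n_avail})")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_avail, size=n_draws, replace=False)

    hierarchical = "mu_logit_lambda" in flat
    if hierarchical:
        L_lam = flat["mu_logit_lambda"][idx] + flat["sigma_logit_lambda"][idx] * rng.standard_normal(n_draws)
        L_gam = flat["mu_log_gamma"][idx] + flat["sigma_log_gamma"][idx] * rng.standard_normal(n_draws)
        lam, gam = expit(L_lam), np.exp(L_gam)
        if "mu_logit_omega" in flat:
            L_om = flat["mu_logit_omega"][idx] + flat["sigma_logit_omega"][idx] * rng.standard_normal(n_draws)
            om = expit(L_om)
        else:
            om = np.zeros(n_draws)
    else:
        lam = flat["lambda_loss"][idx]
        gam = flat["gamma"][idx]
        om = flat["omega"][idx] if "omega" in flat else np.zeros(n_draws)
    phi = flat["phi"][idx] if "phi" in flat else None

    passages = np.arange(protocol.n_passages + 1, dtype=float)
    tau_grid = passages * protocol.tau_per_passage
    f = _model_fractions(lam, gam, om, summary.mechanism, tau_grid, protocol.initial_fraction)
    f = np.clip(f, _F_FLOOR, 1.0 - _F_FLOOR)
    if include_noise and phi is not None:
        f = rng.beta(f * phi[:, None], (1.0 - f) * phi[:, None])
    return pd.DataFrame(
        {
            "passage": passages.astype(int),
            "mean": f.mean(axis=0),
            "median": np.median(f, axis=0),
            "lo2.5": np.quantile(f, 0.025, axis=0),
            "hi97.5": np.quantile(f, 0.975, axis=0),
        }
    )
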