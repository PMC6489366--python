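"""Gaussian-process estimation of maximal specific growth rates.

Log optical density is regressed on time with a squared-exponential
(RBF) kernel plus observation noise; hyperparameters are set by marginal-
likelihood maximisation with restarts.  The maximal specific growth rate
``mu_max`` is the maximum of the posterior-mean derivative of log OD over a
fine time grid — a non-parametric estimate that assumes no particular
growth law.  The derivative of a GP with an RBF kernel is itself a GP with
known cross-covariances, which gives an analytic standard error for
``mu_max`` at the maximising time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .synthesize import GrowthCurve

__all__ = ["GrowthFit", "fit_growth_gp", "gamma_from_doubling_times"]


@dataclass
class GrowthFit:
    """Result of a GP growth-curve fit."""

    mu_max: float  # maximal specific growth rate, per minute
    mu_max_sd: float  # posterior sd of the derivative at the maximising time
    t_at_max: float  # minutes
    grid_time: np.ndarray
    grid_mean: np.ndarray  # posterior mean of log OD
    grid_sd: np.ndarray
    grid_derivative: np.ndarray  # posterior mean of d(log OD)/dt
    kernel: str  # optimised kernel, repr
    label: str = ""

    @property
    def doubling_time(self) -> float:
        """Minutes per doubling, ln 2 / mu_max."""
        if self.mu_max <= 0:
            return math.inf
        return math.log(2.0) / self.mu_max


def fit_growth_gp(
    curve: GrowthCurve,
    blank: float = 0.0,
    n_restarts: int = 5,
    grid_size: int = 400,
    random_state: int = 0,
) -> GrowthFit:
    """Fit log OD with a GP and extract the maximal specific growth rate.

    Parameters
    ----------
    curve:
        Time (minutes, strictly increasing, >= 10 points) and positive OD.
    blank:
        Optional background OD subtracted before the log transform; points
        that become non-positive are dropped with a warning.
    """
    t = np.asarray(curve.time, dtype=float)
    od = np.asarray(curve.od, dtype=float)
    if len(t) < 10:
        raise ValueError("need at least 10 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    if blank:
        od = od - blank
        keep = od > 0
        if not np.all(keep):
            warnings.warn(
                f"dropping {int((~keep).sum())} non-positive points after blank subtraction",
                stacklevel=2,
            )
        t, od = t[keep], od[keep]
        if len(t) < 10:
            raise ValueError("fewer than 10 points remain after blank subtraction")
    y = np.log(od)

    span = t[-1] - t[0]
    kernel = ConstantKernel(1.0, (1e-3, 1e4)) * RBF(
        length_scale=span / 5.0, length_scale_bounds=(span / 50.0, span * 5.0)
    ) + WhiteKernel(noise_level=1e-3, noise_level_bounds=(1e-9, 1.0))
    gp = GaussianProcessRegressor(
        kernel=kernel,
        n_restarts_optimizer=n_restarts,
        normalize_y=True,
        random_state=random_state,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gp.fit(t.reshape(-1, 1), y)

    grid = np.linspace(t[0], t[-1], grid_size)
    mean, sd = gp.predict(grid.reshape(-1, 1), return_std=True)
    d_mean, d_sd = _derivative_posterior(gp, t, grid)
    i = int(np.argmax(d_mean))
    return GrowthFit(
        mu_max=float(d_mean[i]),
        mu_max_sd=float(d_sd[i]),
        t_at_max=float(grid[i]),
        grid_time=grid,
        grid_mean=mean,
        grid_sd=sd,
        grid_derivative=d_mean,
        kernel=str(gp.kernel_),
        label=curve.label,
    )


def _derivative_posterior(
    gp: GaussianProcessRegressor, t_train: np.ndarray, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and sd of the GP derivative at the grid points.

    For k(s, t) = c * exp(-(s-t)^2 / (2 l^2)), the derivative process has
    cross-covariance dk/ds = -c (s-t)/l^2 * exp(...) and prior variance
    c / l^2.  Uses the fitted Cholesky factor; the white-noise component
    contributes to training covariances only, not to cross terms.
    """
    k_prod = gp.kernel_.k1  # ConstantKernel * RBF
    c = k_prod.k1.constant_value
    ell = k_prod.k2.length_scale
    y_std = getattr(gp, "_y_train_std", 1.0)

    diff = grid[:, None] - t_train[None, :]
    k_cross = c * np.exp(-0.5 * (diff / ell) ** 2)
    dk = -(diff / ell**2) * k_cross  # d/ds k(s, t_i)

    d_mean = dk @ gp.alpha_.ravel() * y_std
    v = cho_solve((gp.L_, True), dk.T, check_finite=False)
    prior_var = c / ell**2
    d_var = np.maximum(prior_var - np.einsum("ij,ji->i", dk, v), 0.0) * y_std**2
    return d_mean, np.sqrt(d_var)


def gamma_from_doubling_times(dt_free: float, dt_bearing: float) -> float:
    """Burden ratio gamma = plasmid-free doubling time / plasmid-bearing doubling time.

    Equivalently mu_max_bearing / mu_max_free (the ln 2 factors cancel);
    < 1 when the plasmid slows growth.
    """
    if dt_free <= 0 or dt_bearing <= 0:
        raise ValueError("doubling times must be > 0")
    return dt_free / dt_bearing
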