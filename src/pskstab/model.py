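"""Population model of plasmid loss and post-segregational killing (PSK).

Two exponentially growing populations are tracked: plasmid-bearing ``X+``
and plasmid-free ``X-``.  Time ``tau`` is measured in plasmid-free growth
units (the plasmid-free per-capita rate is 1).  A plasmid-bearing cell
divides at relative rate ``gamma`` (the ratio of plasmid-free to
plasmid-bearing doubling time; < 1 for a burdensome plasmid) and produces a
plasmid-free daughter with probability ``lambda_loss`` per division.

Two PSK mechanisms are modelled:

* toxin-antitoxin (TA): a newly plasmid-free daughter is killed with
  probability ``omega`` at the moment it arises, so the loss influx is
  thinned to ``(1 - omega) * lambda_loss * gamma * X+``;
* bacteriocin: a secreted toxin exerts a constant killing pressure
  ``2 * omega * X-`` on the whole plasmid-free population.

The system is linear, so exact solutions and long-run fractions are
available in closed form; an adaptive ODE integration of :func:`derivatives`
serves as an independent numerical check in the test-suite.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Mechanism",
    "PSKParams",
    "PopulationState",
    "CopyNumber",
    "derivatives",
    "closed_form_solution",
    "copy_number_to_loss_prob",
    "asymptotic_fraction",
]


class Mechanism(enum.Enum):
    """Which post-segregational killing mechanism acts on plasmid-free cells."""

    NONE = "none"
    TA = "ta"
    BACTERIOCIN = "bacteriocin"


@dataclass(frozen=True)
class PSKParams:
    """Model parameters for one population/replicate.

    Parameters
    ----------
    lambda_loss:
        Probability that a dividing plasmid-bearing cell produces a
        plasmid-free daughter, in [0, 1].
    gamma:
        Ratio of plasmid-free to plasmid-bearing doubling time (> 0);
        values below 1 mean the plasmid slows growth.
    omega:
        Probability of successful post-segregational killing, in [0, 1].
        Forced to 0 for ``Mechanism.NONE``.
    mechanism:
        One of :class:`Mechanism`.
    """

    lambda_loss: float
    gamma: float
    omega: float = 0.0
    mechanism: Mechanism = Mechanism.NONE

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_loss <= 1.0:
            raise ValueError(f"lambda_loss must be in [0, 1], got {self.lambda_loss}")
        if not self.gamma > 0.0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"omega must be in [0, 1], got {self.omega}")
        if not isinstance(self.mechanism, Mechanism):
            raise TypeError("mechanism must be a Mechanism")
        if self.mechanism is Mechanism.NONE and self.omega != 0.0:
            object.__setattr__(self, "omega", 0.0)


@dataclass(frozen=True)
class PopulationState:
    """Plasmid-bearing/plasmid-free abundances at elapsed model time ``tau``."""

    x_plus: float
    x_minus: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.x_plus < 0.0 or self.x_minus < 0.0:
            raise ValueError("abundances must be non-negative")
        if self.tau < 0.0:
            raise ValueError("tau must be non-negative")

    @property
    def total(self) -> float:
        return self.x_plus + self.x_minus

    @property
    def fraction(self) -> float:
        """Plasmid-bearing fraction X+/(X+ + X-); undefined for an empty population."""
        if self.total <= 0.0:
            raise ValueError("fraction undefined for empty population")
        return self.x_plus / self.total


@dataclass(frozen=True)
class CopyNumber:
    """Average plasmid copy number per cell (> 0, real-valued)."""

    n: float

    def __post_init__(self) -> None:
        if not self.n > 0.0:
            raise ValueError(f"copy number must be > 0, got {self.n}")


def _exponents(params: PSKParams) -> tuple[float, float]:
    """Per-capita exponential rates (a_plus, a_minus) of the two populations.

    X+ always grows at gamma*(1 - lambda).  X- grows at rate 1 (TA/NONE) or
    1 - 2*omega under constant bacteriocin killing.
    """
    a_plus = params.gamma * (1.0 - params.lambda_loss)
    if params.mechanism is Mechanism.BACTERIOCIN:
        a_minus = 1.0 - 2.0 * params.omega
    else:
        a_minus = 1.0
    return a_plus, a_minus


def _influx_coefficient(params: PSKParams) -> float:
    """Coefficient b of the X+ -> X- influx term b * X+."""
    b = params.lambda_loss * params.gamma
    if params.mechanism in (Mechanism.TA, Mechanism.NONE):
        b *= 1.0 - params.omega
    return b


def derivatives(state: PopulationState, params: PSKParams) -> tuple[float, float]:
    """Instantaneous rates (dX+/dtau, dX-/dtau) of the PSK model.

    TA / no-PSK:   dX+/dtau = gamma*X+ - lambda*gamma*X+
                   dX-/dtau = X- + lambda*gamma*X+ - omega*lambda*gamma*X+
    bacteriocin:   dX+/dtau as above (the plasmid-bearing equation is shared)
                   dX-/dtau = X- + lambda*gamma*X+ - 2*omega*X-
    """
    if state.x_plus < 0.0 or state.x_minus < 0.0:
        raise ValueError("invalid state: negative abundance")
    lam, gam, om = params.lambda_loss, params.gamma, params.omega
    d_plus = gam * state.x_plus - lam * gam * state.x_plus
    if params.mechanism is Mechanism.BACTERIOCIN:
        d_minus = state.x_minus + lam * gam * state.x_plus - 2.0 * om * state.x_minus
    else:
        d_minus = state.x_minus + lam * gam * state.x_plus - om * lam * gam * state.x_plus
    return d_plus, d_minus


# Relative spacing below which the two exponents are treated as resonant.
_RESONANCE_RTOL = 1e-12


def closed_form_solution(
    state0: PopulationState, params: PSKParams, tau: float
) -> PopulationState:
    """Exact solution of the linear PSK system after elapsed time ``tau``.

    With per-capita rates a+ = gamma*(1-lambda) and a- (1 or 1-2*omega) and
    influx coefficient b (see module docstring),

        X+(tau) = X+(0) exp(a+ tau)
        X-(tau) = X-(0) exp(a- tau) + b X+(0) (exp(a+ tau) - exp(a- tau))/(a+ - a-)

    falling back to the resonant form b X+(0) tau exp(a tau) when the
    exponents coincide.
    """
    if tau < 0.0:
        raise ValueError("tau must be non-negative")
    a_plus, a_minus = _exponents(params)
    b = _influx_coefficient(params)
    x_plus = state0.x_plus * math.exp(a_plus * tau)
    homogeneous = state0.x_minus * math.exp(a_minus * tau)
    if abs(a_plus - a_minus) <= _RESONANCE_RTOL * max(1.0, abs(a_plus), abs(a_minus)):
        forced = b * state0.x_plus * tau * math.exp(a_plus * tau)
    else:
        forced = (
            b
            * state0.x_plus
            * (math.exp(a_plus * tau) - math.exp(a_minus * tau))
            / (a_plus - a_minus)
        )
    x_minus = homogeneous + forced
    # guard against tiny negative round-off in the forced term
    if x_minus < 0.0:
        if x_minus < -1e-9 * max(1.0, x_plus):
            raise ArithmeticError("closed-form solution produced a negative abundance")
        x_minus = 0.0
    return PopulationState(x_plus=x_plus, x_minus=x_minus, tau=state0.tau + tau)


def fraction_at(
    params: PSKParams, tau: float | np.ndarray, initial_fraction: float = 1.0
) -> np.ndarray | float:
    """Plasmid-bearing fraction at time(s) ``tau`` starting from ``initial_fraction``.

    Vectorised over ``tau``; numerically stable for large ``tau`` (works with
    the ratio X-/X+ rather than the raw abundances, which overflow).
    """
    if not 0.0 <= initial_fraction <= 1.0:
        raise ValueError("initial_fraction must lie in [0, 1]")
    a_plus, a_minus = _exponents(params)
    b = _influx_coefficient(params)
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ValueError("tau must be non-negative")
    if initial_fraction == 0.0:
        return np.zeros_like(tau_arr) if tau_arr.ndim else 0.0
    # ratio r(tau) = X-(tau)/X+(tau)
    r0 = (1.0 - initial_fraction) / initial_fraction
    delta = a_minus - a_plus
    if abs(delta) <= _RESONANCE_RTOL * max(1.0, abs(a_plus), abs(a_minus)):
        ratio = r0 + b * tau_arr
    else:
        with np.errstate(over="ignore"):
            ratio = r0 * np.exp(delta * tau_arr) + b * (1.0 - np.exp(delta * tau_arr)) / (
                -delta
            )
    ratio = np.where(np.isinf(ratio), np.inf, ratio)
    frac = 1.0 / (1.0 + ratio)
    return frac if tau_arr.ndim else float(frac)


def copy_number_to_loss_prob(cn: CopyNumber | float) -> float:
    """Plasmid-loss probability from mean copy number: lambda = 2**(1 - n).

    All copies segregating to one daughter at binomial random has
    probability 2 * (1/2)**n; the result is clipped to [0, 1].
    """
    n = cn.n if isinstance(cn, CopyNumber) else float(cn)
    if not n > 0.0:
        raise ValueError(f"copy number must be > 0, got {n}")
    return float(min(1.0, 2.0 ** (1.0 - n)))


def asymptotic_fraction(params: PSKParams) -> float:
    """Long-run plasmid-bearing fraction, lim X+/(X+ + X-) as tau -> infinity.

    Assumes a pure plasmid-bearing inoculum (X-(0) = 0, the experimental
    starting condition).  0 when the plasmid-free exponent exceeds the
    plasmid-bearing one; otherwise the coexistence value 1/(1 + c) with
    c = b/(a+ - a-) the forced-mode amplitude ratio.  An exact exponent tie
    returns 0 (the resonant t*exp(a t) mode dominates) — degenerate by
    construction.
    """
    a_plus, a_minus = _exponents(params)
    b = _influx_coefficient(params)
    if b == 0.0:
        # no influx into X-: a pure plasmid-bearing population stays pure
        return 1.0
    if abs(a_plus - a_minus) <= _RESONANCE_RTOL * max(1.0, abs(a_plus), abs(a_minus)):
        return 0.0
    if a_minus > a_plus:
        return 0.0
    c = b / (a_plus - a_minus)
    return 1.0 / (1.0 + c)
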