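"""Serial-passaging experimental designs mapped onto the PSK model.

A daily passage dilutes the culture D-fold into fresh medium and regrows it
to the pre-dilution density.  Under a unit plasmid-free per-capita rate,
regrowth takes ln(D) model-time units, which is the default
``tau_per_passage``.  Because the model is linear and dilution rescales both
populations equally, dilution preserves the plasmid-bearing fraction
exactly; the simulator is fully deterministic (stochastic bottlenecks live
in :mod:`pskstab.synthesize`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Mechanism, PSKParams, PopulationState, closed_form_solution, fraction_at

__all__ = [
    "PassagingProtocol",
    "LossCurve",
    "simulate_loss_curve",
    "predict_competition",
    "parameter_sweep",
]

_SWEEPABLE = ("lambda_loss", "gamma", "omega")


@dataclass(frozen=True)
class PassagingProtocol:
    """Dilution–regrowth protocol for a plasmid-loss assay.

    ``tau_per_passage`` defaults to ln(dilution_factor): the model time for
    the culture to regrow to its pre-dilution density at unit plasmid-free
    rate.
    """

    dilution_factor: float = 1000.0
    n_passages: int = 37
    tau_per_passage: float | None = None
    initial_fraction: float = 1.0
    initial_total: float = 1e9

    def __post_init__(self) -> None:
        if not self.dilution_factor > 1.0:
            raise ValueError("dilution_factor must be > 1")
        if self.n_passages < 1:
            raise ValueError("n_passages must be >= 1")
        if self.tau_per_passage is None:
            object.__setattr__(self, "tau_per_passage", math.log(self.dilution_factor))
        if not (self.tau_per_passage > 0 and math.isfinite(self.tau_per_passage)):
            raise ValueError("tau_per_passage must be finite and > 0")
        if not 0.0 <= self.initial_fraction <= 1.0:
            raise ValueError("initial_fraction must lie in [0, 1]")
        if not self.initial_total > 0.0:
            raise ValueError("initial_total must be > 0")


@dataclass
class LossCurve:
    """Per-passage plasmid-bearing fractions for one replicate."""

    replicate_id: str
    passage: np.ndarray
    fraction: np.ndarray
    n_events: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.passage = np.asarray(self.passage, dtype=int)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.passage.shape != self.fraction.shape:
            raise ValueError("passage and fraction must have the same length")
        if np.any(np.diff(self.passage) <= 0):
            raise ValueError("passages must be strictly increasing")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        if self.n_events is not None:
            self.n_events = np.asarray(self.n_events)
            if self.n_events.shape != self.fraction.shape:
                raise ValueError("n_events must match fraction length")
            if np.any(self.n_events < 0):
                raise ValueError("n_events must be non-negative")

    def __len__(self) -> int:
        return len(self.passage)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "replicate_id": self.replicate_id,
                "passage": self.passage,
                "fraction": self.fraction,
            }
        )
        df["n_events"] = self.n_events if self.n_events is not None else np.nan
        return df


def simulate_loss_curve(params: PSKParams, protocol: PassagingProtocol) -> LossCurve:
    """Deterministic plasmid-loss curve over a serial-passaging experiment.

    Within each passage the state advances by the closed-form model solution
    over ``tau_per_passage``; the D-fold dilution rescales both populations
    and therefore preserves the fraction, so passage-boundary fractions
    equal the closed-form fraction at cumulative time p * tau_per_passage.
    Abundances are renormalised each passage to avoid overflow at long
    times, which is exact for the recorded fractions (linearity).
    """
    state = PopulationState(
        x_plus=protocol.initial_total * protocol.initial_fraction,
        x_minus=protocol.initial_total * (1.0 - protocol.initial_fraction),
    )
    fractions = [protocol.initial_fraction]
    for _ in range(protocol.n_passages):
        grown = closed_form_solution(state, params, protocol.tau_per_passage)
        total = grown.total
        if total <= 0.0 or not math.isfinite(total):
            raise ArithmeticError(
                "population underflow/overflow during passaging; "
                "increase initial_total or reduce tau_per_passage"
            )
        frac = grown.fraction
        fractions.append(frac)
        # dilute (fraction-preserving) and renormalise scale
        state = PopulationState(
            x_plus=frac * protocol.initial_total,
            x_minus=(1.0 - frac) * protocol.initial_total,
        )
    return LossCurve(
        replicate_id="sim",
        passage=np.arange(protocol.n_passages + 1),
        fraction=np.array(fractions),
    )


def predict_competition(
    params: PSKParams, initial_fractions, tau: float
) -> np.ndarray:
    """Model fraction after one passage of length ``tau`` for a dilution series.

    Emulates the competition design in which a plasmid-bearing culture is
    diluted with plasmid-free cells at a range of starting ratios and
    sampled after one regrowth period.
    """
    f0 = np.asarray(initial_fractions, dtype=float)
    if np.any((f0 < 0) | (f0 > 1)):
        raise ValueError("initial fractions must lie in [0, 1]")
    out = np.array([fraction_at(params, tau, initial_fraction=f) for f in np.atleast_1d(f0)])
    return out.reshape(f0.shape)


def parameter_sweep(
    base: PSKParams, protocol: PassagingProtocol, parameter: str, values
) -> dict[float, LossCurve]:
    """One simulated loss curve per value of a swept model parameter."""
    if parameter not in _SWEEPABLE:
        raise ValueError(f"unknown parameter {parameter!r}; one of {_SWEEPABLE}")
    curves: dict[float, LossCurve] = {}
    for v in values:
        kwargs = {
            "lambda_loss": base.lambda_loss,
            "gamma": base.gamma,
            "omega": base.omega,
            "mechanism": base.mechanism,
        }
        kwargs[parameter] = float(v)
        curve = simulate_loss_curve(PSKParams(**kwargs), protocol)
        curve.replicate_id = f"{parameter}={v:g}"
        curves[float(v)] = curve
    return curves
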