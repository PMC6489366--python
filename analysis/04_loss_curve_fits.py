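"""Hierarchical Bayesian fits of simulated plasmid-loss curves.

Generates the study-sized dataset (9 replicates, 37 daily passages, 10^4
events per sample, Beta observation noise) from a toxin-antitoxin hierarchy
with known truth, fits the hierarchical model, and writes the posterior
summary, replicate-level estimates and the posterior-predictive envelope
under results/fits/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

import pskstab as ps
from pskstab import io
from pskstab.inference import SamplerSettings, posterior_predictive

OUT = Path(__file__).resolve().parent.parent / "results" / "fits"
OUT.mkdir(parents=True, exist_ok=True)

SEED = 42
truth = ps.HierarchicalTruth(
    lambda_loss=0.01, gamma=0.9, omega=0.95, mechanism=ps.Mechanism.TA
)
protocol = ps.PassagingProtocol(n_passages=37)
curves, truth_table = ps.generate_loss_curves(
    truth, protocol, n_replicates=9, n_events=10_000,
    noise="beta", noise_precision=500.0, seed=SEED,
)
io.write_loss_curves(curves, OUT / "loss_curves.csv")
truth_table.to_csv(OUT / "truth.csv", index=False)

fit = ps.fit_hierarchical(
    curves, protocol, mechanism=ps.Mechanism.TA, seed=11,
    settings=SamplerSettings(n_chains=4, n_steps=2000, n_burn=1000),
)
fit.summary.to_csv(OUT / "posterior_summary.csv", index=False, float_format="%.8g")
fit.replicate_summary.to_csv(OUT / "replicate_summary.csv", index=False,
                             float_format="%.8g")
env = posterior_predictive(fit, protocol, n_draws=500, seed=SEED, force=True)
env.to_csv(OUT / "envelope.csv", index=False, float_format="%.8g")

fig, ax = plt.subplots(figsize=(6, 4))
for c in curves:
    ax.plot(c.passage, c.fraction, color="0.6", lw=0.8)
ax.plot(env["passage"], env["mean"], color="crimson", label="model mean")
ax.plot(env["passage"], env["lo2.5"], "--", color="crimson", lw=0.8)
ax.plot(env["passage"], env["hi97.5"], "--", color="crimson", lw=0.8,
        label="95% envelope")
ax.set_xlabel("passage")
ax.set_ylabel("plasmid-bearing fraction")
ax.legend()
fig.tight_layout()
fig.savefig(OUT / "loss_curve_fit.png", dpi=150)

print(fit.summary.to_string(index=False))
print(
    f"\nTruth: lambda=0.01, gamma=0.9, omega=0.95. "
    f"Posterior medians: lambda={fit.median('lambda_loss'):.2e}, "
    f"gamma={fit.median('gamma'):.3f}, omega={fit.median('omega'):.3f}; "
    f"survival probability 1-omega={fit.median('survival_prob'):.2e}."
)
print(
    "Within a loss curve the loss probability and the killing efficacy enter "
    "only through the surviving-influx product lambda*gamma*(1-omega), so "
    "their individual posteriors stay ridge-shaped and wide (the overlap "
    "column flags this), while gamma is pinned by the late-passage slope."
)
if not fit.converged:
    print(f"NOTE: max rhat {fit.max_rhat:.3f} (>1.01); summary is flagged.")
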