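"""Automated gating: event tables -> plasmid-bearing fractions.

Generates cytometry event tables for one replicate across passages of a
simulated loss experiment, runs the automated gating pipeline (debris gate,
log10 transform, BIC-selected Gaussian mixture), and compares the gated
fractions with the generator's truth.  Writes per-sample gating results and
the reconstructed loss curve under results/gating/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import pskstab as ps
from pskstab import io

OUT = Path(__file__).resolve().parent.parent / "results" / "gating"
OUT.mkdir(parents=True, exist_ok=True)

SEED = 4242
params = ps.PSKParams(0.01, 0.9, 0.5, ps.Mechanism.TA)
protocol = ps.PassagingProtocol(n_passages=12)
latent = ps.simulate_loss_curve(params, protocol)

samples = {}
rows = []
for p, frac in zip(latent.passage, latent.fraction):
    key = f"rep01_p{int(p):02d}"
    samples[key] = ps.generate_events(
        float(frac), n_events=10_000, separation_decades=2.0,
        debris_fraction=0.05, seed=SEED + int(p),
    )
    res = ps.classify_events(samples[key])
    rows.append(
        {"sample": key, "passage": int(p), "true_fraction": frac,
         "gated_fraction": res.fraction_bearing,
         "n_components": res.n_components_selected,
         "n_events_used": res.n_events_used,
         "n_debris_removed": res.n_debris_removed}
    )

results = pd.DataFrame(rows)
results.to_csv(OUT / "gating_results.csv", index=False, float_format="%.8g")
curves = ps.batch_fractions(samples)
io.write_loss_curves(curves, OUT / "gated_loss_curve.csv")

err = (results["gated_fraction"] - results["true_fraction"]).abs()
print(results.to_string(index=False))
print(
    f"\nGated {len(samples)} samples of 10^4 events; worst absolute error "
    f"{err.max():.4f}, mean {err.mean():.4f}. Saturated samples (all bearing "
    "or all free) are resolved through the single-component path against "
    "the autofluorescence reference."
)
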