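"""Model behaviour: parameter sensitivity of plasmid-loss dynamics.

Sweeps each model parameter (loss probability lambda, burden ratio gamma,
killing efficacy omega) around a burdensome-plasmid baseline for both the
toxin-antitoxin and the bacteriocin mechanism, and tabulates the
copy-number -> loss-probability relation lambda = 2^(1-n) for the measured
origins of replication.  Writes curve families and summary tables under
results/model_dynamics/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

import pskstab as ps
from pskstab import io

OUT = Path(__file__).resolve().parent.parent / "results" / "model_dynamics"
OUT.mkdir(parents=True, exist_ok=True)

protocol = ps.PassagingProtocol(n_passages=37)
base = dict(lambda_loss=0.01, gamma=0.9, omega=0.5)

sweeps = {
    "lambda_loss": [1e-4, 1e-3, 1e-2, 1e-1],
    "gamma": [0.7, 0.8, 0.9, 1.0],
    "omega": [0.0, 0.5, 0.9, 0.99],
}

fig, axes = plt.subplots(2, 3, figsize=(12, 6), sharey=True)
rows = []
for j, mech in enumerate((ps.Mechanism.TA, ps.Mechanism.BACTERIOCIN)):
    for i, (name, values) in enumerate(sweeps.items()):
        params = ps.PSKParams(mechanism=mech, **base)
        family = ps.parameter_sweep(params, protocol, name, values)
        io.write_loss_curves(
            list(family.values()), OUT / f"sweep_{mech.value}_{name}.csv"
        )
        ax = axes[j, i]
        for v, curve in family.items():
            ax.plot(curve.passage, curve.fraction, label=f"{name}={v:g}")
            rows.append(
                {"mechanism": mech.value, "parameter": name, "value": v,
                 "final_fraction": curve.fraction[-1]}
            )
        ax.set_title(f"{mech.value}: vary {name}")
        ax.set_xlabel("passage")
        ax.legend(fontsize=7)
    axes[j, 0].set_ylabel("plasmid-bearing fraction")
fig.tight_layout()
fig.savefig(OUT / "parameter_sweeps.png", dpi=150)

summary = pd.DataFrame(rows)
summary.to_csv(OUT / "sweep_final_fractions.csv", index=False)

# copy number -> loss probability for the four measured origins
origins = {"SC101": 4.8, "p15A": 12.0, "pUC": 14.5, "ColE1-RO1600": 21.0}
cn = pd.DataFrame(
    {
        "origin": list(origins),
        "copy_number": list(origins.values()),
        "lambda_loss": [ps.copy_number_to_loss_prob(n) for n in origins.values()],
    }
)
cn.to_csv(OUT / "copy_number_loss_prob.csv", index=False)

print("Parameter sweeps written to", OUT)
print(cn.to_string(index=False))
print(
    "\nLoss probability spans",
    f"{cn['lambda_loss'].min():.2e} (highest copy) to "
    f"{cn['lambda_loss'].max():.2e} (lowest copy):",
    "copy number alone changes segregational loss by orders of magnitude,",
    "while the burden ratio controls how fast an established plasmid-free",
    "population takes over.",
)
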