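"""Growth-rate burden: GP fits of plate-reader-style curves.

Generates replicate growth curves for a plasmid-free host and three
plasmid-bearing strains of increasing burden, fits each with the
Gaussian-process estimator, and derives the burden ratio gamma for each
strain relative to the plasmid-free host.  Writes fits and the gamma table
under results/growth/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import pskstab as ps
from pskstab import io

OUT = Path(__file__).resolve().parent.parent / "results" / "growth"
OUT.mkdir(parents=True, exist_ok=True)

SEED = 20240917
# per-minute maximal growth rates: plasmid-free host and increasingly
# burdensome plasmids (roughly 25-min to 35-min doubling times)
strains = {
    "EcN-free": 0.0270,
    "low-burden": 0.0250,
    "mid-burden": 0.0230,
    "high-burden": 0.0200,
}

rows = []
curves_path = OUT / "growth_curves.csv"
first = True
for i, (label, mu) in enumerate(strains.items()):
    for rep in range(3):
        curve = ps.generate_growth_curve(
            mu_max=mu, noise_sd=0.01, label=f"{label}_r{rep}",
            seed=SEED + 100 * i + rep,
        )
        io.write_growth_curve(curve, curves_path, append=not first)
        first = False
        fit = ps.fit_growth_gp(curve)
        rows.append(
            {"strain": label, "replicate": rep, "true_mu": mu,
             "mu_max": fit.mu_max, "mu_max_sd": fit.mu_max_sd,
             "doubling_time_min": fit.doubling_time}
        )

fits = pd.DataFrame(rows)
fits.to_csv(OUT / "growth_fits.csv", index=False, float_format="%.8g")

by_strain = fits.groupby("strain", sort=False)["mu_max"].mean()
mu_free = by_strain["EcN-free"]
gamma = pd.DataFrame(
    {
        "strain": by_strain.index,
        "mean_mu_max": by_strain.values,
        "gamma_vs_free": [
            ps.gamma_from_doubling_times(
                np.log(2) / mu_free, np.log(2) / m
            )
            for m in by_strain.values
        ],
    }
)
gamma.to_csv(OUT / "gamma_table.csv", index=False, float_format="%.6g")

rel_err = (fits["mu_max"] - fits["true_mu"]).abs() / fits["true_mu"]
print(gamma.to_string(index=False))
print(
    f"\nGP recovery: median relative error {rel_err.median():.1%} across "
    f"{len(fits)} fits. The heaviest-burden strain grows at gamma = "
    f"{gamma['gamma_vs_free'].iloc[-1]:.2f} of the plasmid-free rate; in the "
    "loss model this growth deficit, not the loss probability, dominates "
    "how quickly an established plasmid-free population takes over."
)
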