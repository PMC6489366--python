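"""Single-passage competition: can a PSK system restore a diluted population?

Emulates the dilution-series design: plasmid-bearing cultures are mixed
with plasmid-free cells at a range of starting fractions and sampled after
one 24-h passage.  The bacteriocin (policing) model drives every mixture
back toward fully plasmid-bearing, while the toxin-antitoxin model cannot
rescue a diluted population.  A posterior over (lambda, gamma, omega) is
then recovered from noisy synthetic observations of the bacteriocin series.
Writes tables under results/competition/.
"""

import math
from pathlib import Path

import numpy as np
import pandas as pd

import pskstab as ps
from pskstab import io
from pskstab.inference import SamplerSettings

OUT = Path(__file__).resolve().parent.parent / "results" / "competition"
OUT.mkdir(parents=True, exist_ok=True)

SEED = 7
TAU = math.log(1000.0)  # one 24-h dilution-regrowth cycle
f0 = np.array([0.05, 0.1, 0.2, 0.4, 0.6, 0.8])

bact = ps.PSKParams(1e-4, 0.9, 0.9, ps.Mechanism.BACTERIOCIN)
ta = ps.PSKParams(1e-4, 0.9, 0.95, ps.Mechanism.TA)
pred = pd.DataFrame(
    {
        "initial_fraction": f0,
        "bacteriocin_final": ps.predict_competition(bact, f0, TAU),
        "ta_final": ps.predict_competition(ta, f0, TAU),
    }
)
pred.to_csv(OUT / "predicted_restoration.csv", index=False, float_format="%.8g")

# noisy synthetic observations of the bacteriocin series, then inference
rng = np.random.default_rng(SEED)
f1 = np.asarray(ps.predict_competition(bact, f0, TAU))
obs = rng.beta(np.clip(f1, 1e-9, 1 - 1e-9) * 500, np.clip(1 - f1, 1e-9, 1) * 500)
pairs = np.column_stack([f0, np.clip(obs, 0, 1)])
io.write_competition(pairs, OUT / "observed_series.csv")

fit = ps.fit_competition(
    pairs, mechanism=ps.Mechanism.BACTERIOCIN, tau=TAU, seed=SEED,
    settings=SamplerSettings(n_chains=4, n_steps=2000, n_burn=1000),
)
fit.summary.to_csv(OUT / "posterior_summary.csv", index=False, float_format="%.8g")

lo, hi = fit.credible_interval("omega")
print(pred.to_string(index=False))
print(
    f"\nBacteriocin: every mixture returns above "
    f"{pred['bacteriocin_final'].min():.4f} within one passage, while the TA "
    "mixtures are further diluted (final < initial at every ratio)."
)
print(
    f"Posterior killing efficacy omega: median {fit.median('omega'):.3f}, "
    f"95% CI ({lo:.3f}, {hi:.3f}) — truth 0.9. A fully restored series "
    "bounds omega from below but cannot pin it tightly; partial restoration "
    "would be far more informative."
)
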