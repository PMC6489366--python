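# pskstab — plasmid stability under post-segregational killing

Engineered bacteria carry their synthetic circuits on plasmids, and
plasmids get lost: at division a cell can hand every copy to one daughter,
and because circuit-bearing cells grow slower, the plasmid-free lineage
then takes over the culture. Post-segregational killing (PSK) systems
fight this — toxin-antitoxin (TA) cassettes such as hok/sok or axe/txe
kill the newly plasmid-free daughter, and secreted bacteriocins such as
microcin-V police the whole population. This package quantifies how well
such systems work from the standard wet-lab readouts: serial-passage
plasmid-loss curves (flow cytometry), growth curves (plate reader), and
single-passage competition dilution series.

## The model

Plasmid-bearing (`X+`) and plasmid-free (`X-`) populations grow
exponentially in time `τ` measured in plasmid-free generations:

    TA / no PSK:   dX+/dτ = γX+ − λγX+
                   dX−/dτ = X− + λγX+ − ωλγX+
    bacteriocin:   dX+/dτ = γX+ − λγX+
                   dX−/dτ = X− + λγX+ − 2ωX−

with λ the probability a dividing plasmid-bearing cell produces a
plasmid-free daughter (related to mean copy number by λ = 2^(1−n)), γ the
ratio of plasmid-free to plasmid-bearing doubling time (burden), and ω
the killing efficacy (1 − ω is the survival probability of a plasmid-free
cell). The package provides exact solutions of this linear system, a
serial-passage simulator, synthetic-data generators with known ground
truth, automated mixture-model gating of cytometry events, a
Gaussian-process estimator of maximal growth rates, and a hierarchical
Bayesian fit of (λ, γ, ω) from replicate loss curves via adaptive
parallel tempering, with identifiability diagnostics. See
`docs/methods.md` for the statistical details and their rationale.

## Worked example

Simulate the study-sized design (9 replicates, 37 daily passages, TA
mechanism with λ = 0.01, γ = 0.9, ω = 0.95, Beta observation noise) and
fit it back:

```python
import pskstab as ps
from pskstab.inference import SamplerSettings, posterior_predictive

truth = ps.HierarchicalTruth(lambda_loss=0.01, gamma=0.9, omega=0.95,
                             mechanism=ps.Mechanism.TA)
protocol = ps.PassagingProtocol(n_passages=37)          # 1000x daily dilution
curves, table = ps.generate_loss_curves(truth, protocol, n_replicates=9,
                                        noise="beta", noise_precision=500.0,
                                        seed=42)
fit = ps.fit_hierarchical(curves, protocol, mechanism=ps.Mechanism.TA,
                          seed=11, settings=SamplerSettings(n_steps=2000,
                                                            n_burn=1000))
print(fit.summary[["parameter", "median", "q2.5", "q97.5",
                   "prior_posterior_overlap", "identifiable"]])
```

prints (abridged):

```
   parameter     median      q2.5     q97.5   overlap  identifiable
 lambda_loss   0.001887  0.000754  0.017756  0.383     False
       gamma   0.910197  0.892103  0.932487  0.051     True
       omega   0.719995  0.456038  0.973541  0.361     False
         phi 478.525586 367.5179  589.3532   -         True
```

Read this the way the model dictates: the burden ratio γ is recovered
tightly (truth 0.9 inside a ±2% interval) and the noise precision φ comes
back at its true value (~500). The loss probability and killing efficacy,
however, enter a loss curve only through the surviving influx
λγ(1−ω), so their individual posteriors are ridge-shaped: λ's interval
spans over a decade and both parameters are flagged non-identifiable by
the prior-posterior overlap diagnostic. That flag is the method working
as intended — exactly this confound is why a perfectly stable plasmid
(axe/txe-like, no loss observed) admits no λ estimate at all, and why an
external copy-number measurement (λ = 2^(1−n), see
`pskstab.copy_number_to_loss_prob`) is the right way to pin λ when a
point estimate of ω is needed.

The same machinery distinguishes mechanisms in one passage: a bacteriocin
population restores any dilution (`analysis/05_competition.py` prints a
minimum restored fraction of 0.9998 across starting fractions 0.05–0.8),
while a TA population is further diluted at every ratio.

The `analysis/` scripts run the full narrative — parameter sweeps and the
copy-number relation (`01`), GP growth-rate fits and γ estimation (`02`,
median recovery error 1.4%), automated gating (`03`, worst error < 0.01
at 10⁴ events), hierarchical loss-curve fits with posterior-predictive
envelopes (`04`), and the competition assay (`05`) — writing tables under
`results/`. A `pskstab` command-line interface exposes the same steps
(`pskstab generate|gate|growth|simulate|sweep|fit|compete`).

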