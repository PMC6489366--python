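# Methods

## The population model

Two populations are tracked in continuous time: plasmid-bearing cells
`X+` and plasmid-free cells `X-`. Time `τ` is measured in plasmid-free
growth units, i.e. the plasmid-free per-capita rate is 1 and a
plasmid-bearing cell grows at relative rate `γ` (the ratio of plasmid-free
to plasmid-bearing doubling time; `γ < 1` for a burdensome plasmid). A
division of a plasmid-bearing cell produces a plasmid-free daughter with
probability `λ`, which for `n` plasmid copies segregating independently is
`λ = 2^(1−n)`.

Toxin-antitoxin (TA) killing acts at the moment of plasmid loss: the newly
plasmid-free daughter dies with probability `ω`, thinning the influx term.
Bacteriocin policing instead kills established plasmid-free cells at a
constant per-capita rate `2ω`:

    TA / none:    dX+/dτ = γX+ − λγX+
                  dX−/dτ = X− + λγX+ − ωλγX+
    bacteriocin:  dX+/dτ = γX+ − λγX+
                  dX−/dτ = X− + λγX+ − 2ωX−

The system is linear, so the solution is a sum of two exponentials with
rates `a+ = γ(1−λ)` and `a− = 1` (TA) or `1 − 2ω` (bacteriocin), plus a
forced mode; the degenerate case `a+ = a−` uses the resonant `τ·e^{aτ}`
form rather than an epsilon perturbation. All fraction trajectories are
invariant to a common rescaling of time, so the choice of e-folding units
(rather than doublings) for `τ` does not affect any estimated fraction; a
reader who prefers doubling units can rescale `τ` by `ln 2`.

Assumptions inherited from the model: constant copy number within and
across passages, constant growth rates across passages, pure exponential
growth (no stationary phase), and no evolution of bacteriocin immunity.
The last of these is exactly the failure mode real bacteriocin cultures
show over long experiments, so fitted bacteriocin parameters describe the
early, immunity-free phase only.

### Identifiability

A loss curve constrains only two functions of the three parameters: the
exponent gap `δ = 1 − γ(1−λ)` (how fast an established plasmid-free
population takes over) and the surviving influx `b = λγ(1−ω)` (TA) or
`b = λγ` with the gap shifted by `2ω` (bacteriocin). For the TA model `λ`
and `ω` therefore sit on a one-dimensional ridge — any `(λ, ω)` pair with
the same `λ(1−ω)` (and tiny second-order `λ` effect through `a+`) fits the
data equally well. The package does not hide this: the prior-posterior
overlap diagnostic flags weakly identified parameters, intervals on `λ`
and `ω` stay honestly wide, and `γ` (pinned by `δ`) is the parameter a
loss curve genuinely measures. An external copy-number measurement,
through `λ = 2^(1−n)`, is the natural way to break the ridge when a point
estimate of `ω` is needed.

## Serial passaging

A passage dilutes the culture `D`-fold and regrows it to the pre-dilution
density; at unit plasmid-free rate that regrowth takes `ln D` time units,
which is the default `tau_per_passage` (default `D = 1000`, configurable —
the exact dilution used in the assays is a protocol detail the model only
sees through `τ` per passage). Dilution rescales both populations equally
and so preserves the plasmid-bearing fraction exactly; the simulator is
deterministic, with stochastic bottleneck sampling available in the
synthetic-data generator so the inference forward model stays
deterministic. Abundances are renormalised each passage, which is exact
for fractions by linearity and avoids overflow over long experiments.

## Synthetic data

The generator defaults mirror the fluorescent-plasmid stability design:
9 replicates, 37 daily passages, 10^4 cytometry events per sample.
Per-replicate parameters are drawn on transformed scales
(`logit λ`, `log γ`, `logit ω`) from normal population distributions, which
respects the parameter bounds; default replicate scales (0.3, 0.05, 0.3)
are conservative day-to-day variation. Observed fractions are corrupted
either binomially (pure counting noise) or by a Beta distribution with
precision `φ` (default 500, an overdispersed counterpart of ~10^4-event
counting noise at the fraction scales that matter).

Event tables are a two-component location-scale mixture in log10
fluorescence (default separation 2 decades, component scale 0.2 decades)
plus a low-scatter debris population (default 5%); no spillover or
compensation artifacts are emulated. Growth curves are logistic with a
Baranyi-Roberts lag (transition-rate parameter `ν = 5 μmax`, so the lag
ends quickly but smoothly — a hard lag switch would put a derivative
discontinuity into the curve that no plate reader records) and
multiplicative log-normal noise.

What passing tests on these data do *not* show: robustness to instrument
drift, spectral spillover, autofluorescence shifts between days, deviation
from Beta-shaped fraction noise, or growth curves with diauxie or death
phases.

## Flow-cytometry gating

Debris is removed below a configurable quantile (default 0.05) on both
scatter channels; log10 fluorescence is then fitted with 1- and
2-component Gaussian mixtures and the component count chosen by BIC. With
two components the higher-mean component is the plasmid-bearing population
and the reported fraction is its responsibility-weighted share, which is
invariant to global rescaling of the fluorescence axis. Components whose
means are within 0.2 decades are declared unresolved and the sample falls
back to the single-component path, which calls the whole sample bearing or
free by comparing the fitted mode with a reference autofluorescence level
(config scalar, log10 units; best taken from a plasmid-free control).

## Growth-rate estimation

Log OD is regressed on time with a Gaussian process (constant × RBF +
white noise kernel; hyperparameters by marginal-likelihood maximisation
with 5 restarts; length scale bounded to [span/50, 5·span]). The maximal
specific growth rate is the maximum of the posterior-mean derivative of
log OD on a 400-point grid; because the derivative of a GP with an RBF
kernel is again a GP, its standard error comes from the analytic
derivative-process variance at the maximising time. An optional blank OD
is subtracted before the log transform; points that become non-positive
are dropped with a warning. The burden ratio is `γ = dt_free/dt_bearing`,
identically `μ+ / μ−` by cancellation of `ln 2`; both routes are exposed.

## Hierarchical Bayesian inference

Per-replicate parameters are non-centered deviations from population-level
means and scales on the transformed scales. Default priors are weakly
informative: `logit λ ~ N(−6, 2.5)` for the population mean (loss
probabilities from ~1 to ~10^-9 carry mass), `log γ ~ N(0, 0.5)`,
`logit ω ~ N(0, 4)` — wide on the logit scale because killing efficacies
of practical interest span survival probabilities from ~0.5 down to below
10^-4 — half-normal population scales (1.0, 0.3, 1.0) and
`log φ ~ N(5, 2)` for the Beta observation precision, which absorbs
day-to-day overdispersion beyond counting noise and the unknown true event
counts.

Observations are scored under `Beta(Fφ, (1−F)φ)` with `F` the
deterministic model fraction. A fraction estimated from `n` events cannot
resolve values within `ε = 1/(2n)` of a boundary (`ε = 10^-4` when the
event count is unknown), so observations at or beyond `[ε, 1−ε]` are
scored as interval-censored tail probabilities rather than as exact
interior values; treating them as exact points at the boundary makes the
likelihood depend on the arbitrary `ε` and demonstrably mis-calibrates the
posterior.

Because the posterior carries a long curved ridge between `λ` and `ω`
(see Identifiability), single-temperature samplers — including
affine-invariant ensembles, whose cross-mode proposals pay a `Z^(d-1)`
acceptance penalty — stall at one position on the ridge and can pass
within-run convergence checks while doing so. Sampling therefore uses
adaptive parallel tempering, written against the fully vectorised
log-posterior: four independent replicas, each an 8-rung geometric ladder
of likelihood-tempered distributions from the posterior (β = 1) down to a
near-prior rung (β = 0.04), with Haario-style adaptive random-walk
proposals per rung (covariance and step size adapted during the burn-in
half only, preserving ergodicity) and state swaps between neighbouring
rungs every sweep. The near-prior rungs traverse the ridge freely and
feed de-correlated states to the cold rung. Cold rungs are initialised at
anchor states from per-replicate least-squares curve fits; hot rungs are
blended toward independent prior draws. If the cross-replica potential
scale reduction factor of the population coordinates is still above 1.05
after the configured sweeps, sampling is extended before summarising.
Correctness of the sampler was verified by exact prior recovery (the
likelihood switched off) and by cross-seed agreement of the posterior on
fixed datasets. A fit is reported as converged only when every
parameter's PSRF is below 1.01; otherwise the summary carries the flag
rather than being discarded.

Identifiability is reported per parameter as the overlap coefficient
between the prior and the marginal posterior of the population mean
(Gaussian KDE on the transformed scale); overlap above 0.35 flags the
parameter as non-identifiable — the behaviour expected when no loss is
observed at all and the data carry no information about `λ`. The summary
reports the survival probability `1 − ω` alongside `ω`, since survival is
the quantity of practical interest for a killing system.

The posterior-predictive envelope draws a fresh replicate from the
population distribution for each retained posterior draw and, by default,
adds Beta observation noise at the drawn precision, so the band is a
predictive interval for observed fractions; both the pointwise mean and
median are reported (with heavy right-skew near a saturated boundary the
mean can legitimately leave the central interval, the median cannot).

The competition (dilution-series) fit uses the same machinery without the
hierarchy: a single `(λ, γ, ω, φ)` with the one-passage map as forward
model. A fully restored series (every mixture back above 0.99 within one
passage) bounds `ω` from below but cannot pin it — the posterior interval
is honest about that.

## Calibration

Calibration is assessed the standard way for a Bayesian procedure: ground
truths are drawn from the model's own prior, data are generated at the
reduced design (5 replicates × 15 passages), and the rate at which 95%
credible intervals cover the truth is counted. Under correct inference
coverage is nominal regardless of identifiability, so this test detects
sampler failures and likelihood mis-specification rather than rewarding
lucky point estimates. Fixed-truth recovery at the full design
(9 × 37, `λ = 0.01, γ = 0.9, ω = 0.95, φ = 500`) is also exercised; for
`γ` this is a genuine recovery test, while the `λ` marginal is
prior-dominated along the ridge (see Identifiability) and its posterior
median is expected to sit below a truth placed at high `ω`.

## Problem sizes and numerics

Default test and acceptance problem sizes — 500 random draws for the
analytic-oracle check, 9 × 37 for recovery, 20 prior-drawn datasets at
5 × 15 for calibration, 10^4 events per gating sample, 9 growth curves —
are the package's chosen balance between statistical resolution and a test
suite that a maintainer will actually run. Model fractions are floored at
10^-12; population scales are sampled on the log scale with the Jacobian
included; exponent ties in the closed form switch to the resonant branch
at relative spacing 10^-12.

## Known limitations

- The TA `λ–ω` ridge is structural; only external copy-number information
  (or partial-restoration competition designs) breaks it.
- The tempered sampler can remain above the 1.01 PSRF threshold on hard
  datasets (large replicate scatter, extreme ridge tails) even after
  extension; such fits are flagged, and the extreme tail quantiles of the
  weakly identified parameters carry Monte-Carlo noise.
- Mechanism choice (TA vs bacteriocin) is taken from the construct, never
  inferred.
- No stationary phase, age structure, within-passage copy-number dynamics,
  or immunity evolution.
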