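# Methods

## Model and assumptions

The package models the mill-outlet temperature during wet stirred media
milling with a lumped-capacity enthalpy balance,
`m·Cp dT/dt = Q_gen − UA (T − T_ch)`, whose solution is a single exponential
approach from T₀ to the steady state `T_ch + Q_gen/UA` with time constant
`m·Cp/UA`. The assumptions this encodes:

- the chamber is perfectly mixed, so the outlet temperature equals the
  charge temperature;
- Q_gen, UA, Cp and T_ch are constant over a milling cycle (in reality the
  instantaneous power draw falls as viscosity drops with temperature, which
  is why Q_gen and UA are *apparent*, time-averaged fitting parameters, not
  first-principles quantities);
- recirculation and holding-tank enthalpy effects are ignored; the model
  says nothing about tank, bead, or stirrer temperatures.

Only the product m·Cp enters the model, so mass and specific heat are never
stored separately; the six tabulated anchors (470.9 … 444.8 J/°C at bead
loadings 0.35 … 0.60) are authoritative, and intermediate loadings are
answered by linear interpolation — the anchor at 0.45 equals the 0.4/0.5
midpoint, confirming the table is affine (slope ≈ −104 J/°C per unit
loading) to the printed precision. Outside [0.35, 0.60] the ends are
extrapolated linearly with a warning; loadings beyond the ~0.63 random
close-packing limit are rejected.

Units are minutes, °C, J/min and J/(min·°C) throughout; CSV inputs in other
time units must be converted at the I/O boundary.

## Parameter estimation

`fit_lpm` minimizes the sum of squared temperature residuals over
(Q_gen, UA) with bounds Q_gen ≥ 0, UA > 0, using a trust-region-reflective
least-squares solver (relative tolerances 1e-10, ≤ 500 function
evaluations). T₀ is fixed to the first observed sample rather than freed as
a third parameter: the model is defined by exactly two fitted parameters per
run, and the published per-run tables report only (Q_gen, UA). The RMSE
convention is √(SSE/n) (denominator configurable to n − p via `ddof`).

Starting values come from the profile shape: a log-linear fit of the
normalized remaining rise over the first half of the profile estimates the
time constant τ, giving UA₀ = m·Cp/τ and Q_gen₀ = UA₀·(T_end − T_ch); if the
heuristic degenerates (flat or non-decaying profiles) a generic mid-range
fallback (1000 J/min, 50 J/(min·°C)) is used. Profiles whose systematic rise
(difference of first- and last-decile means) is below twice the estimated
noise floor trigger a non-identifiability warning: the exponential
degenerates toward a constant and the two parameters are separable only
weakly.

The ODE route (`simulate_ode`, explicit Runge–Kutta, DOP853) exists purely
as an independent cross-check of the closed form; the two agree to
integration tolerance on every packaged parameter set.

Identifiability is strongly condition-dependent. For the 2000-rpm runs the
total rise is only ~5–9 °C, and with 0.3 °C measurement noise the
Cramér–Rao bound puts 1σ relative parameter errors at 3–7% (fixing T₀ to a
noisy first sample contributes an error floor of roughly noise/rise). The
4000-rpm runs, with steady states of 50–70 °C, recover to well under 1%.
Consequently the recovery simulations achieve median relative errors of
~1.5% across the design, but the error distribution has a genuine tail from
the low-rise corner that no unbiased estimator can remove under these noise
conditions.

## Meta-models

**Power law.** `response = a · ω^p1 · c^p2 · D_b^p3`. Two fit modes are
provided because the original coefficients cannot be reproduced by log-space
OLS: on the packaged Q_gen table, log-OLS gives an ω-exponent of 2.76
whereas the published value is 3.02. `log_ols` (default for testing) is the
deterministic closed form — OLS of ln y on ln features, exact on noiseless
power-law data. `raw_nls` (default for reporting) refits on the original
response scale starting from the log-OLS solution; raw-scale weighting
emphasizes the large-response runs and lands within ~0.01 of every published
exponent, so it is evidently the convention the original fits used.

**k-nearest neighbors (k = 5).** Features (ω, c, D_b) are z-scored with
training-set means and population standard deviations; prediction is the
unweighted mean response of the k nearest training runs under Euclidean
distance. Standardization was reverse-engineered: it is the only
normalization under which all ten published test-run predictions reproduce
exactly after integer rounding (unscaled and min-max variants fail or tie
differently). Neighbor ordering is invariant to uniform rescaling of all
feature scales, so the population-vs-sample σ choice cannot change
predictions.

Because the training design is a balanced factorial grid, test conditions
midway between grid levels produce exact distance ties at the fifth
neighbor (four training runs equidistant). Ties — detected with a 1e-9
relative tolerance on squared distances, since "exact" ties differ in the
last floating-point ulp — are broken by preferring lower stirrer speed, then
higher bead loading, then lower bead size. This policy reproduces every
published prediction cell but is an empirical reconstruction (the original
implementation's internal ordering is unknown); it is configurable, and a
training-order policy is also provided.

One data inconsistency is handled explicitly: the extrapolated test run is
listed at 4000 rpm in the design table but 4200 rpm in the results table;
the package stores 4200 rpm (the value consistent with the published
nearest-neighbor predictions) and keeps the as-printed value in a
provenance column. Likewise the fourth results row carries a mislabeled
condition (its values belong to 3500 rpm / 0.55) and is stored corrected.

## Synthetic data

Raw experimental logs were published only as figures, so tests and
demonstrations use a generator that emulates the measurement setting:
closed-form trajectories on a uniform grid plus i.i.d. Gaussian noise.
Defaults — 60 min duration, 0.5 min sampling, noise sd 0.3 °C (mid-range of
the 0.15–0.90 °C published fit RMSEs), T₀ uniform on the observed 13–18 °C
window, chiller at 6.1 °C — mirror the reported operating conditions.
`generate_study` builds whole synthetic studies with ground-truth parameters
drawn from the power-law structure plus lognormal scatter (sd 0.1 on the log
scale by default), enabling end-to-end meta-model recovery tests.

What the generator does *not* emulate: the slow decline of instantaneous
power draw within a run (the model's own idealization), autocorrelated
sensor noise, intermittent milling cycles (only the first heating cycle is
modeled), and ambient-driven drift of T_ch. Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the model's
assumptions, not robustness to every feature of real mill data.

## Numerical choices

- Threshold-crossing times (`time_to_temperature`) return an infinite
  sentinel for targets beyond the asymptote instead of raising, so
  design-space sweeps never abort.
- Gompertz fitting linearizes the double exponential at 1.05× the maximum
  observed rise for starting values, then refines by bounded least squares.
- The heat-fraction slope is through-origin by default (the slope is
  interpreted as the fraction of shaft work dissipated as heat); an
  intercept variant is available by flag.
- Tie detection in KNN and grid comparisons use relative tolerances of 1e-9;
  fixture integrity is guarded by SHA-256 checksums.
- Report tables round parameters to integers and RMSEs to two decimals for
  display, retaining full precision internally.

## Problem sizes

The packaged study is small (27 + 5 runs), so every deterministic
computation is instantaneous. Recovery simulations use 100 synthetic
profiles per training condition (2700 fits, 61–121 samples each), which
completes in well under a minute on a single core.

## Known limitations

- Valid only for a fixed mill setup, batch size and recirculation rate; the
  fitted parameters do not transfer across equipment.
- Q_gen and UA are apparent parameters; they absorb model error and are not
  the true heat generation rate or transfer coefficient.
- Single-cycle only: intermittent milling (stop at 45 °C, restart at 18 °C)
  is supported only through single-cycle threshold times.
- Meta-models interpolate the training grid well but degrade outside it —
  the extrapolated 4200 rpm / 0.35 / 100 µm condition is exactly the case
  where the power-law prediction deviates most.
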