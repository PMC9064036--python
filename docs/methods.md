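# Methods

## Observation model and censoring correction

A mother-machine experiment observes, per growth channel, a single-file
lineage; each recorded event is one cell life: birth time t (first
appearance) and generation time τ (first to last appearance, ending in a
division), both resolved only on the imaging grid Δτ (default 5 min). The
analysis window is `[t_start, t_end]` (defaults 15 h and 40 h): events of
cells born before `t_start` are discarded to remove preculture carry-over,
and an event is only observable at all if its division falls before
`t_end`. A life of length τ can therefore start anywhere in a span of
length `L − τ`, with `L = t_end − t_start`, so the raw τ histogram is
biased toward short generation times. Each bin count is weighted by

    c_τ = L / (L − τ),

the inverse of the relative observable span, and the weighted counts are
normalized into the discrete distribution f(τᵢ) on the Δτ grid. Any
τ-independent prefactor of the weight cancels in the normalization, so only
the 1/(L − τ) shape matters. Weights are evaluated at bin centers; since
times are snapped to the grid at ingest this is exact, not an
approximation. Events with τ ≥ L cannot arise from a correctly censored
observation and are rejected at ingest with a warning.

Ingest snapping uses nearest-multiple rounding with ties rounding up.
Events whose generation time collapses to zero on the grid are dropped with
a warning (the microscope cannot resolve them).

## Population growth rate

Under binary division and iid generation times drawn from f, the
population (colony) growth rate μ satisfies the Euler–Lotka relation

    1 = 2 Σᵢ f(τᵢ) exp(−μ τᵢ).

The residual is strictly decreasing in μ, positive at 0 and non-positive at
`ln 2 / min τᵢ`, so the positive root is unique; it is solved with Brent's
method on that bracket to relative tolerance 1e−10. Jensen's inequality
gives `μ · E[τ] ≥ ln 2`, with equality only for a point mass — variability
in generation times speeds up the population relative to its mean
generation time; this bound is property-tested.

Replicate classification follows the event-count rule: < 5 surviving events
→ growth rate exactly 0 (retained for kinetic fitting), 5–49 → excluded
(status reported, no rate), ≥ 50 → analyzed. The boundary n = 5 is assigned
to "excluded" (continuity of the too-few-to-be-representative rationale)
and n = 50 to "analyzed".

Heterogeneity statistics (mean, variance, CV of τ) are probability-weighted
moments of the corrected distribution, with no finite-sample correction —
they describe the distribution, not a sample estimate of a superpopulation.

Lineage structure is deliberately ignored: mother–daughter correlations in
generation time exist in real data but the growth-rate relation treats
events as exchangeable draws from f. This is a known limitation; with
correlations the inverted μ is an approximation.

## Kinetic models and fitting

Growth versus substrate concentration c (mmol/L) is modelled as

    single-step:  μ(c) = μ_max · c/(K + c) · 1/(1 + (c/K_I)^{n_I})
    two-step:     μ(c) = [μ₁ c/(K₁ + c) + μ₂ c/(K₂ + c)] · 1/(1 + (c/K_I)^{n_I})

plus plain Monod `μ_max c/(K + c)` and Teissier `μ_max (1 − e^{−c/K})` as
comparators. The Hill factor is the standard non-competitive inhibition
form; for large c/K_I it is evaluated via the algebraically identical
log-domain expression to avoid overflow. Both inhibited models are 0 at
c = 0, positive for c > 0 and unimodal for n_I > 1; at the published
parameters they peak in the 2–8 mmol/L range.

Fitting is unweighted least squares on replicate-level (c, μ) pairs —
individual replicate results, not per-concentration means — with
zero-growth replicates included as μ = 0 (toggleable). Bounds: rates in
(0, 2] 1/h, half-velocity constants in [1e−4, 10] mmol/L, K_I in
[1, 1000] mmol/L, n_I in [0.5, 10], chosen for physical plausibility at the
magnitudes of the published fits. Initial guesses come from a deterministic
grid of geometric interior points of the bounds (3 per parameter; 2 per
parameter for the 6-parameter two-step model to keep the 64-start search
fast); the best final residual wins, so fitting is reproducible without a
seed. Standard errors come from the Gauss–Newton curvature at the optimum,
`cov = (JᵀJ)⁻¹ · RSS/(n − p)`. When the data contain no downturn at high c,
K_I and n_I are unidentifiable; the fit then leaves the inhibition factor
≈ 1 over the data range (documented, tested behavior). A c = 0, μ = 0
observation is exactly satisfied by every model and contributes zero
residual. The two-step fit enforces K₁ ≤ K₂ by post-hoc swap and warns if a
rate hits a bound. No model-selection statistic beyond RSS is computed.

## Transport bounds

With diffusivity D, half-saturation ḡ, penetration depth l_g, areal cell
density ρ and chamber height h (SI units throughout; concentrations exposed
as mmol/L = mol/m³), the penetration-depth relation `l_g² = D ḡ h / (ρ u)`
inverted for the per-cell uptake gives `u = D ḡ h/(ρ l_g²)`; the colony
volumetric uptake is `Û = u ρ / h`. Assuming zeroth-order (saturated)
uptake, the steady-state profile in a channel of length l open at both ends
is the parabola `c(x) = c_in − Û x (l − x)/(2D)`, clipped at zero, with
center drop `Û l²/(8D)`. The critical inlet concentration is exposed under
two conventions: `half_center` (default) — the inlet value at which the
center sits at half the inlet, `Û l²/(4D)` ≈ 0.139 mmol/L at the default
parameters — and `center_drop` — the inlet value at which the center
reaches zero, `Û l²/(8D)` ≈ 0.070 mmol/L. Both land at the order of the
concentration below which spatial heterogeneity along channels is observed
(~0.05 mmol/L); the exact convention behind that observation is not
recoverable from the available description, hence the explicit option
rather than a guess. The Monod-limited (concentration-dependent) uptake
profile is out of scope.

## Synthetic studies

The simulator emulates the event-generation process the estimators assume,
at the study's design conditions: 30 growth channels per experiment, a 40 h
observation imaged every 5 min with the first 15 h discarded downstream,
5 replicates at each of the 12 design concentrations (0.01–100 mmol/L),
and single-step kinetics with the published parameters as the generating
concentration–growth-rate map.

* Only the mother-cell lineage is simulated per channel; daughters wash out
  with the medium flow immediately, which is the minimal faithful model of
  event generation in this device.
* Generation times are iid gamma by default (positive support, tunable cv;
  lognormal and point-mass families available). The default cv 0.2 is a
  realistic mid-concentration choice for a steadily growing culture, in line
  with the sharp mid-range distributions such experiments show; it is not a
  fitted value.
* Concentration maps to the family's mean through the exact Euler–Lotka
  inverse (gamma closed form: shape k = 1/cv², scale θ = (2^{1/k} − 1)/μ),
  so the generating population rate is known analytically — not merely
  ln 2 / mean τ.
* The cell occupying a channel at t = 0 has age uniform over its first
  generation time (steady-state approximation); its own birth is unobserved
  and never emitted. Descendants are emitted when their division falls
  within the window; residual initialization transients are absorbed by the
  15 h cutoff.
* Replicate-level all-or-nothing non-growth is a per-replicate coin with
  default probability 0.3 below 0.05 mmol/L (occasional fully inactive
  low-concentration replicates), 0 in the reliable 0.05–20 mmol/L range,
  0.6 for 20–50 mmol/L (matching 3 of 5 replicates without growth at
  30 mmol/L), and 1 at ≥ 50 mmol/L (complete inactivity).
* RNG streams are named per (experiment, channel) and derived from the
  master seed, so adding replicates or channels never perturbs existing
  ones; identical configs give byte-identical outputs.

Not simulated: intra-channel nutrient gradients and position-dependent
growth, mother–daughter generation-time correlation, and cell-size
dynamics. Passing recovery tests therefore show that the estimators invert
the censored observation process they were designed for — not that real
data are free of lineage correlations or spatial structure.

A note on the event-table dialect: the row-per-event TSV cannot represent a
replicate with zero events, so analyses driven from a TSV only see
replicates that produced at least one event. The in-memory route
(`analyze_records` on simulated or constructed records) retains empty
replicates, which then enter the kinetic fit as μ = 0; the simulator's
`truth.json` manifest records them in either case.

## Problem sizes and numerical choices

Estimator-consistency checks use gamma generation times (cv 0.3) in a 25 h
window at 500/5000/50000 events over 20 seeds; kinetic parameter recovery
uses the 12 design concentrations × 5 replicates with Gaussian noise
σ = 0.03 1/h truncated at zero, over 50 seeds; end-to-end recovery runs the
full default study plus a denser 120-channel variant to exercise the
≥ 500-event regime. These sizes are the package's verification conditions
and match the study design where one exists. Root solving uses bracketed
Brent iteration (deterministic); fitting uses bounded trust-region least
squares with tolerances 1e−12; grid binning is exact integer counting after
ingest snapping, with ties rounding up.
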