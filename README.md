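# mmgrowth

Single-cell growth analysis for mother-machine microfluidic cultivations.

In a mother machine, single-file lineages of bacteria grow in ~1 µm
channels perfused by fresh medium; time-lapse microscopy yields, per cell,
a birth time and a generation time τ (first to last appearance, ending in a
division). `mmgrowth` turns tables of such division events into population
growth rates and substrate kinetics. It was built around growth of
*Corynebacterium glutamicum* on protocatechuic acid (PCA) as sole carbon
source, but the machinery is generic.

The core pieces:

* **Censoring-bias correction.** A cell life of length τ fits in a finite
  observation window `[t_start, t_end]` only if it starts after `t_start`
  and divides before `t_end`, so long generation times are under-observed.
  Each count is weighted by
  `c_τ = (t_end − t_start) / (t_end − t_start − τ)`
  before normalization, which removes the bias.
* **Euler–Lotka inversion.** The population growth rate μ solves
  `1 = 2 Σᵢ f(τᵢ) e^(−μ τᵢ)` for the corrected distribution *f*; the root
  is unique and bracketed, solved to 1e−10.
* **Replicate classification.** Events of cells born in the first 15 h are
  discarded; replicates with < 5 surviving events are marked growth rate 0,
  with 5–49 events excluded as unrepresentative, with ≥ 50 analyzed.
* **Substrate-inhibition kinetics.** Replicate-level (c, μ) pairs are fitted
  by deterministic multi-start least squares to
  `μ(c) = μ_max · c/(K + c) · 1/(1 + (c/K_I)^{n_I})` (single-step) or to two
  parallel Michaelis–Menten terms times the same Hill inhibition factor
  (two-step), with plain Monod and Teissier as comparators.
* **Transport bounds.** From the diffusivity D, half-saturation ḡ,
  penetration depth l_g, cell density ρ and chamber height h, the per-cell
  uptake `u = D ḡ h/(ρ l_g²)`, the volumetric uptake `Û = u ρ/h`, and the
  critical inlet concentration `Û l²/(4D)` at which the center of a channel
  of length l sits at half the inlet concentration.
* **Synthetic studies.** A simulator generates statistically faithful event
  tables (one mother lineage per channel, iid generation times, imaging-grid
  discretization, window censoring, concentration-dependent kinetics,
  replicate-level non-growth) with a ground-truth manifest, so the whole
  pipeline is verifiable without raw microscopy data.

## Worked example

`examples/04_transport_limits.py` computes the device's diffusion bounds:

```
per-cell uptake u       : 4.73e-19 mol/s
volumetric uptake U_hat : 0.39 mol s^-1 m^-3
critical concentration  : 0.139 mmol/L (center at half inlet)
                          0.0696 mmol/L (center fully depleted)
```

`examples/02_simulate_and_analyze.py` simulates a small study and analyzes
it end to end (abridged):

```
experiment   c, mmol/L  events   mu_hat  mu_true
c0.1_r1            0.1     107   0.1266   0.1298
c1_r1                1     307   0.3110   0.3122
c6_r1                6     351   0.3576   0.3577
c20_r1              20     229   0.2414   0.2412

single-step fit to the replicate growth rates:
  mu_max = 0.3711  (se 0.004)
  K      = 0.1857  (se 0.0066)
  K_I    = 24.26  (se 1.4)
  n_I    = 3.409  (se 1.1)
```

`mu_hat` is the Euler–Lotka growth rate recovered from the censored event
table; `mu_true` the simulator's generating rate. The fitted parameters
recover the generating kinetics (μ_max 0.37 1/h, K 0.185 mmol/L,
K_I 23.37 mmol/L, n_I 4.2). Growth peaks near 6 mmol/L and is suppressed at
high PCA — the substrate is simultaneously carbon source and inhibitor.

There is also a thin CLI: `mmgrowth simulate`, `mmgrowth analyze`,
`mmgrowth fit`, `mmgrowth transport` (see `--help`).

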