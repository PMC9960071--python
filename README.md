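# kflux

Analysis toolkit for the modulation of KCNQ1-type potassium channels by
external K⁺. Raising extracellular K⁺ reduces KCNQ1 outward current well
beyond the loss of driving force, an effect that localizes to the
selectivity filter. Quantifying it requires a chain of analyses that this
package implements as reusable, tested components for electrophysiologists
and simulators:

- **Constant-field (GHK) modelling.** The flux equation
  `I = P·(VmF²/RT)·[Kᵢ − K₀·e^(−VmF/RT)]/(1 − e^(−VmF/RT))` and the
  current ratio between two external K⁺ conditions, used both to fit
  absolute single-channel permeability `P` (cm/s) and to correct
  dose–response data for the trivial driving-force reduction (`Ith`).
- **Hill dose–response fitting.** The inhibition form
  `I(C) = (1 − I_max) + I_max/(1 + (C/IC₅₀)^n_H)` fitted per cell over a
  concentration ladder (0.2–100 mM K⁺) with mean ± SEM reporting across
  cells.
- **Fast (hook) inactivation.** Repolarization tails are fitted with two
  or three exponentials; extrapolating the constant plus the deactivating
  components to the segment start gives the total current `Y`, the full
  model gives the initial open-channel current `X`, and the inactivated
  fraction is `1 − X/Y`.
- **Boltzmann-with-offset activation,**
  `G/G_max = (1 − G_min)/{1 + exp[(V½ − V)·ZF/RT]} + G_min`, and
  permeability ratios from reversal-potential shifts,
  `P_X/P_K = exp(ΔE_rev·ZF/RT)`.
- **Single-channel amplitudes.** All-point histograms, Gaussian-mixture
  peak fitting (the dominant non-baseline peak is the open level),
  conductance regression in pS, and a slope-equality (ANCOVA) test.
- **Selectivity-filter permeation analysis** of MD-style ion
  z-trajectories: per-frame occupancy substates (S_cav, S4…S0), permeation
  events completed at a 4 Å exit criterion, classification of each event
  as *canonical* (knock-on: a cavity ion newly binds S_cav and triggers
  the S0 release) versus *spontaneous-S0* release, S0 occupancy split by
  ion origin (≥0.4 ns dwells), axial density profiles, and conversion of
  event counts to current (`I = n·e/t`).
- **Synthetic-data generators** for every input class — dose–response
  triplets, hooked-tail voltage-clamp traces, filtered telegraph
  single-channel sweeps, GHK I–V tables, G–V tables, reversal shifts, and
  a stochastic ion-hopping trajectory generator with programmed conduction
  modes — each emitting a ground-truth log for recovery testing.

Fitted models follow a statsmodels-style pattern: a model object built
from data whose `fit()` returns a results object with estimates, standard
errors, diagnostics, `summary()` and `plot()`.

## Worked example

```python
import pandas as pd
from kflux import simulate as sim, dose_response as dr, traces, permeation as perm

# 8 synthetic cells at wild-type inhibition parameters, GHK effect included
cells, truth = sim.gen_dose_response(0.55, 7.67, 1.02, noise_sd=0.02,
                                     n_cells=8, seed=1, with_ghk_effect=True)
norm = {}
for cid, tab in cells.items():
    g = tab.groupby("conc_mM")["observed_norm"]
    norm[cid] = pd.DataFrame({"conc_mM": g.mean().index.to_numpy(),
                              "observed_norm": g.mean().to_numpy()})
res = dr.DoseResponseExperiment.from_normalized(norm).fit()
print(res.summary())

# hooked-tail inactivation statistic
cfg = sim.TraceModelConfig(inactivation_fraction=0.35, noise_sd=0.02, seed=1)
rec, t = sim.gen_tevc_trace(cfg)
fit = traces.fit_tail_multiexp(rec, "tail")
print(f"fractional inactivation: {traces.fractional_inactivation(fit):.3f}")

# ion-hopping trajectory -> permeation events, modes, current
hop = sim.HopModelConfig(duration_ns=250.0, seed=1)
tracks, _ = sim.gen_ion_trajectory(hop)
ev = perm.classify_modes(perm.detect_permeations(tracks, hop.sitemap()),
                         tracks, hop.sitemap())
n_out = sum(e.direction == "outward" for e in ev)
print(len(ev), "events,",
      f"{perm.current_from_flux(n_out, hop.duration_ns):.2f} pA,",
      perm.mode_fractions(ev))
```

prints

```
Hill inhibition, 8 cells (mean ± SEM)
  IC50 = 7.53 ± 0.24 mM
  Imax = 0.549 ± 0.0045
  nH   = 1.04 ± 0.032
fractional inactivation: 0.357
26 events, 16.66 pA, {'canonical': 53.8..., 'spontaneous_S0': 42.3..., 'other': 3.8...}
```

The Hill parameters recover the generating values (IC₅₀ 7.67 mM, I_max
0.55, n_H 1.02) within the ensemble scatter; the tail statistic recovers
the programmed 0.35 inactivated fraction; the trajectory analyzer finds
all 26 programmed permeations (≈16.7 pA over 250 ns) and their programmed
≈50/40/10 canonical/spontaneous/other mode mixture.

## Command line

`kflux` exposes `simulate-dose-response`, `simulate-trace`,
`simulate-single-channel`, `simulate-trajectory`, `fit-dose-response`,
`analyze-inactivation`, `analyze-single-channel`, `analyze-trajectory`
and `report`. Simulators write CSV/TSV fixtures plus a `*.truth.json`
ground-truth log; analyzers write results JSON with a reproducibility
block (config echo, seed, version).

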