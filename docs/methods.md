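# Methods

This note records the models implemented in `kflux`, the design of the
synthetic-data generators, the numerical choices, and the limits of what
the test suite can demonstrate.

## Physical models

**GHK flux.** For a monovalent cation the constant-field current density
is

    I = P · (Vm F² / RT) · [Kᵢ − K₀ e^(−u)] / (1 − e^(−u)),   u = Vm F / RT

with `P` in cm/s, concentrations in mM (converted internally to mol/cm³,
so `I` is A/cm²; only ratios of fluxes are unit-sensitive downstream) and
`Vm` in mV at the interface (converted to volts inside). The singularity
at `Vm = 0` is removed by a second-order series for `|u| < 1e-4`, giving
the exact limit `P·F·(Kᵢ−K₀)`; elsewhere `1 − e^(−u)` is evaluated with
`expm1` for numerical continuity. Temperature defaults to 293 K
throughout (room-temperature oocyte recordings).

**GHK current ratio.** At equal permeability and voltage the current
ratio between two ionic conditions reduces to the bracket ratio
`[Kᵢ(C1) − K₀(C1)e^(−u)]/[Kᵢ(C2) − K₀(C2)e^(−u)]`. With oocyte internal
K⁺ of 108 mM and `Vm = +60 mV`, the predicted "driving-force only"
reduction from 0.2 to 100 mM external K⁺ is ≈8.6% (`Ith ≈ 0.914`) — far
smaller than the observed inhibition, which is the point of the
correction.

**Hill inhibition.** `I(C) = (1 − I_max) + I_max/(1 + (C/IC₅₀)^n_H)`,
the fraction of current remaining at blocker concentration `C`.
`I_max ∈ [0,1]` is the maximal fractional inhibition, `IC₅₀ > 0` the
half-maximal concentration (mM), `n_H > 0` the Hill coefficient.

**Boltzmann with offset.**
`G/G_max = (1 − G_min)/{1 + exp[(V½ − V)ZF/RT]} + G_min`, where `G_min`
is the voltage-independent conductance fraction. `Z` is free by default
(it can be fixed via `fix_z`), since conductance–voltage data of modest
size often cannot separate `Z` from `V½` cleanly; both modes are exposed.

**Permeability ratio.** `P_X/P_K = exp(ΔE_rev · Z F / RT)` from the mean
reversal-potential shift upon cation exchange. A −7.26 mV shift at
`Z = 1`, 293 K corresponds to `P_X/P_K ≈ 0.75`.

## Fitting

All nonlinear fits use scipy's trust-region-reflective least squares with
heuristic starting values (IC₅₀ starts at the geometric middle of the
positive concentration range; `V½` at the half-range crossing) and report
the first converged local optimum from that start. Standard errors come
from the Jacobian-based covariance; no bootstrap — cell-to-cell SEMs are
produced at the pipeline level by fitting per cell and averaging, which
matches how per-cell `n` and ±SEM are reported in this field. The GHK
permeability fit is linear in `P`, so it is solved in closed form
(regression through the origin on the GHK shape function), with variance
`s²/Σg²`.

A results object flags itself `identifiable = False` when any standard
error is non-finite or exceeds five times the parameter's own scale;
degenerate designs (a flat dose–response, a saturating-only G–V) trip
this flag rather than raising.

**Multi-exponential tails** are the one genuinely ill-conditioned fit.
The fitter (a) bounds amplitudes to ±10× the data range and time
constants to [10⁻⁴, 5]× the cursor-window span, (b) multi-starts over
three log-spaced time-constant ladders with linear-least-squares
amplitude initialization, (c) rejects degenerate optima (amplitude pairs
cancelling at time constants within 1.3× of each other, or amplitudes
beyond 8× the data range), and (d) with `auto_fallback` refits with two
components when the three-component fit is degenerate or its smallest
amplitude is statistically indistinguishable from zero.

## The inactivation statistic

A hooked tail is modelled as `a0 + Σ aᵢ e^(−t/τᵢ)` between two cursors
(default: 7.5 ms after the tail-segment start — the midpoint of the usual
5–10 ms placement past the capacitive transient — to 97% of the segment;
both overridable). The deactivation direction is the sign of the summed
amplitudes; components with that sign are deactivating, the opposing one
is the recovery (hook) component. `Y` extrapolates `a0` plus the
deactivating components to the segment start; `X` extrapolates the full
model there; the inactivated fraction is `1 − X/Y`, which is
sign-invariant and hence valid for inward and outward tails.

`X` is evaluated by default at the segment start (`model_t0`), not at the
first cursor: only then does a hook-free tail give exactly zero, and the
extrapolated model value is the natural estimate of the "initial current
immediately after the capacitive transient". Evaluation at the cursor
(`model_cursor`) and the raw sample at the cursor (`raw_cursor`) are
provided for fidelity to the historical procedure. Capacitive transients
are excluded by cursor placement, never by filtering.

## Dose–response pipeline

Per-pulse peak amplitudes stabilize over the first pulses in a solution;
stabilization is declared at the first index where three consecutive
pulses spread less than 5% of their mean (the recordings this emulates
stabilize "after four to six pulses"; the 5%/3-pulse rule is this
package's operationalization). Exactly three points are retained per
concentration; series that never reached the highest (100 mM) step are
excluded. Blank (water-injected oocyte) means are subtracted at identical
cursors. Normalization uses the mean of the three retained
reference-concentration points.

The GHK correction is **additive** by default:
`corrected(C) = observed(C) + (1 − Ith(C))`, i.e. the theoretical
*reduction* is added back. A multiplicative mode
(`observed/Ith`) is provided because the literature wording ("corrected
for theoretical values", `[(I/I₀.₂) − Ith]`) is ambiguous — read
literally, subtracting `Ith` itself cannot give values near 1 at the
reference concentration, so the additive reading is taken as intended.
The two modes agree to first order in `(1 − Ith)` when the observed
response is close to `Ith` (weak modulation); with strong inhibition they
differ by `(1 − Ith)(obs − Ith)/Ith` (≈0.04 at 100 mM for wild-type-like
parameters), which is why the default is stated explicitly in reports.

Aggregation fits per cell and averages parameters (mean ± SEM over
cells); a pooled global fit is available as an option.

## Single-channel analysis

All-point histograms (default bin 0.01 pA) are fitted as Gaussian
mixtures on the underlying samples with BIC selection of the component
count (up to `k_max`). The baseline is the component nearest 0 pA;
components whose means are not resolved from the baseline within 2 sd
count as baseline-like (heavy-tailed closed levels often split into two
near-zero Gaussians); the open-level amplitude is the highest-*weight*
resolved component — mixture weight (area) rather than peak height, for
bin-width invariance. Conductance lines are ordinary least squares with
slope reported in pS; slope equality between two lines is the standard
ANCOVA interaction F test (via statsmodels OLS). The 200 Hz digital
low-pass of the acquisition chain is modelled in the generator, not the
analyzer.

The internal K⁺ for single-channel GHK fits (cell-attached patches) is a
required input with documented default 135 mM, the bath-solution value.

## Trajectory analysis

Ion positions are per-frame z coordinates (Å) along the pore axis,
relative to the filter reference (center of mass of the four G314
carbonyl carbons). Filter sites S_cav, S4…S0 are axial bands; the
defaults use canonical K⁺-channel spacing (3.1 Å bands, S2 centered at
z = 0, S_cav below S4, S0 topmost) and are **not** literature values —
they are fully configurable via a SiteMap JSON, and every test uses the
same definition the generator uses. The exit reference (historically the
G316 carbonyl oxygens) defaults to +6.0 Å above the substate reference;
a passage is complete when the ion exceeds exit reference + 4.0 Å.

Permeation detection assigns each frame to below/inside/above zones with
a 2-frame debounce against boundary chatter; each below→above transit is
one outward event (re-entry and re-exit yields multiple events), and
outward − inward per ion equals its net side change (conservation).

Mode classification looks at the window `w` (default 1.0 ns) before the
permeating ion's last S0 occupancy: *canonical* if any other ion newly
entered S_cav within the window (the knock-on trigger), *spontaneous-S0*
if S_cav was vacant throughout, *other* if S_cav was occupied but not
newly. The window length is a package choice — the mechanism description
gives no operational value — and the generator's coupling delay (0.3 ns)
is set well inside it.

S0 occupancy statistics count dwells of at least 0.4 ns (the documented
dwell criterion; a source that prints "0.4 nS" is read as a units typo
for ns) and attribute them to external origin (entered from above) or
filter origin (from S1). Density profiles are normalized so the integral
over z equals the mean in-range ion count per frame (an exact counting
identity). Current from flux is `I = (n_out − n_in)·e/t`. Dihedral flip
statistics classify the aromatic-ring χ (C–Cα–Cβ–Cγ) time series into
the ~55° and ~160° configurations with a boundary at 110° and a ±10°
hysteresis band, reporting per-subunit state probabilities and flip
counts.

## Synthetic-data generators

Every generator is deterministic given (config, seed) and emits a
ground-truth log. Generator defaults are the study conditions the
analyses assume:

- **Dose–response**: triplet points per concentration over
  {0.2, 2, 5, 20, 100} mM, Gaussian noise sd 0.02, 8 cells; optional
  superposition of the GHK driving-force effect in the additive
  first-order form `observed = I_Hill − (1 − Ith)` so the correction
  pipeline can be exercised end to end.
- **TEVC traces**: hold/depolarize/tail protocol; the tail is a
  capacitive spike plus a recovery (hook) exponential (τ 30 ms) and two
  deactivating exponentials (τ 150/500 ms, 60/40 split); the hook
  amplitude is solved so the programmed inactivated fraction satisfies
  `1 − X/Y` exactly, and X, Y are logged. Leak enters as a pure constant
  added to the whole trace (removed in analysis by blank subtraction).
- **Single-channel sweeps**: exponential-dwell telegraph over the level
  set (segment levels drawn i.i.d. with the programmed weights, so
  stationary occupancy equals the weights; mean dwell 50 ms ≫ the filter
  rise time), filtered with a 4-pole Bessel low-pass at 200 Hz
  (`scipy.signal.bessel`), then Gaussian noise.
- **Reversal shifts**: `ΔE_rev = (RT/ZF)ln(ratio) + noise`, noise sd
  0.5 mV (typical TEVC reversal-reading precision), n = 5 cells.
- **G–V tables**: Boltzmann-with-offset plus Gaussian noise. The
  generator's gating charge is Z = 2.0 e (a typical KCNQ1 equivalent
  charge; the recovery targets V½ and G_min, which do not depend on the
  choice).
- **Ion-hopping trajectories**: a validation instrument, not a physical
  model. Permeating ions enter from the internal bulk and traverse the
  site ladder with exponential per-site dwells (mean 0.3 ns); the
  resident S0 ion is released per a programmed mode mixture (default
  50/40/10 canonical/spontaneous/other): canonical releases follow a
  fresh S_cav arrival by the coupling delay; spontaneous releases are
  preceded by an enforced S_cav-free guard longer than the
  classification window; "other" events have S_cav occupied since before
  the window. External ions bind a vacant S0 at a rate proportional to
  [K⁺]ₒ. Frames (0.05 ns) carry Gaussian positional jitter of 0.25 Å —
  small against the 1.55 Å band half-width, so site classification is
  unambiguous by construction. Two background options exist:
  a non-S_cav `S3-S2` alternator (safe alongside permeation traffic) and
  a three-ion `full-cycle` alternation S_cav-S3-S2 ↔ S4-S3-S1 for
  substate-distribution studies; the latter is meant to run with
  permeation disabled, because background S_cav entries would
  contaminate the canonical-trigger window.

What the generators do **not** emulate: series-resistance and capacitance
artifacts beyond a single-exponential spike, perfusion-exchange kinetics,
flicker/sublevel gating, correlated (1/f) noise, multi-ion knock-on
physics inside the filter, and any force-field-level realism. Passing
recovery tests therefore demonstrates correctness of the *analysis
chain* under the stated statistical structure, not performance on real
recordings or real MD trajectories.

## Problem sizes

The test suite and the acceptance script use desk-scale ensembles chosen
as representative of the real experiments: 8 cells (dose–response and
G–V), 10 I–V replicates, 20 trajectories of 250 ns at 0.05 ns frames
(~25 permeations each, ~500 events pooled), 100-replicate bias checks.
Everything runs in well under a minute in total.

## Known limitations

- Under the synthetic G–V conditions (9 voltages, conductance noise sd
  0.03) the V½ estimator is efficient (it attains the Cramér–Rao bound,
  ~1.7 mV per dataset), so an 8-dataset mean carries ~0.6 mV of
  irreducible spread; V½ recovery is verified against the published
  uncertainty of the reference value, not to a tighter band.
- IC₅₀ estimates near the top of the concentration ladder (≳25 mM on a
  0.2–100 mM grid) are noticeably skewed at n = 8; the bias checks are
  run in the well-conditioned interior of the parameter ranges.
- Mode classification assumes single-file traffic through S_cav; dense
  multi-ion traffic (many near-simultaneous passages) would blur the
  canonical trigger window.
- The tail fitter reports the first converged non-degenerate optimum;
  multi-exponential likelihoods are multimodal and pathological data can
  still defeat the degeneracy heuristics, which is why `converged` and
  the component standard errors are always carried on the results.
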