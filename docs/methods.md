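# Methods

`autokinetics` is a desk-scale re-creation of an automated
reaction-kinetics workflow: a simulator of instrument-monitored chemistry
experiments feeding the same analysis chain a feedback-controlled
synthesis platform would run — spectral integration, conversion
computation, initial-rate and pseudo-first-order fitting, variable time
normalization analysis (VTNA), Hammett regression, and windowed plateau
detection that terminates a monitored experiment.  This note records the
models, the parameter choices, and the design decisions that were
genuinely open.

## Reaction simulation

Networks are mass-action: for reaction $r$ with rate constant $k_r$ and
reactant stoichiometries $\nu_{r,s}$,

$$\frac{d[S]}{dt} = \sum_r (\nu^{prod}_{r,S} - \nu^{react}_{r,S})\, k_r
\prod_j [R_j]^{o_{r,j}},$$

where the exponent $o_{r,j}$ defaults to the stoichiometric coefficient
but can be overridden per species.  The overrides exist because monitored
campaigns routinely report *empirical fractional* orders (the tosylation
study generates arylamine orders between 0.46 and 0.94) produced by
catalytic networks nobody wants to enumerate; a lumped rate law with a
fractional exponent reproduces the observable kinetics without claiming
mechanism.

Integration is `scipy.integrate.solve_ivp` with LSODA at rtol 1e-8 /
atol 1e-10: complexation networks can have well-separated timescales, and
LSODA switches to a stiff method on its own.  Concentrations are floored
at zero inside the right-hand side (fractional powers of small negative
integrator excursions are otherwise fatal) and clipped at zero on output.

Units are millimolar and minutes everywhere; rate constants are
mM$^{1-n}$ min$^{-1}$.  Seconds are accepted at exactly one boundary —
the sampling schedule — because instruments are configured in seconds
while solution kinetics is reported per minute.

## Synthetic spectra

Each species carries a list of peaks (center, half-width at half-maximum,
response per mM).  NMR lines are Lorentzian with *integral* =
concentration x response (response proportional to proton count, which is
why NMR needs no calibration); UV-Vis bands are Gaussian with *peak
absorbance* = concentration x response, additive per Beer-Lambert.  NMR
axes are stored descending in ppm, UV-Vis ascending in nm, matching
instrument conventions; processing code normalizes orientation
internally.

Noise is additive Gaussian with standard deviation `relative_sigma` times
the spectrum's maximum clean intensity, plus an optional per-spectrum
baseline offset that grows linearly over a run (a slowly wandering
baseline).  The noise generator is keyed on `(seed, spectrum index)`, so
a plan with a fixed seed renders bit-identical spectra — full-campaign
determinism rests on this.

What the generator does *not* emulate: phase/shim errors, lineshape
distortion, peak overlap and drift of chemical shift with composition,
solvent background, photometric nonlinearity at high absorbance.
Passing recovery tests therefore demonstrate that the *analysis chain* is
unbiased and correctly plumbed under a realistic noise floor — not that
it would survive pathological instrument artifacts.

The shipped peak positions (tosyl methyls at 2.46/2.30 ppm, tetrazine
band at 525 nm, complex band at 575 nm) are plausible placeholders:
the real diagnostic shifts and wavelengths are instrument- and
solvent-specific, and everything is configurable through
`SpectralSignature`/`ProcessingRecipe` (YAML-serializable).

## Spectral processing

Region integrals are trapezoidal — instrument grids are arbitrary, and
higher-order rules buy nothing on noisy data.  The only baseline model is
the straight chord through the region's endpoint intensities, which
exactly removes constant offsets and linear drifts.  Two deliberate
choices here:

* **The shipped NMR recipe integrates without the chord.**  The chord is
  anchored on two single samples, so under white noise it *adds* variance
  of order $\sigma_{pt} \cdot w$ ($w$ = region width) — roughly ten times
  the trapezoid's own noise on our geometry — while removing nothing (the
  simulated baseline is flat).  Chord correction is there for data whose
  baseline actually drifts.
* **Regions are narrow (±0.025 ppm) and peaks well separated.**
  Lorentzian tails are heavy; with 0.003-ppm linewidths and 0.16-ppm
  separation the cross-talk between substrate and product integrals is a
  few parts in 10^3 and cancels to first order in the conversion ratio.

Conversion is the product integral over the sum of all related-species
integrals, small negative areas clipped to zero first, the ratio clipped
to [0, 1].  UV-Vis traces interpolate absorbance at a wavelength and
divide by a linear response factor when concentrations are wanted.

## Kinetic inference

All line fits are ordinary least squares (`scipy.stats.linregress`); LFER
math is base-10 throughout, the Hammett convention.

**Initial rates.**  The default window is the first 15 datapoints (one
full acquisition of the tosylation design) shortened to the points below
20% conversion — the early-linearity guard for fast runs.

**Pseudo-first-order $k_2$.**  Each decay trace yields
$k_{obs} = -\text{slope} / \overline{[A]}_{win}$, the fitted initial rate
normalized by the *mean* substrate concentration over the fit window
rather than by $[A]_0$.  A straight line fitted to
$A_0 e^{-k t}$ has slope $\approx -k A_0 e^{-a/2}$ with $a = kT$ (window
span $T$), so dividing by $A_0$ leaves a first-order bias $\sim a/2$
(10–14% at the 200 mM design point); the window mean is
$A_0 (1 - e^{-a})/a \approx A_0 e^{-a/2}$, so the ratio cancels the bias
to $O(a^2)$ (&lt;0.1% here) while keeping the initial-rate fit as the
first-stage estimator.  $k_2$ is then the OLS slope of $k_{obs}$ against
the excess concentration; the intercept is reported, not forced to zero —
a nonzero intercept is the standard diagnostic for a background path.

**Log-log orders.**  Slope of $\log_{10}(\text{rate})$ vs
$\log_{10}([\text{amine}]_0)$ over the five-concentration design
(100/75/50/37.5/25 mM).  Non-positive fitted rates (possible at the
lowest concentration under noise) are dropped with a warning.

**VTNA.**  The normalized time axis uses midpoint-concentration
trapezoidal increments
$\tau_i = \sum_{j \le i} \left(\tfrac{C_j + C_{j-1}}{2}\right)^{\alpha} \Delta t_j$,
the standard discretization.  $\alpha = 0$ returns elapsed time *exactly*
(special-cased, so the identity is bitwise).  The overlay score at each
candidate $\alpha$ is the RMS deviation of every experiment's profile
from the pooled piecewise-linear mean profile, evaluated on the union of
normalized-time points restricted to the range all experiments cover.
This metric is an artifact choice — "visual overlay quality" has no
canonical definition — picked because it is $O(N)$, symmetric in the
experiments, and exactly zero for identical profiles.  Ties break toward
smaller $\alpha$.  Default grid: $-1.0$ to $3.0$ in steps of 0.05
(inhibition through second order); the excess-screen campaign scans 0 to
2 in steps of 0.1.

**Hammett.**  $\rho$ is the OLS slope of $\log_{10}(k_X / k_H)$ against
tabulated $\sigma$, the reference substituent contributing the exact
point $(0, 0)$.  Rates are compared at the highest (standard) amine
concentration.  The shipped $\sigma$ table holds standard Hansch
para/meta values for the eight shipped anilines and is fully overridable
from YAML, since any real campaign's substituent set will differ.

## Endpoint monitoring

The stop rule is a while-loop on data: after every acquisition, compute
conversion and stop once the spread (max − min) of the last $W$ values is
at most $\varepsilon$.  The decision runs on the *derived conversion*,
not on raw spectra — that is what an operator actually watches — but a
raw-spectrum mode (L∞ spread across the window) is available behind
`MonitorConfig.metric` for analytes without a clean conversion
observable.  $W$ and $\varepsilon$ are mandatory configuration (defaults
in the shipped drivers: $W = 5$, $\varepsilon = 0.01$ conversion units);
there is no universal right value, so none is hard-coded.  The dead time
between mixing and the first measurement is a plan parameter, 0 in
simulation.

A plateau-terminated run can be frozen into a static protocol: the
monitored stop condition is replaced by the realized fixed duration and
measurement count.  Replaying the static protocol without monitoring must
end within $\varepsilon$ of the monitored final conversion — checked on
randomized kinetics in the test suite.  This is the bridge from a
dynamic, instrument-driven procedure to a fixed procedure reusable
without analytics; the iterative model-improvement loop around it is out
of scope.

## Study designs and recovery harnesses

The generator defaults are the monitored-campaign designs themselves:

| study | design | noise |
|---|---|---|
| IEDDA $k_2$ | 1.5 mM substrate; 100/150/200 mM excess; 20 points at 82 s; truth $k_2 = 3.50 \times 10^{-5}$ mM$^{-1}$min$^{-1}$ | 1% spectral |
| Hammett $\rho$ | 8 substituents x 5 concentrations (100–25 mM) x 15 points at 60 s; truth $\rho = -0.98$, amine order 0.7 | 5% lognormal on rate constants + 1% spectral |
| log-log order | initial rates $\propto c^n$ at the 5 concentrations; truths 0.46 / 0.70 / 0.94 | 5% lognormal |
| VTNA screen | 1:2:2 standard + 1.2-equivalent excess per reagent; 112 s sampling over 3 h | noiseless (visual analysis) |
| endpoint | first-order $k_{obs} = 1.5\,h^{-1}$, 7.5-min interval, $W=5$, $\varepsilon=0.01$ | 0.5% spectral |

Free parameters the studies do not pin down were set once to
bench-plausible values and documented here: tosyl chloride at 5 mM
(limiting, so amine depletion stays below ~20% even at 25 mM amine), the
reference tosylation rate constant $8 \times 10^{-4}$ mM$^{-0.7}$
min$^{-1}$ (standard run reaches ~25% conversion inside the 15-minute
window), iron screen at 1 mM base concentration with an effective
third-order constant of 0.05 mM$^{-2}$ min$^{-1}$ (~80% complexation in
three hours).  The 5% "rate noise" of the Hammett harness is lognormal
with median 1 so it is unbiased in log space, where the regression runs.

Recovery harnesses (`autokinetics.recovery`) rerun the *entire* pipeline
per replicate — simulate, render, integrate, fit, regress — and report
per-replicate estimates; 50 replicates give Monte-Carlo standard errors
of ~0.001 on orders, ~0.009 on $\rho$ and ~$0.09\times10^{-5}$ on $k_2$,
small against the tolerances of interest.  Replicate seeds are spawned
from one root seed through `numpy.random.SeedSequence`.

## Numerical edge cases

* Degenerate OLS inputs (zero spread in $y$) return stderr 0 and
  $r^2 = 1$ rather than NaN.
* `simulate_network` treats a missing species in the initial map as an
  error, not an implicit zero — silent typos in species names are the
  failure mode to fear.
* Rendering rejects any signature peak whose center ± 5 widths falls
  outside the grid, so no appreciable area is silently truncated.
* Conversion with a vanishing total integral raises (no diagnostic
  signal) instead of returning 0/0.

## Known limitations

* One-step lumped networks with order overrides cannot represent
  induction periods, catalyst decomposition or product inhibition; the
  ODE machinery can (add the steps), but no shipped study does.
* The overlay score weights all profile points equally; strongly uneven
  sampling in normalized time would bias the scan toward densely sampled
  segments.
* The plateau rule sees only spread, so a very slow late drift below
  $\varepsilon$ per window is indistinguishable from completion — the
  monitored quantity, not the rule, has to make that acceptable.
* Peak deconvolution and automatic peak finding are out of scope;
  integration regions are assumed to isolate their signals.
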