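# Methods

## Line-shape model

An NV ensemble's zero-field ODMR spectrum is modeled as unit baseline minus
two Lorentzians sharing one half-width γ:

I(ω) = 1 − (a₁/γπ)·[1 + ((ω−D−E)/γ)²]⁻¹ − (a₂/γπ)·[1 + ((ω−D+E)/γ)²]⁻¹

The a₁ term is the dip at D+E, the a₂ term the dip at D−E.  Amplitudes
carry MHz units so that the dimensionless dip depths are a/γπ; parameters
are valid when γ > 0, D > 0, E ≥ 0, a ≥ 0 and each depth lies in [0, 1).
Default "ensemble-mean" parameters are D = 2869.34 MHz, E = 4.21 MHz,
a₁ = 0.72, a₂ = 0.80, γ = 5.07 MHz, the measured means over ~200
nanodiamond bright spots; the per-parameter SDs (1.31, 0.31, 0.16, 0.23,
0.59) define the default `ParamDistribution` as independent Gaussians (no
covariances are available).  Temperature enters only through D, as
ΔT = −ΔD / 0.077 MHz·K⁻¹; the model deliberately omits Zeeman terms,
hyperfine structure, and any temperature dependence of E, γ or contrast.

## Sweep grids and timing

A digital sweep of n points over [f_start, f_end) samples
f_k = f_start + k·(f_end−f_start)/n, k = 0…n−1 (half-open, evenly spaced).
This convention was chosen so that the standard 100-point 2850–2890 MHz
sweep decomposes exactly — no interpolation — into a narrow sub-sweep
(central 50 points, 2860–2880 MHz, 0.4 MHz spacing) and a wide sub-sweep
(every second point, 2850–2890 MHz, 0.8 MHz spacing).  Integration time is
0.02 s per point, making a 50-point sweep 1 s and the 100-point parent 2 s;
each sub-sweep inherits half the parent's time.  With 1-second sweeps an
accuracy quoted in kelvin equals its value in K/Hz^1/2, since the
bandwidth normalization multiplies the per-measurement SD by √(sweep time).

## Noise model

Simulated spectra add i.i.d. Gaussian noise with SD = level × (deeper dip
depth max(a₁,a₂)/γπ).  The dip depth — not the unit baseline — is used as
the "signal strength" reference: with ~5 % contrast dips, a baseline
reference would make 10 % noise an order of magnitude larger than the
signal and no sweep design would yield usable accuracies.  A calibration
test checks the realized residual SD against level × depth to 3 % at 10⁴
points.

## Fitting

Spectra are fit by unweighted nonlinear least squares (the simulated noise
is homoscedastic by construction).  Initialization: D₀ at the grid
frequency of the minimum after 3-point smoothing (a dip location, biased by
±E, well inside the basin of attraction), E₀ = 4.21 MHz, γ₀ = 5.07 MHz,
amplitudes from the observed dip depth × γ₀π.  Box bounds γ ∈ [0.5, 30],
E ∈ [0, 15], a ∈ [0, 60] MHz and D within the grid span ± 20 MHz prevent
the dip-swap degeneracy (D, E) → (D±2E, −E↔reordered amplitudes); the
baseline is fixed at exactly 1 (spectra are pre-normalized; no sixth
parameter).  Standard errors come from the curvature at the optimum,
cov = s²(JᵀJ)⁻¹ with s² the residual variance over n−5 degrees of freedom.
Non-convergence is flagged, counted and excluded — never raised from batch
paths and never silently dropped.  Fits whose estimated dip depth falls
below 10⁻³ (e.g. an all-ones spectrum) are flagged non-converged: a flat
spectrum carries no information about D.

Two fitter implementations share the identical objective:
`fit_spectrum` wraps `scipy.optimize.least_squares` (TRF, analytic
Jacobian) for single spectra, while the Monte Carlo paths use a vectorized
box-constrained Levenberg–Marquardt (`nvtherm._batchfit`) that advances
thousands of same-grid spectra per iteration — the sweep-range study is
~570 000 fits and would be impractical one scipy call at a time.  A test
pins the two to the same optimum (|ΔD| < 5·10⁻⁶ MHz on noisy spectra), so
the fast path is an implementation detail, not a second model.

## Accuracy metrics

* `sd_of_repeats`: SD (ddof = 1) of the fitted D over repeated sweeps,
  divided by 0.077 MHz/K, times √(sweep time).  This is the primary metric.
* `fit_error`: the standard error of D from a single fit, normalized the
  same way.

On well-specified synthetic data the two agree within sampling error
(checked at 20–25 % tolerance over 200 replicates), which is the
equivalence the wide-field experiment validated.

## Monte Carlo sweep-range study

Candidate designs are 50-point grids centered at 2870 MHz with half-widths
5–20 MHz stepped by 0.25 MHz (the granularity implied by the optimum's
0.25 MHz edges).  Each (half-width, noise level) cell simulates replicate
spectra at the ensemble-mean parameters (fixed means, not per-trial
redraws; per-trial draws remain available for robustness studies), fits
them, and scores the design by the SD-based accuracy; a bootstrap over the
replicate D values supplies a Monte Carlo SE.  Cells with more than 50 %
failed fits are flagged unreliable and excluded from optimization.

Two variance-reduction/design choices matter here.  First, the scan reuses
one standard-normal noise matrix across all cells, scaled by each level's
noise SD (common random numbers): every design sees the same noise stream,
so accuracy *differences* between neighboring ranges — and hence the argmin
— are far more stable than independent sampling would allow, while each
individual estimate keeps its usual distribution.  Second, the objective
averaged across noise levels picks the reported optimum, with ties broken
toward the narrower range; per-level argmins are reported alongside so
"optimal at every noise level" can be verified.  The scan uses 2000
replicates per cell (argmin stable to ±1 step of 0.25 MHz; ~45 s on one
CPU).  As an internal cross-check, the Cramér–Rao bound of D for this
model and grid family has its minimum at half-width 9.25 MHz
(2860.75–2879.25 MHz), slightly wider than the signal half-width
2γ + 2E = 18.56 MHz — the Monte Carlo argmin lands on or adjacent to it.

The head-to-head comparison draws noise levels uniformly from 0–20 % of
dip depth; for each draw both designs' accuracies are estimated from
independent 200-replicate sets (narrow 2860–2880 vs wide 2850–2890 MHz, the
pairing used in the wide-field experiment).  A strict accuracy_A <
accuracy_B counts as a win for A; exact ties (which occur only in
degenerate zero-noise settings) are reported separately, so win(A,B) +
win(B,A) + ties = 1 on the same trial set.  At 500 draws × 200 replicates
the narrow design wins ~96–97 % of draws.

## Synthetic wide-field scenes

The generator emulates the acquisition geometry: spots placed uniformly at
random with a minimum separation (default one ROI edge, 7 µm), rendered as
pixel-integrated Gaussian PSFs (default σ = 0.5 µm — diffraction-scale for
a 20× objective, configurable, not fitted to hardware), per-frame flux =
brightness × line-shape value at that frame's frequency, optional
per-repeat Gaussian jitter of each spot's D (to inject a known
temperature-equivalent variance), plus constant background and per-pixel
Gaussian noise.  Stacks serialize as multi-page TIFF with a JSON
acquisition sidecar; ground truth (positions, per-spot parameters,
brightness, seed) as a second JSON sidecar.  All generators are pure
functions of (config, seed).

Deliberately not modeled: photon shot noise (Gaussian only, matching the
simulation being emulated), EMCCD gain/readout physics, photobleaching,
stage drift, and multi-orientation single-NV effects.  Passing pipeline
tests on these scenes therefore demonstrates the correctness of the
analysis chain, not robustness to every real-microscope artifact.

## Pipeline conventions

Bright-spot detection: Gaussian smooth (σ = 1 px), local maxima above
median + k × robust SD (1.4826 × MAD, k = 5 default), brighter-first
minimum-separation suppression, border-ROI rejection, deterministic
brightness ordering.  ROI spectra are per-frame sums over the odd-sized
pixel window nearest 7 µm, normalized by the spectrum's own off-resonance
plateau (mean of the top decile of values); no background subtraction is
applied, so a strong background pedestal compresses the apparent contrast
— exact round-trip fixtures therefore use zero-background scenes.  ΔT time
courses are referenced to the per-spot series mean (the acquisition has no
absolute calibration).  The narrow-vs-wide winner per spot is decided by
the SD-of-repeats accuracies, with gaps below 10⁻³ K/Hz^1/2 reported as
ties (so noiseless stacks tie rather than flip on 10⁻¹⁵-scale jitter);
spots with more than 20 % failed fits in either sub-sweep are excluded
from summaries and listed with the reason.  Summary fractions count
decided (non-tie) spots.

## Problem sizes

Default study sizes are the ones quoted above: 61 half-widths × 3 noise
levels × 2000 replicates for the scan, 500 draws × 200 replicates for the
comparison; pipeline tests use scenes of 1–20 spots with 2–100 sweep
repeats at 64–220 px frames.  These sizes give Monte Carlo errors
comfortably below the effects being measured (bootstrap SEs are attached to
every scan cell).

## Known limitations

The dip-depth definition of "noise level" is a modeling choice; if a
baseline-referenced definition is preferred, only the noise-level axis
rescales.  The optimizer explores uniform symmetric grids with a fixed
point budget only — no asymmetric ranges, no non-uniform point placement,
no analytic optimization (the Cramér–Rao computation above is a
cross-check, not the method).  Accuracy is defined through D alone; E and
γ are nuisance parameters, not temperature channels.
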