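# nvtherm

Sweep-range design and wide-field analysis for nanodiamond ODMR thermometry.

Fluorescent nanodiamonds hosting nitrogen-vacancy (NV) centers act as
nanoscale thermometers on a fluorescence microscope: the axial zero-field
splitting *D* (~2870 MHz) of the NV ground-state spin shifts with
temperature at |d*D*/d*T*| = 77 kHz/K, and *D* is read out by sweeping an
applied microwave frequency ω and fitting the resulting optically detected
magnetic resonance (ODMR) spectrum with two Lorentzian dips:

```
I(ω) = 1 − (a₁/γπ) · 1/(1 + ((ω − D − E)/γ)²) − (a₂/γπ) · 1/(1 + ((ω − D + E)/γ)²)
```

with rhombic splitting *E*, half-width at half-maximum γ, and amplitude
coefficients a₁, a₂ (dip depths a/γπ).  With a fixed budget of sweep points,
the *range* over which those points are spread controls how precisely *D* —
and hence temperature — can be determined.  `nvtherm` provides:

- the line-shape model, sweep-grid convention, and *D* ↔ temperature
  conversion (`nvtherm.spectral_model`);
- a synthetic microscope: noisy digital-sweep spectra and wide-field TIFF
  image stacks of diffraction-blurred bright spots, with JSON ground truth
  (`nvtherm.synthetic_data`);
- double-Lorentzian least-squares fitting plus both temperature-accuracy
  metrics, in K/Hz^1/2: the SD of repeated *D* determinations and the fit
  standard error of a single sweep (`nvtherm.fitting`);
- the Monte Carlo optimization of the sweep range centered at 2870 MHz and
  the paired narrow-vs-wide win-probability comparison
  (`nvtherm.sweep_optimizer`);
- the end-to-end image-stack pipeline: bright-spot detection, 7 µm × 7 µm
  ROI spectrum extraction, decomposition of the 100-point 2850–2890 MHz
  sweep into its 2860–2880 and 2850–2890 MHz 50-point sub-sweeps, repeated
  fitting, and per-spot accuracy reports (`nvtherm.widefield_pipeline`).

It is aimed at experimenters planning wide-field ODMR temperature imaging
and at anyone who wants the sweep-design simulation as reusable, tested
code.

## Worked example

```python
from nvtherm import (MEAN_PARAMS, NoiseModel, SweepGrid, accuracy_from_fit_error,
                     fit_spectrum, signal_halfwidth, simulate_spectrum)

print(f"signal half-width: {signal_halfwidth(MEAN_PARAMS):.2f} MHz")
grid = SweepGrid(2860.0, 2880.0, 50)          # the optimized narrow sweep
spec = simulate_spectrum(MEAN_PARAMS, grid, NoiseModel(level=0.10), rng=1)
fit = fit_spectrum(spec)
acc = accuracy_from_fit_error(fit, spec.sweep_time)
print(f"D_obs = {fit.d_obs:.3f} +/- {fit.se_d:.3f} MHz (true 2869.340)")
print(f"single-sweep accuracy: {acc.value:.2f} K/Hz^1/2")
```

prints

```
signal half-width: 18.56 MHz
D_obs = 2869.611 +/- 0.204 MHz (true 2869.340)
single-sweep accuracy: 2.64 K/Hz^1/2
```

The half-width 2γ + 2E = 18.56 MHz is the natural scale of the two-dip
signal; the optimal sweep span turns out to sit just above it.  One noisy
1-second 50-point sweep at 10 % noise localizes *D* to ±0.20 MHz, i.e. a
temperature uncertainty of 0.204/0.077 ≈ 2.6 K for 1 s of measurement.

The same machinery is scriptable from the shell:

```sh
nvtherm simulate --out scene.tiff --seed 3 --n-spots 10 --n-repeats 50
nvtherm analyze scene.tiff --out-prefix results/scene
nvtherm optimize --out-prefix results/design --seed 1 --plot
```

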