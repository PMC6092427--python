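# tubekin

Kinematic analysis of oscillatory tip growth.

Tip-growing cells — pollen tubes, root hairs, fungal hyphae — elongate
from a dome-shaped apex, and many pollen tubes do so in pulses: the tip
velocity oscillates with a period of tens of seconds. `tubekin` is a
toolkit for analysing those oscillations from velocity records or
time-lapse image stacks. Its organising idea is that the oscillation is
most naturally described in **space** rather than time: the distance the
tip advances during one cycle (the wavelength λ) is markedly more stable
than the cycle duration (the period τ), and each cycle covers equal
distances below and above the mean velocity.

The core model is a *spatial bi-oscillator*: the tip velocity as a
function of the distance `s` the tip has travelled,

    v(s) = v̂ [ a sin(2πs/λ) + b sin(4πs/λ) + 1 ],

two in-phase sine modes (wavelengths λ and λ/2) around the spatial mean
velocity v̂, with dimensionless amplitudes `a` and `b` as the only free
parameters (|a| + |b| ≤ 0.95 keeps v > 0). A spatial profile is projected
into the time domain through t = ∫ v(s)⁻¹ ds, which reproduces the
asymmetric, pulsing and doubly-periodic waveforms seen in velocity
records — slow cells automatically acquire long periods at fixed λ.

The package provides, as importable modules and a `tubekin` CLI:

- **`synthetic`** — generate velocity records, 159-cell populations and
  rendered time-lapse TIFF stacks with known ground truth (λ̄ = 6.3 μm,
  population CV 27%; v̄ = 0.16 μm/s, CV 24%; 2-s sampling; 0.1339 μm
  pixels).
- **`model`** — evaluate the bi-oscillator, map between space and time
  domains, and fit (a, b) to observed cycles by constrained least
  squares in the space domain.
- **`kinematics`** — Savitzky–Golay + moving-average smoothing, cycle
  segmentation at velocity maxima, per-cell summaries (λ̄, τ̄,
  v̄ = λ̄/τ̄, CVs), population statistics and correlations, and an
  ergodicity comparison of one long-tracked cell against a population.
- **`symmetry`** — the slow/fast symmetry ratios
  S_time = |{t : v < v̄}| / |{t : v ≥ v̄}| and
  S_space = |{s : v < v̂}| / |{s : v ≥ v̂}| per complete cycle, plus
  period-binned population curves.
- **`precision`** — endpoint-error propagation P_τ = 2ε/τ and
  P_λ = 2εv*/λ, with the characteristic endpoint velocity v*.
- **`tracking`** — spline-based contour tracking of a growing tube in an
  image stack, growth-axis/pole extraction, tip-velocity series,
  tube-width profiles and kymographs.

## Worked example

```python
from tubekin import GeneratorConfig, generate_cell
from tubekin.pipeline import analyze_cell, PipelineParams

cfg = GeneratorConfig(a=0.5, b=-0.3, lambda_mean=6.3, vhat_mean=0.16, seed=7)
profile, series = generate_cell(cfg)          # one synthetic cell, 8 cycles
result = analyze_cell(series, PipelineParams(fit_cycles=True))
rec = result.record
print(f"wavelength: {rec.lambda_mean:.2f} um (CV {rec.cv_lambda:.0f}%)")
print(f"period:     {rec.tau_mean:.1f} s  (CV {rec.cv_tau:.0f}%)")
print(f"velocity:   {rec.v_mean:.3f} um/s")
```

prints

```
wavelength: 5.89 um (CV 8%)
period:     48.6 s  (CV 13%)
velocity:   0.121 um/s
```

Six complete cycles are segmented from the record (the two incomplete
edge cycles are discarded). The wavelength fluctuates less than the
period (CV 8% vs 13%) even though both inherit the same generator
jitter — the period also absorbs the velocity fluctuations through
τ = λ/v. The same analysis object carries the per-cycle symmetry ratios
(here S_space ≈ 0.98 — a ratio of 1 means equal distances covered in the
slow and fast phases — while S_time ≈ 1.06 > 1 because the slow phase
takes disproportionately long), the fitted bi-oscillator amplitudes
(a ≈ 0.47, b ≈ −0.22; slightly attenuated by smoothing), and the
measurement-precision block (P_τ ≈ 8%, P_λ ≈ 16%: the wavelength is
measured *less* precisely than the period, so an observed excess
fluctuation of the period cannot be a measurement artifact).

The same pipeline runs from the shell:

```sh
tubekin simulate --seed 1 --n-cells 159 --out sim/
tubekin analyze  --input sim/ --out analysis/
tubekin simulate --seed 2 --n-cells 1 --render --out one/
tubekin track    --stack one/stack.tif --out tracked/
```

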