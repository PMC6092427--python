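# Methods

## The model

The tip velocity of an oscillatory, polarly growing cell is modelled in
the space domain as

    v(s) = v̂ [ a sin(2πs/λ) + b sin(4πs/λ) + 1 ],

where `s` is the distance the tip has advanced, λ the wavelength of one
oscillation (μm), v̂ the spatial mean velocity (μm/s), and `a`, `b` the
dimensionless amplitudes of the two sine modes. The functional form
encodes three assumptions: the wavelength is fixed; the inter-sine phase
is zero, so v − v̂ is antisymmetric about λ/2 and equal distances are
covered below and above the mean; and only the first two modes are
retained (they suffice for symmetric, asymmetric, pulsing and
doubly-periodic waveforms; higher modes are out of scope). The
constraint |a| + |b| ≤ 0.95 keeps v ≥ 0.05 v̂, so the time projection
t = ∫ v(s)⁻¹ ds is well conditioned; 0.95 rather than 1.0 is a
deliberate conditioning margin.

Two identities are used throughout and serve as internal cross-checks:

- The cycle-mean velocity v̄ = λ/τ is the *harmonic* spatial mean of
  v(s); `harmonic_velocity_factor(a, b)` gives v̄/v̂, equal to √(1 − a²)
  when b = 0, and hence the closed-form period τ = λ/(v̂√(1 − a²)) for a
  single-sine cycle.
- v̄ ≤ v̂ always, so slow phases last disproportionately long in time.

### Parameter identifiability and fitting

Cycles are delimited at velocity maxima, so before fitting, the model is
circularly shifted to put its global maximum at the cycle start. After
that alignment, (a, b) and (−a, b) generate identical waveforms (the sign
of `a` is a half-wavelength phase shift), so the fit is constrained to
a ≥ 0; the sign of `b` is identifiable (it mirrors the waveform
left-right). λ and v̂ are fixed at the measured cycle extent and spatial
mean; only (a, b) are free. The objective is the summed squared residual
in the *space* domain — residuals in time would over-weight the slow
phase. Optimisation is SLSQP from a deterministic coarse grid of starts
(the mirror symmetries create distant local minima), with bounds
a ∈ [0, 0.95], |b| ≤ 0.95 and the linear constraint a + |b| ≤ 0.95.
Cycles whose peak-to-trough amplitude is below 5% of v̂ are flagged
non-oscillatory and not fitted. On noiseless model-generated cycles the
fit recovers (a, b) to ~1e−8; on smoothed measured cycles the recovered
amplitudes are attenuated by a few percent (the moving-average stage
reduces amplitude but not peak positions).

## Synthetic data

The generator is the test bed for every downstream stage; its defaults
are the study conditions of time-lapse records of lily pollen tubes:

| parameter | default | meaning |
|---|---|---|
| λ̄ population mean / CV | 6.3 μm / 27% | per-cell mean wavelength |
| v̄ population mean / CV | 0.16 μm/s / 24% | per-cell mean velocity |
| within-cell λ CV / v̂ CV | 15% / 16% | per-cycle jitter |
| a, b | 0.5, −0.3 | waveform (asymmetric, left-leaning) |
| n_cycles | 8 | ≈ 5 min of record at τ ≈ 40 s |
| dt | 2 s | acquisition interval |
| noise_sd | 0.008 μm/s | 5% of v̂; additive Gaussian |
| pixel scale | 0.1339 μm | rendering and kymographs |

Each cycle is one wavelength of the bi-oscillator with its own jittered
(λᵢ, v̂ᵢ), anchored at the velocity maximum so cycle boundaries coincide
with the maxima the segmentation looks for. Jitter is lognormal,
parameterised by arithmetic mean and CV — positivity is guaranteed and
the CV parameterisation is natural; the within-cell CVs (15%, 16%) were
chosen so the *emergent* per-cycle period CV is ≈ √(0.15² + 0.16²) ≈ 22%,
i.e. the period is intrinsically more variable than the wavelength —
the qualitative headline the generator must reproduce. Mode switches
(`mode_schedule`) are abrupt at a cycle boundary, with no interpolation.

Populations draw per-cell (λ̄ₖ, v̄ₖ) independently; the period then
*emerges* as τ̄ₖ = λ̄ₖ/v̄ₖ, which by itself forces R(λ̄, τ̄) > 0 and
R(v̄, τ̄) < 0 — the triplets are confined to the surface v = λ/τ by
construction. The drawn v̄ₖ is the observable cycle-mean velocity, so the
generator converts it to the spatial mean it needs via
v̂ = v̄/harmonic_velocity_factor(a, b); omitting this conversion biases
the realised population velocity low by ≈ 15–20% for the default
waveform.

Rendered stacks depict a straight tube of constant width (15 μm) capped
by a semicircular tip on a light background (dark tube, as in
bright-field), with a Gaussian-profile edge (σ = 1.5 px) and the apex
advancing by the cumulative integral of the velocity series; ground-truth
sub-pixel apex positions are returned alongside. What the renderer does
*not* emulate: tube curvature, cytoplasmic texture, illumination
gradients, debris, focus drift. Tracking results on these stacks
therefore demonstrate the correctness of the geometry pipeline, not
robustness to real micrographs.

## Cycle kinematics

Raw records are smoothed by a Savitzky–Golay filter (window 7 samples,
order 3, at dt = 2 s) followed by a centred moving average (window 3,
shrinking at the boundaries). The filters are named by the protocol; the
window sizes are this package's defaults, chosen well below the shortest
expected period (≈ 14 s = 7 samples) so peak positions are preserved.
Cycle boundaries are local maxima of the smoothed record with prominence
≥ 20% of its peak-to-trough range (large enough to reject the secondary
hump of doubly-periodic waveforms), refined to sub-sample precision by a
three-point parabola. Per cycle, τ is the boundary spacing and λ the
trapezoid integral of the *raw* velocity between the exact boundary
times (smoothing attenuates amplitude and would bias λ); v̄ = λ/τ holds
by definition. Incomplete edge cycles are discarded, so an n-cycle
record yields at most n − 2 measured cycles.

Oscillatory windows require peak-to-trough amplitude ≥ 25% of the local
mean velocity and at least 2 consecutive cycles of similar duration
(within a factor 2.5 of the median qualifying duration); terminal
windows extend to the record edges and the excluded fraction is
reported.

Cell summaries use the ratio of means v̄ₖ = λ̄ₖ/τ̄ₖ and sample (n−1)
standard deviations; CVs are (std/mean)×100%. Population analyses
require ≥ 4 complete cycles per cell and ≥ 3 cells. The ergodicity
report compares one long-tracked cell's per-cycle values against the
population's per-cell means: a two-sample Kolmogorov–Smirnov statistic
plus the overlap coefficient of the value ranges (intersection over the
smaller range — normalising by the population range alone is unstable
under lognormal outliers). "Ergodic-consistent" means every overlap
≥ 0.8.

### Measurement error

Boundary selection carries ±1 frame (±2 s) of error per endpoint, giving
P_τ = 2ε/τ and P_λ = 2εv*/λ, where v* — the velocity at the endpoints,
i.e. at the maxima — is read from the smoothed record (raw boundary
values would inflate it with noise). Since v* > v̄, P_λ/P_τ = v*/v̄ > 1:
wavelengths are measured *less* precisely than periods, which is what
makes the observed excess fluctuation of the period meaningful rather
than artefactual. Per-cycle λ recovery on jittered synthetic records is
limited by exactly this endpoint effect (median ≈ 1–4% error at dt = 2 s),
consistent with the P_λ formula; with zero jitter recovery is exact to
the quadrature tolerance.

## Symmetry ratios

S_time and S_space split one complete cycle at its time-mean v̄ and
space-mean v̂ respectively; measures are computed from uniform samples
with linear interpolation at threshold crossings, and samples exactly at
the mean count toward the "≥" set (the convention here; ties are not
otherwise specified). Cycles with amplitude below 5% of the mean are
reported as missing. Two numerical points matter at a 2-s sampling
interval: (i) measured cycles are first re-sampled onto a 512-point
monotone (PCHIP) grid between the exact sub-sample boundary times —
sample-aligned cropping plus the raw ~20–25 samples per cycle otherwise
bias S_space low by up to tens of percent; (ii) with that interpolation,
noiseless measured cycles give S_space = 0.985 ± 0.001 (the residual
bias is the PCHIP shape error near the sharp velocity maximum).

For every admissible (a, b), S_space = 1 exactly in the continuum (the
antisymmetry argument above). S_time > 1 — the time domain biased toward
slow velocities — holds for first-mode-dominant waveforms, including
every single-sine cycle and the default (0.5, −0.3); it is *not*
universal (e.g. a = 0.3, b = 0.2 gives S_time ≈ 0.78, a short dwell at a
high shoulder), so the package asserts it only where it holds.

## Contour tracking

Outlines are points equally spaced in arc length along a cubic spline
(periodic for closed contours, clamped for the open, tip-spanning curve
whose distal endpoints stay fixed). Per frame, each point moves along
its local normal to the maximum intensity-gradient magnitude within
±5 px (0.25-px sampling, parabolic sub-pixel refinement), then the
contour is re-splined. Two stabilising choices:

- Re-splining uses a smoothing allowance of 0.2 px² per point. With pure
  interpolation the contour develops self-amplifying creases at the
  high-curvature tip during growth bursts (> 2 px/frame) and collapses;
  0.2 is the smallest tested level stable on burst stacks while keeping
  static-stack drift below 0.5 px. The cost is a small inward bias at
  the cap (apex RMS error ≈ 0.3 px on ground truth).
- The edge-loss threshold is 5% of the frame's intensity range per
  pixel, with an absolute floor so featureless frames fail loudly; > 10%
  lost points in a frame is a tracking failure.

The growth axis is found from the orthogonal paths that lead from each
point of the last outline back to the first by successive
minimal-distance projections. On a blunt hemispherical cap the path
*length* is nearly flat over an arc of starting points, so the single
longest path is laterally arbitrary; the near-longest paths (≥ 98% of
the maximum) are averaged — they straddle the apex symmetrically — and a
total-least-squares line through the averaged path is the axis. The pole
at each frame is the apical intersection of that line with the outline.
Growth is declared absent when the *net* tip displacement is below 1 px
(jitter accumulates along a path but does not displace it), in which
case the velocity series is zero by definition. The tip velocity is the
frame-to-frame along-axis displacement of the five-point contour
neighbourhood around the pole, converted to μm/s.

Kymographs reslice the stack along a 1-px line on the growth axis by
nearest-pixel lookup (pixel centres at integer coordinates, origin
top-left, x = column), one row per frame. Cycle measurements trace the
tip edge per row (maximum gradient, parabolic sub-pixel), difference it
into a velocity record, and reuse the standard smoothing + segmentation;
an absolute amplitude guard (≥ 10% of the mean velocity) keeps
edge-quantisation wiggle on steady growth from being segmented into
cycles. On rendered ground truth the kymograph- and tracking-derived
per-cycle (λ, τ) agree to well under one pixel, and the full
render → track → segment round trip recovers per-cycle (λ, τ) with
median relative error ≈ 1–2%.

## Problem sizes and numerics

Default analyses use 1024 spatial points per generated cycle, 256-point
resampling for fits, 512-point cycle interpolation and ds = λ/2048 for
symmetry, and 2048+ point grids for quadrature oracles; population runs
use 159 cells × 8 cycles. These sizes put all discretisation errors at
least an order of magnitude below the assertion tolerances while keeping
a full population analysis at ≈ 1 s and the complete test suite well
under a minute apart from the imaging round trip. Seeds: every source of
randomness flows from a single integer seed (populations spawn per-cell
seeds from it), and identical seeds give bit-identical outputs.

## Known limitations

- The tracker is validated on rendered stacks only; it has no
  illumination correction or debris rejection and assumes one dominant,
  roughly horizontal tube.
- The generator's lognormal jitter and abrupt mode switches are modelling
  choices; the underlying protocol reports no within-cycle noise model.
- The fitted (a, b) inherit smoothing attenuation (a few percent); fits
  on raw cycles are noisier but unbiased.
- S_space on measured cycles carries a ≈ 1–2% interpolation bias at 2-s
  sampling even without noise.
- No spectral/wavelet period estimation: periods are strictly
  peak-to-peak, and no mechanistic (ODE) oscillator is included — the
  sine basis is motivated by, but not coupled to, harmonic-oscillator
  dynamics.
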