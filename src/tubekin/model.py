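"""The spatial bi-oscillator and the space ↔ time domain mappings.

The model describes the tip velocity of an oscillatory, polarly growing
cell as a function of the distance ``s`` the tip has advanced rather than
of time::

    v(s) = v̂ [ a sin(2πs/λ) + b sin(4πs/λ) + 1 ]

with λ the wavelength (distance covered per oscillation), v̂ the spatial
mean velocity, and two in-phase sine modes of wavelengths λ and λ/2 whose
dimensionless amplitudes ``a`` and ``b`` are the only free parameters.
The zero inter-sine phase makes v − v̂ antisymmetric about λ/2, so equal
distances are covered below and above the mean velocity.  A velocity
profile specified in space is projected into the time domain through
t = ∫ v(s)⁻¹ ds, which requires v > 0 everywhere; the constraint
|a| + |b| ≤ 0.95 keeps the velocity strictly positive with margin.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize, minimize_scalar

from .records import SpaceProfile, VelocityTimeSeries

__all__ = [
    "AMPLITUDE_LIMIT",
    "BiOscillatorFit",
    "bioscillator_velocity",
    "peak_phase",
    "elapsed_time",
    "map_space_to_time",
    "map_time_to_space",
    "fit_bioscillator",
]

#: largest admissible |a| + |b|; keeps v(s) ≥ 0.05 v̂ so the time mapping
#: t = ∫ ds/v stays well conditioned
AMPLITUDE_LIMIT = 0.95

_TWO_PI = 2.0 * np.pi


def bioscillator_velocity(s, a, b, lam, vhat, phase_origin=0.0):
    """Evaluate v(s) = v̂[a sin(2πs'/λ) + b sin(4πs'/λ) + 1], s' = s + phase_origin.

    ``phase_origin`` (μm) shifts the waveform; with ``phase_origin`` equal
    to :func:`peak_phase` times λ the global velocity maximum sits at s = 0.
    Periodic with period λ.
    """
    if lam <= 0 or vhat <= 0:
        raise ValueError("lam and vhat must be positive")
    x = _TWO_PI * (np.asarray(s, dtype=float) + phase_origin) / lam
    return vhat * (a * np.sin(x) + b * np.sin(2.0 * x) + 1.0)


def _waveform(x, a, b):
    """Dimensionless oscillatory part a sin(2πx) + b sin(4πx) on x ∈ [0, 1)."""
    return a * np.sin(_TWO_PI * x) + b * np.sin(2.0 * _TWO_PI * x)


def peak_phase(a: float, b: float, n_grid: int = 1024) -> float:
    """Phase fraction x* ∈ [0, 1) where the waveform attains its global maximum.

    Grid scan followed by a bounded scalar refinement; for a = b = 0 the
    waveform is flat and 0.25 (the single-sine maximum) is returned.
    """
    if a == 0.0 and b == 0.0:
        return 0.25
    x = np.arange(n_grid) / n_grid
    i = int(np.argmax(_waveform(x, a, b)))
    lo, hi = (i - 1) / n_grid, (i + 1) / n_grid
    res = minimize_scalar(
        lambda u: -_waveform(u, a, b), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x % 1.0)


def harmonic_velocity_factor(a: float, b: float, n_grid: int = 4096) -> float:
    """Ratio v̄/v̂ of the cycle-mean to the spatial-mean velocity.

    The period of one wavelength is τ = ∫ ds/v, so the cycle-mean
    velocity λ/τ is the *harmonic* spatial mean of v — always at most v̂,
    with equality only for a flat profile.  For b = 0 the factor reduces
    to √(1 − a²).
    """
    if abs(a) + abs(b) > AMPLITUDE_LIMIT:
        raise ValueError("|a| + |b| exceeds the positivity limit")
    x = (np.arange(n_grid) + 0.5) / n_grid
    return float(1.0 / np.mean(1.0 / (1.0 + _waveform(x, a, b))))


@dataclass
class BiOscillatorFit:
    """Fitted spatial bi-oscillator for one cycle.

    λ and v̂ are fixed by observation (measured wavelength and spatial mean
    velocity); only a and b are free.  ``phase_origin`` (μm) is the shift
    placing the model's global maximum at the cycle start, mirroring the
    convention that cycles are delimited at velocity maxima.
    """

    a: float
    b: float
    lam: float
    vhat: float
    phase_origin: float = 0.0
    rmse: float = float("nan")
    n_points: int = 0

    def __post_init__(self):
        if abs(self.a) + abs(self.b) > AMPLITUDE_LIMIT + 1e-9:
            raise ValueError(f"|a| + |b| must be <= {AMPLITUDE_LIMIT}")
        if self.lam <= 0 or self.vhat <= 0:
            raise ValueError("lam and vhat must be positive")

    def __call__(self, s):
        return bioscillator_velocity(s, self.a, self.b, self.lam, self.vhat,
                                     self.phase_origin)

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "lambda_um": self.lam,
            "vhat_um_s": self.vhat, "phase_origin_um": self.phase_origin,
            "rmse": self.rmse, "n_points": self.n_points,
        }


def elapsed_time(profile: SpaceProfile, positions=None):
    """t(s) = ∫ ds/v along the profile (trapezoid quadrature).

    Returns the elapsed-time array on the profile grid, or, if
    ``positions`` is given, t interpolated at those positions.
    """
    if np.any(profile.v <= 0):
        raise ValueError("time mapping requires v > 0 everywhere")
    t_of_s = cumulative_trapezoid(1.0 / profile.v, profile.s, initial=0.0)
    if positions is None:
        return t_of_s
    return np.interp(np.asarray(positions, dtype=float), profile.s, t_of_s)


def map_space_to_time(profile: SpaceProfile, dt: float) -> VelocityTimeSeries:
    """Project a spatial velocity profile into the time domain.

    t(s) is obtained by quadrature of 1/v; v(t) is resampled on a uniform
    grid of step ``dt`` with a monotone (PCHIP) interpolant, so no
    overshoot can drive the interpolated velocity negative.  The series
    spans t = 0 … t(s_end).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t_of_s = elapsed_time(profile)
    duration = t_of_s[-1]
    n = int(np.floor(duration / dt + 1e-9)) + 1
    t = np.arange(n) * dt
    v = PchipInterpolator(t_of_s, profile.v)(t)
    return VelocityTimeSeries(t, v, dt, profile.cell_id)


def map_time_to_space(series: VelocityTimeSeries, ds: float,
                      policy: str = "raise",
                      floor_frac: float = 1e-3) -> SpaceProfile:
    """Project a velocity time series into the space domain.

    s(t) is the cumulative trapezoid integral of v; v(s) is resampled on a
    uniform grid of step ``ds``.  Non-positive velocity samples make the
    mapping ill-defined: with ``policy="raise"`` (appropriate for raw
    records) they are an error, with ``policy="floor"`` (appropriate for
    smoothed records) they are clipped to ``floor_frac`` times the mean
    absolute velocity.
    """
    if ds <= 0:
        raise ValueError("ds must be positive")
    v = series.v.astype(float).copy()
    if np.any(v <= 0):
        if policy == "raise":
            raise ValueError("series contains non-positive velocities")
        elif policy == "floor":
            floor = floor_frac * float(np.mean(np.abs(v)))
            v = np.maximum(v, floor if floor > 0 else floor_frac)
        else:
            raise ValueError(f"unknown policy {policy!r}")
    s_of_t = cumulative_trapezoid(v, series.t, initial=0.0)
    n = int(np.floor(s_of_t[-1] / ds + 1e-9)) + 1
    s = np.arange(n) * ds
    vs = PchipInterpolator(s_of_t, v)(s)
    return SpaceProfile(s, vs, cell_id=series.cell_id)


def _resample_cycle(profile: SpaceProfile, n: int):
    """Uniform resampling of one anchored cycle onto n points over [0, λ)."""
    s0 = profile.s[0]
    lam = profile.length
    grid = np.arange(n) / n * lam
    interp = PchipInterpolator(profile.s - s0, profile.v, extrapolate=True)
    return grid, interp(grid), lam


def fit_bioscillator(cycle_profile: SpaceProfile, n_resample: int = 256,
                     amplitude_threshold: float = 0.05) -> BiOscillatorFit | None:
    """Fit (a, b) of the spatial bi-oscillator to one anchored cycle.

    The cycle is assumed to span exactly one wavelength and to start at
    its velocity maximum (the cycle delimiter used throughout).  λ is the
    cycle's measured extent and v̂ its spatial mean; both are fixed by
    observation.  The model is circularly shifted so that its own global
    maximum aligns with the cycle start, and (a, b) minimise the summed
    squared residuals in the space domain, subject to a ≥ 0 (the sign of
    ``a`` is a pure half-wavelength phase shift and is not identifiable
    after alignment) and |a| + |b| ≤ 0.95.  Deterministic multi-start on a
    coarse (a, b) grid avoids the mirror-symmetric local minima.

    Returns ``None`` for degenerate, non-oscillatory cycles whose
    peak-to-trough amplitude is below ``amplitude_threshold`` × v̂.
    """
    if n_resample < 64:
        raise ValueError("need at least 64 resampled points per wavelength")
    grid, vobs, lam = _resample_cycle(cycle_profile, n_resample)
    vhat = float(np.mean(vobs))
    if vhat <= 0:
        raise ValueError("cycle has non-positive mean velocity")
    if (vobs.max() - vobs.min()) < amplitude_threshold * vhat:
        return None  # non-oscillatory

    x = grid / lam  # phase fraction

    def sse(params):
        a, b = params
        model = vhat * (_waveform((x + peak_phase(a, b)) % 1.0, a, b) + 1.0)
        r = vobs - model
        return float(r @ r)

    # coarse deterministic start grid, a >= 0
    starts = [(a0, b0)
              for a0 in (0.05, 0.2, 0.4, 0.6, 0.8)
              for b0 in (-0.6, -0.4, -0.2, 0.0, 0.2, 0.4, 0.6)
              if a0 + abs(b0) <= 0.9]
    starts.sort(key=sse)
    best = None
    cons = ({"type": "ineq",
             "fun": lambda p: AMPLITUDE_LIMIT - p[0] - abs(p[1])},)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for x0 in starts[:4]:
            res = minimize(sse, x0, method="SLSQP",
                           bounds=[(0.0, AMPLITUDE_LIMIT),
                                   (-AMPLITUDE_LIMIT, AMPLITUDE_LIMIT)],
                           constraints=cons,
                           options={"maxiter": 200, "ftol": 1e-14})
            if best is None or res.fun < best.fun:
                best = res
    a, b = float(best.x[0]), float(abs(best.x[1])) * np.sign(best.x[1])
    # clip tiny constraint violations from the SQP steps
    if a + abs(b) > AMPLITUDE_LIMIT:
        scale = AMPLITUDE_LIMIT / (a + abs(b))
        a, b = a * scale, b * scale
    rmse = float(np.sqrt(sse((a, b)) / n_resample))
    return BiOscillatorFit(a=a, b=b, lam=lam, vhat=vhat,
                           phase_origin=peak_phase(a, b) * lam,
                           rmse=rmse, n_points=n_resample)
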