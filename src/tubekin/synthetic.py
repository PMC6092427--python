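"""Synthetic velocity records, cell populations, and rendered tube stacks.

Emulates time-lapse records of oscillatory pollen-tube growth: each cell's
velocity waveform is defined in the space domain by the spatial
bi-oscillator (wavelength λ, spatial mean v̂, mode amplitudes a, b), one
wavelength per cycle, with lognormal per-cycle jitter on (λ, v̂).  The
space profile is projected into the time domain through t = ∫ ds/v,
sampled at the acquisition interval, and corrupted with additive Gaussian
measurement noise.  Populations draw per-cell mean wavelength and mean
velocity independently, so the (λ̄, τ̄, v̄) triplets are confined to the
surface v = λ/τ and the correlation structure of the period emerges from
τ̄ = λ̄/v̄ alone.

Defaults reflect lily pollen tubes growing under standard culture
conditions: λ̄ = 6.3 μm (population CV 27%), v̄ = 0.16 μm/s (population CV
24%), 2-s sampling, 0.1339 μm pixels, within-cell per-cycle CVs of 15%
(λ) and 16% (v̂) so the emergent per-cycle period CV is ≈22%.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .model import (AMPLITUDE_LIMIT, bioscillator_velocity, elapsed_time,
                    harmonic_velocity_factor, map_space_to_time, peak_phase)
from .records import SpaceProfile, VelocityTimeSeries

__all__ = [
    "GeneratorConfig",
    "PopulationConfig",
    "RenderConfig",
    "generate_cell",
    "generate_population",
    "true_cycles",
    "render_tube_stack",
    "rough_outline_points",
]


@dataclass
class GeneratorConfig:
    """Per-cell generator settings.

    a, b : dimensionless bi-oscillator amplitudes (|a| + |b| ≤ 0.95 so the
        velocity never reverses).
    lambda_mean, lambda_cv : μm and fraction — per-cycle wavelength jitter.
    vhat_mean, vhat_cv : μm/s and fraction — per-cycle mean-velocity jitter.
    n_cycles : number of whole wavelengths generated.
    dt : s, sampling interval.
    noise_sd : μm/s, additive Gaussian measurement noise (default 5% of v̂).
    mode_schedule : optional [(cycle_index, a, b), ...] — abrupt waveform
        mode switches taking effect from the given cycle onward.
    points_per_cycle : spatial resolution of the generated profile.
    """

    a: float = 0.5
    b: float = -0.3
    lambda_mean: float = 6.3
    lambda_cv: float = 0.15
    vhat_mean: float = 0.16
    vhat_cv: float = 0.16
    n_cycles: int = 8
    dt: float = 2.0
    noise_sd: float = 0.008
    seed: int = 0
    mode_schedule: list | None = None
    points_per_cycle: int = 1024

    def validate(self) -> None:
        if abs(self.a) + abs(self.b) > AMPLITUDE_LIMIT:
            raise ValueError(
                f"|a| + |b| must be <= {AMPLITUDE_LIMIT} (velocity would reverse)")
        if self.mode_schedule:
            for _, a, b in self.mode_schedule:
                if abs(a) + abs(b) > AMPLITUDE_LIMIT:
                    raise ValueError("mode_schedule entry violates |a| + |b| <= 0.95")
        if self.lambda_mean <= 0 or self.vhat_mean <= 0:
            raise ValueError("lambda_mean and vhat_mean must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.lambda_cv < 0 or self.vhat_cv < 0 or self.noise_sd < 0:
            raise ValueError("dispersion parameters must be non-negative")


@dataclass
class PopulationConfig:
    """Population generator: independent lognormal per-cell (λ̄_k, v̄_k) draws."""

    n_cells: int = 159
    lambda_pop_mean: float = 6.3
    lambda_pop_cv: float = 0.27
    v_pop_mean: float = 0.16
    v_pop_cv: float = 0.24
    within_cell: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if self.lambda_pop_mean <= 0 or self.v_pop_mean <= 0:
            raise ValueError("population means must be positive")
        self.within_cell.validate()


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int):
    """Lognormal draws parameterised by arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean, dtype=float)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _cycle_modes(config: GeneratorConfig):
    a = np.full(config.n_cycles, config.a)
    b = np.full(config.n_cycles, config.b)
    if config.mode_schedule:
        for idx, ai, bi in sorted(config.mode_schedule):
            a[idx:] = ai
            b[idx:] = bi
    return a, b


def generate_cell(config: GeneratorConfig) -> tuple[SpaceProfile, VelocityTimeSeries]:
    """Generate one cell: a spatial profile and its noisy time series.

    Each of the ``n_cycles`` cycles is one wavelength of the bi-oscillator
    with its own jittered (λ_i, v̂_i), anchored so the cycle starts at the
    velocity maximum (the cycle delimiter used by the analysis).  The time
    series is the space → time projection resampled at ``dt`` with i.i.d.
    Gaussian noise added; the underlying velocity is strictly positive.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lams = _lognormal(rng, config.lambda_mean, config.lambda_cv, config.n_cycles)
    vhats = _lognormal(rng, config.vhat_mean, config.vhat_cv, config.n_cycles)
    a_arr, b_arr = _cycle_modes(config)

    ppc = config.points_per_cycle
    seg_s, seg_v = [], []
    offset = 0.0
    boundaries = [0.0]
    for lam, vhat, a, b in zip(lams, vhats, a_arr, b_arr):
        srel = np.arange(ppc) / ppc * lam
        phase = peak_phase(a, b) * lam
        seg_s.append(offset + srel)
        seg_v.append(bioscillator_velocity(srel, a, b, lam, vhat, phase))
        offset += lam
        boundaries.append(offset)
    # close the profile at the final boundary (periodic: v(λ) = v(0))
    seg_s.append(np.array([offset]))
    seg_v.append(np.array([seg_v[-1][0] if ppc else 0.0]))
    profile = SpaceProfile(np.concatenate(seg_s), np.concatenate(seg_v),
                           np.array(boundaries), cell_id=f"cell{config.seed}")

    series = map_space_to_time(profile, config.dt)
    if config.noise_sd > 0:
        series.v = series.v + rng.normal(0.0, config.noise_sd, series.v.size)
    return profile, series


def true_cycles(profile: SpaceProfile) -> pd.DataFrame:
    """Ground-truth per-cycle table (λ_i, τ_i, v̄_i) from a generated profile."""
    if profile.cycle_boundaries is None:
        raise ValueError("profile carries no cycle boundaries")
    t_b = elapsed_time(profile, profile.cycle_boundaries)
    lam = np.diff(profile.cycle_boundaries)
    tau = np.diff(t_b)
    return pd.DataFrame({
        "cycle_index": np.arange(lam.size),
        "t_start_s": t_b[:-1],
        "tau_s": tau,
        "lambda_um": lam,
        "vbar_um_s": lam / tau,
    })


def generate_population(config: PopulationConfig):
    """Generate a population of cells with independent (λ̄_k, v̄_k) draws.

    Returns a list of (cell_id, SpaceProfile, VelocityTimeSeries).  All
    randomness flows from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lam_k = _lognormal(rng, config.lambda_pop_mean, config.lambda_pop_cv,
                       config.n_cells)
    v_k = _lognormal(rng, config.v_pop_mean, config.v_pop_cv, config.n_cells)
    child_seeds = rng.integers(0, 2**31 - 1, size=config.n_cells)
    # the drawn v̄_k is the observable cycle-mean velocity λ̄/τ̄; convert to
    # the spatial mean v̂ the waveform generator needs
    h = harmonic_velocity_factor(config.within_cell.a, config.within_cell.b)
    cells = []
    for k in range(config.n_cells):
        cfg = replace(config.within_cell, lambda_mean=float(lam_k[k]),
                      vhat_mean=float(v_k[k]) / h, seed=int(child_seeds[k]))
        profile, series = generate_cell(cfg)
        cell_id = f"cell{k:03d}"
        profile.cell_id = cell_id
        series.cell_id = cell_id
        cells.append((cell_id, profile, series))
    return cells


# ---------------------------------------------------------------------------
# image-stack rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderConfig:
    """Rendered time-lapse settings (bright-field-like: dark tube, light bg).

    The tube is straight, of constant width, capped by a semicircular tip;
    the apex advances by the cumulative integral of the velocity series.
    ``pixel_scale`` defaults to 0.1339 μm/pixel and ``frame_interval`` to
    the 2-s acquisition interval.
    """

    tube_width: float = 15.0          # μm
    pixel_scale: float = 0.1339       # μm / pixel
    frame_interval: float = 2.0       # s
    image_size: tuple = (160, 384)    # (rows, cols) pixels
    edge_blur_sd: float = 1.5         # pixels
    background: float = 200.0         # intensity level
    foreground: float = 60.0          # intensity level
    initial_tip_px: float | None = None   # default: tube radius + 16 px
    intensity_noise_sd: float = 0.0   # additive intensity noise
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        if self.tube_width <= 0 or self.frame_interval <= 0:
            raise ValueError("tube_width and frame_interval must be positive")


def render_tube_stack(series: VelocityTimeSeries, config: RenderConfig):
    """Render a growing-tube image stack with ground-truth tip positions.

    Returns ``(stack, truth)`` where ``stack`` is a (frames, rows, cols)
    uint8 array (one frame per velocity sample) and ``truth`` a DataFrame
    with the sub-pixel apex position per frame.  Raises if the tube would
    leave the frame.
    """
    config.validate()
    if np.any(series.v < 0):
        raise ValueError("rendering requires a non-negative velocity series")
    if abs(series.dt - config.frame_interval) > 1e-9:
        raise ValueError("series.dt must equal the render frame_interval")
    h, w = config.image_size
    r = 0.5 * config.tube_width / config.pixel_scale
    yc = 0.5 * (h - 1)
    if 2 * r + 4 > h:
        raise ValueError("tube wider than the frame")
    x0 = config.initial_tip_px if config.initial_tip_px is not None else r + 16.0

    from scipy.integrate import cumulative_trapezoid
    disp_px = cumulative_trapezoid(series.v, series.t, initial=0.0) / config.pixel_scale
    x_tip = x0 + disp_px
    margin = 3.0 * config.edge_blur_sd + 2.0
    if x_tip[-1] + margin >= w:
        raise ValueError("tube exits the frame; enlarge image_size or shorten the series")

    rng = np.random.default_rng(config.seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dy = yy - yc
    stack = np.empty((len(series), h, w), dtype=np.uint8)
    for f, tip in enumerate(x_tip):
        dx = xx - (tip - r)
        # signed distance to the capped-tube boundary
        d = np.where(dx <= 0, np.abs(dy) - r, np.hypot(dx, dy) - r)
        if config.edge_blur_sd > 0:
            inside = ndtr(-d / config.edge_blur_sd)
        else:
            inside = (d < 0).astype(float)
        img = config.background + (config.foreground - config.background) * inside
        if config.intensity_noise_sd > 0:
            img = img + rng.normal(0.0, config.intensity_noise_sd, img.shape)
        stack[f] = np.clip(img, 0, 255).astype(np.uint8)

    truth = pd.DataFrame({
        "frame": np.arange(len(series)),
        "t_s": series.t,
        "tip_x_px": x_tip,
        "tip_y_px": np.full(len(series), yc),
    })
    return stack, truth


def rough_outline_points(tip_x: float, yc: float, radius: float,
                         x_start: float = 2.0, n_flank: int = 12,
                         n_cap: int = 17) -> np.ndarray:
    """Rough open outline of a capped tube for tracker initialisation.

    Runs from (x_start, yc − r) along the top flank, around the
    semicircular cap, and back along the bottom flank to (x_start, yc + r).
    """
    xc = tip_x - radius
    top = np.linspace(x_start, xc, n_flank, endpoint=False)
    theta = np.linspace(np.pi / 2, -np.pi / 2, n_cap)
    cap_x = xc + radius * np.cos(theta)
    cap_y = yc - radius * np.sin(theta)
    bottom = np.linspace(xc, x_start, n_flank + 1)[1:]
    pts = np.concatenate([
        np.column_stack([top, np.full(top.size, yc - radius)]),
        np.column_stack([cap_x, cap_y]),
        np.column_stack([bottom, np.full(bottom.size, yc + radius)]),
    ])
    return pts
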