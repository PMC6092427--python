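"""Measurement-precision analysis for period and wavelength.

Cycle endpoints are placed at velocity maxima, each with a selection
error of ±ε (one time pixel, i.e. one frame interval, by default).  The
resulting relative precisions are

    P_τ = 2 ε / τ          (two endpoints, each ±ε)
    P_λ = 2 ε v* / λ

where v* is the characteristic velocity at the cycle endpoints — at the
maxima, so v* > v̄ — which converts the endpoint timing error into a
displacement error.  Because P_λ / P_τ = v*/v̄ > 1, the wavelength is
measured *less* precisely than the period, so an observed excess
fluctuation of the period over the wavelength cannot be a measurement
artifact.
"""
from __future__ import annotations

import numpy as np

from .records import CellRecord, VelocityTimeSeries

__all__ = [
    "period_precision",
    "wavelength_precision",
    "characteristic_endpoint_velocity",
    "precision_report",
]

#: default endpoint selection error: ±1 time pixel = ±1 frame
DEFAULT_EPSILON_FRAMES = 1.0


def period_precision(tau: float, epsilon: float) -> float:
    """P_τ = 2 ε / τ, in percent.  ``tau`` and ``epsilon`` share a unit."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    return 100.0 * 2.0 * epsilon / tau


def wavelength_precision(lam: float, v_star: float, epsilon: float) -> float:
    """P_λ = 2 ε v* / λ, in percent.

    Units must be consistent: ε in time units, v* in (length unit of λ)
    per (time unit of ε) — e.g. pixels and pixels/frame, or s and μm/s.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if epsilon < 0 or v_star < 0:
        raise ValueError("epsilon and v_star must be non-negative")
    return 100.0 * 2.0 * epsilon * v_star / lam


def characteristic_endpoint_velocity(series: VelocityTimeSeries,
                                     cycles) -> tuple[float, float]:
    """Mean velocity at the cycle endpoints and its ratio to the cell mean.

    ``series`` should be the smoothed record on which the endpoints (the
    velocity maxima) were detected; raw boundary values would inflate v*
    with measurement noise.  The ratio uses the cell mean v̄ = λ̄/τ̄.
    """
    cycles = list(cycles)
    if not cycles:
        raise ValueError("need at least one complete cycle")
    boundary_times = np.unique([c.t_start for c in cycles] +
                               [c.t_end for c in cycles])
    v_star = float(np.mean(np.interp(boundary_times, series.t, series.v)))
    vbar = float(np.mean([c.lam for c in cycles]) /
                 np.mean([c.tau for c in cycles]))
    return v_star, v_star / vbar


def precision_report(cell: CellRecord, smoothed: VelocityTimeSeries,
                     epsilon_s: float | None = None) -> dict:
    """Per-cell precision summary.

    ``epsilon_s`` defaults to one frame interval (the smoothed series'
    dt), the endpoint-reading convention for kymographs.
    """
    eps = smoothed.dt * DEFAULT_EPSILON_FRAMES if epsilon_s is None else epsilon_s
    v_star, ratio = characteristic_endpoint_velocity(smoothed, cell.cycles)
    return {
        "epsilon_s": float(eps),
        "P_tau_pct": period_precision(cell.tau_mean, eps),
        "P_lambda_pct": wavelength_precision(cell.lambda_mean, v_star, eps),
        "v_star_um_s": v_star,
        "v_star_ratio": ratio,
    }
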