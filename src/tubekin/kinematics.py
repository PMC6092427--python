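"""Cycle segmentation and kinematic statistics of velocity records.

A raw tip-velocity record is smoothed (Savitzky–Golay followed by a
centred moving average), local velocity maxima delimit the oscillatory
cycles (the maximum is the most precisely defined feature of a cycle),
and each cycle yields a period τ (maximum-to-maximum interval), a
wavelength λ (tip displacement over the cycle, integrated from the raw
record to avoid the amplitude attenuation of the smoothing filters), and
the cycle mean velocity v̄ = λ/τ.  Cell summaries use the ratio of means
v̄_k = λ̄_k/τ̄_k and coefficients of variation CV = (std/mean) × 100% with
the sample (n−1) standard deviation.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter
from scipy.stats import ks_2samp

from .records import CellRecord, Cycle, PopulationStats, VelocityTimeSeries

__all__ = [
    "smooth_velocity",
    "detect_cycle_boundaries",
    "segment_cycles",
    "select_oscillatory_windows",
    "summarize_cell",
    "population_statistics",
    "ergodicity_comparison",
    "integrate_displacement",
]

#: smoothing defaults at 2-s sampling
SG_WINDOW = 7
SG_ORDER = 3
MA_WINDOW = 3
#: minimum peak prominence as a fraction of the smoothed peak-to-trough range
PROMINENCE_FRAC = 0.2


def _moving_average_shrink(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; the window shrinks at the boundaries."""
    if window <= 1:
        return x.copy()
    num = np.convolve(x, np.ones(window), mode="same")
    den = np.convolve(np.ones_like(x), np.ones(window), mode="same")
    return num / den


def smooth_velocity(series: VelocityTimeSeries, sg_window: int = SG_WINDOW,
                    sg_order: int = SG_ORDER,
                    ma_window: int = MA_WINDOW) -> VelocityTimeSeries:
    """Savitzky–Golay local polynomial smoothing followed by a moving average.

    The Savitzky–Golay stage preserves the position of extrema (hence the
    period); the moving-average stage suppresses residual noise at the
    cost of some amplitude.  Windows are in samples and must be much
    shorter than the expected period; ``sg_window`` and ``ma_window``
    must be odd.
    """
    if sg_window % 2 == 0 or ma_window % 2 == 0:
        raise ValueError("sg_window and ma_window must be odd")
    if sg_order >= sg_window:
        raise ValueError("sg_order must be smaller than sg_window")
    if len(series) < max(sg_window, ma_window):
        raise ValueError("series shorter than the smoothing window")
    v = savgol_filter(series.v, sg_window, sg_order, mode="interp")
    v = _moving_average_shrink(v, ma_window)
    return VelocityTimeSeries(series.t, v, series.dt, series.cell_id)


def detect_cycle_boundaries(smoothed: VelocityTimeSeries,
                            prominence_frac: float = PROMINENCE_FRAC) -> np.ndarray:
    """Times of local velocity maxima, refined to sub-sample precision.

    Peaks must have prominence of at least ``prominence_frac`` times the
    series' peak-to-trough range, which keeps only the dominant maximum
    per wavelength in doubly-periodic waveforms.  Each discrete peak is
    refined by a quadratic through the three surrounding samples.
    Returns an empty array when fewer than two maxima are found.
    """
    v = smoothed.v
    vrange = float(v.max() - v.min()) if len(smoothed) else 0.0
    if vrange <= 0:
        return np.array([])
    peaks, _ = find_peaks(v, prominence=prominence_frac * vrange)
    if peaks.size < 2:
        return np.array([])
    times = []
    for i in peaks:
        delta = 0.0
        if 0 < i < v.size - 1:
            denom = v[i - 1] - 2.0 * v[i] + v[i + 1]
            if denom < 0:
                delta = np.clip(0.5 * (v[i - 1] - v[i + 1]) / denom, -0.5, 0.5)
        times.append(smoothed.t[i] + delta * smoothed.dt)
    return np.sort(np.asarray(times))


def _interp_v(series: VelocityTimeSeries, t: float) -> float:
    return float(np.interp(t, series.t, series.v))


def integrate_displacement(series: VelocityTimeSeries, t0: float, t1: float) -> float:
    """Trapezoid integral of v dt over [t0, t1] with interpolated endpoints."""
    if t1 <= t0:
        raise ValueError("need t1 > t0")
    t, v = series.t, series.v
    inside = (t > t0) & (t < t1)
    ts = np.concatenate([[t0], t[inside], [t1]])
    vs = np.concatenate([[_interp_v(series, t0)], v[inside],
                         [_interp_v(series, t1)]])
    return float(np.trapezoid(vs, ts))


def segment_cycles(raw: VelocityTimeSeries, boundaries) -> list:
    """Cut the record into cycles at the given maxima times.

    τ is the boundary spacing; λ the displacement integral of the *raw*
    velocity between boundaries; incomplete leading/trailing stretches of
    the record are implicitly discarded (only complete maxima-to-maxima
    cycles are returned).
    """
    boundaries = np.asarray(boundaries, dtype=float)
    if boundaries.size < 2:
        return []
    if np.any(np.diff(boundaries) <= 0):
        raise ValueError("boundaries must be strictly increasing")
    cycles = []
    for i, (t0, t1) in enumerate(zip(boundaries[:-1], boundaries[1:])):
        lam = integrate_displacement(raw, t0, t1)
        cycles.append(Cycle.make(t0, t1, lam, index=i))
    return cycles


def select_oscillatory_windows(series: VelocityTimeSeries,
                               min_repeats: int = 2,
                               amplitude_frac: float = 0.25,
                               prominence_frac: float = PROMINENCE_FRAC,
                               period_ratio_max: float = 2.5,
                               smoothed: VelocityTimeSeries | None = None):
    """Select time windows with a clear, repeated oscillation.

    A candidate cycle (the stretch between successive maxima of the
    smoothed record) qualifies when its peak-to-trough amplitude is at
    least ``amplitude_frac`` times its mean velocity and its duration is
    within a factor ``period_ratio_max`` of the median qualifying
    duration; runs of at least ``min_repeats`` consecutive qualifying
    cycles become windows.  Terminal windows are extended to the record
    edges.  Returns ``(windows, excluded_fraction)`` where each window is
    a (t_start, t_end) pair.
    """
    if smoothed is None:
        smoothed = smooth_velocity(series)
    maxima = detect_cycle_boundaries(smoothed, prominence_frac)
    duration = series.duration
    if maxima.size < 2 or duration <= 0:
        return [], 1.0

    n_candidates = maxima.size - 1
    amp_ok = np.zeros(n_candidates, dtype=bool)
    taus = np.diff(maxima)
    for i in range(n_candidates):
        seg = smoothed.crop(maxima[i], maxima[i + 1])
        if len(seg) < 2:
            continue
        mean_v = float(np.mean(seg.v))
        amp = float(seg.v.max() - seg.v.min())
        amp_ok[i] = mean_v > 0 and amp >= amplitude_frac * mean_v
    if not np.any(amp_ok):
        return [], 1.0
    tau_med = float(np.median(taus[amp_ok]))
    ok = amp_ok & (taus <= period_ratio_max * tau_med) \
                & (taus >= tau_med / period_ratio_max)

    windows = []
    i = 0
    while i < n_candidates:
        if ok[i]:
            j = i
            while j + 1 < n_candidates and ok[j + 1]:
                j += 1
            if j - i + 1 >= min_repeats:
                t0 = series.t[0] if i == 0 else maxima[i]
                t1 = series.t[-1] if j == n_candidates - 1 else maxima[j + 1]
                windows.append((float(t0), float(t1)))
            i = j + 1
        else:
            i += 1
    covered = sum(t1 - t0 for t0, t1 in windows)
    return windows, float(1.0 - covered / duration)


def summarize_cell(cell_id: str, cycles) -> CellRecord:
    """Within-cell summary; raises on an empty cycle list."""
    return CellRecord(cell_id=cell_id, cycles=list(cycles))


_VARIABLES = (
    ("wavelength (lambda) [um]", "lambda_mean"),
    ("period (tau) [s]", "tau_mean"),
    ("velocity (v) [um/s]", "v_mean"),
)


def _pearson(x, y) -> float:
    x, y = np.asarray(x), np.asarray(y)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")  # undefined for zero variance
    return float(np.corrcoef(x, y)[0, 1])


def population_statistics(cells, min_cycles: int = CellRecord.MIN_CYCLES_POPULATION
                          ) -> PopulationStats:
    """Population summary over per-cell means.

    Only cells with at least ``min_cycles`` complete cycles are included;
    at least three such cells are required.  Emits the per-variable
    range/mean/std/CV table, the pairwise Pearson correlations over
    per-cell means, and the (λ̄_k, τ̄_k, v̄_k) triplet table.
    """
    eligible = [c for c in cells if c.n_cycles >= min_cycles]
    if len(eligible) < 3:
        raise ValueError("need at least 3 cells with enough cycles")
    triplets = pd.DataFrame({
        "cell_id": [c.cell_id for c in eligible],
        "lambda_mean": [c.lambda_mean for c in eligible],
        "tau_mean": [c.tau_mean for c in eligible],
        "v_mean": [c.v_mean for c in eligible],
        "n_cycles": [c.n_cycles for c in eligible],
        "cv_lambda": [c.cv_lambda for c in eligible],
        "cv_tau": [c.cv_tau for c in eligible],
    })
    rows = []
    for label, col in _VARIABLES:
        x = triplets[col].to_numpy()
        mean = float(np.mean(x))
        std = float(np.std(x, ddof=1))
        rows.append({
            "variable": label,
            "min": float(x.min()), "max": float(x.max()),
            "mean": mean, "std": std,
            "cv_pct": 100.0 * std / mean if mean else float("nan"),
        })
    summary = pd.DataFrame(rows)
    corr = {
        "R_v_tau": _pearson(triplets["v_mean"], triplets["tau_mean"]),
        "R_v_lambda": _pearson(triplets["v_mean"], triplets["lambda_mean"]),
        "R_lambda_tau": _pearson(triplets["lambda_mean"], triplets["tau_mean"]),
    }
    return PopulationStats(summary=summary, correlations=corr,
                           triplets=triplets, n_cells=len(eligible))


def _range_overlap(cell_vals, pop_vals) -> float:
    """Overlap coefficient of the two value ranges.

    Intersection length divided by the smaller of the two ranges, so a
    matched cell scores near 1 even when a population outlier stretches
    the population range.
    """
    lo = max(np.min(cell_vals), np.min(pop_vals))
    hi = min(np.max(cell_vals), np.max(pop_vals))
    smaller = min(np.max(cell_vals) - np.min(cell_vals),
                  np.max(pop_vals) - np.min(pop_vals))
    if smaller <= 0:
        return 1.0 if hi >= lo else 0.0
    return float(max(hi - lo, 0.0) / smaller)


def ergodicity_comparison(long_cell: CellRecord, population: PopulationStats,
                          min_cycles: int = 20,
                          overlap_threshold: float = 0.8) -> dict:
    """Compare one long-tracked cell's per-cycle values with population means.

    For each kinematic variable the report gives the two-sample
    Kolmogorov–Smirnov statistic between the cell's per-cycle values and
    the population's per-cell means, and the overlap coefficient of the
    two value ranges.  ``ergodic_consistent`` is set
    when every overlap reaches ``overlap_threshold`` — the sense in which
    one long record reproduces the population's dynamics.
    """
    if long_cell.n_cycles < min_cycles:
        raise ValueError(f"long cell needs >= {min_cycles} cycles")
    cell_vals = {
        "lambda": np.array([c.lam for c in long_cell.cycles]),
        "tau": np.array([c.tau for c in long_cell.cycles]),
        "v": np.array([c.vbar for c in long_cell.cycles]),
    }
    pop_vals = {
        "lambda": population.triplets["lambda_mean"].to_numpy(),
        "tau": population.triplets["tau_mean"].to_numpy(),
        "v": population.triplets["v_mean"].to_numpy(),
    }
    report = {}
    for key in ("lambda", "tau", "v"):
        a, b = cell_vals[key], pop_vals[key]
        if np.array_equal(a, b):
            ks = 0.0  # degenerate self-comparison
        else:
            ks = float(ks_2samp(a, b).statistic)
        report[key] = {"ks_statistic": ks,
                       "range_overlap": _range_overlap(a, b)}
    report["ergodic_consistent"] = bool(
        all(report[k]["range_overlap"] >= overlap_threshold
            for k in ("lambda", "tau", "v")))
    return report
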