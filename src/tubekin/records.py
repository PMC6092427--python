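"""Core data containers shared across the pipeline.

The central observable is the tip velocity of a polarly growing cell,
either as a uniformly sampled function of time, ``v(t)``, or as a
function of the distance the tip has advanced, ``v(s)``.  One oscillation
of the elongation rate is a :class:`Cycle`, delimited by successive
velocity maxima; a cell contributes a :class:`CellRecord` of cycles, and a
set of cells is summarised by :class:`PopulationStats`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VelocityTimeSeries",
    "SpaceProfile",
    "Cycle",
    "CellRecord",
    "PopulationStats",
]

#: tolerance on sampling uniformity, seconds
_UNIFORMITY_TOL = 1e-9


@dataclass
class VelocityTimeSeries:
    """Uniformly sampled tip velocity.

    Parameters
    ----------
    t : array, s
    v : array, μm/s
    dt : float, s
        Sampling interval; ``t`` must be uniform to within 1 ns.
    cell_id : str
    """

    t: np.ndarray
    v: np.ndarray
    dt: float
    cell_id: str = "cell"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape or self.t.ndim != 1:
            raise ValueError("t and v must be 1-D arrays of equal length")
        if self.t.size >= 2:
            steps = np.diff(self.t)
            if np.max(np.abs(steps - self.dt)) > _UNIFORMITY_TOL:
                raise ValueError("time grid is not uniform at the stated dt")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def crop(self, t0: float, t1: float) -> "VelocityTimeSeries":
        """Return the sub-series with t0 <= t <= t1 (sample-aligned)."""
        keep = (self.t >= t0 - _UNIFORMITY_TOL) & (self.t <= t1 + _UNIFORMITY_TOL)
        return VelocityTimeSeries(self.t[keep], self.v[keep], self.dt, self.cell_id)


@dataclass
class SpaceProfile:
    """Tip velocity as a function of tip position.

    ``cycle_boundaries`` (optional) are the positions delimiting whole
    wavelengths, including the profile's start and end.
    """

    s: np.ndarray
    v: np.ndarray
    cycle_boundaries: np.ndarray | None = None
    cell_id: str = "cell"

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.s.shape != self.v.shape or self.s.ndim != 1:
            raise ValueError("s and v must be 1-D arrays of equal length")
        if self.s.size >= 2 and np.any(np.diff(self.s) <= 0):
            raise ValueError("s must be strictly increasing")
        if self.cycle_boundaries is not None:
            self.cycle_boundaries = np.asarray(self.cycle_boundaries, dtype=float)

    def __len__(self) -> int:
        return self.s.size

    @property
    def length(self) -> float:
        return float(self.s[-1] - self.s[0]) if len(self) else 0.0

    @property
    def n_cycles(self) -> int:
        if self.cycle_boundaries is None:
            return 0
        return max(self.cycle_boundaries.size - 1, 0)


@dataclass(frozen=True)
class Cycle:
    """One oscillation, delimited by successive velocity maxima.

    tau = t_end - t_start (s); lam = tip displacement over the cycle (μm);
    vbar = lam / tau (μm/s) by definition.
    """

    t_start: float
    t_end: float
    tau: float
    lam: float
    vbar: float
    index: int = 0

    @classmethod
    def make(cls, t_start: float, t_end: float, lam: float, index: int = 0) -> "Cycle":
        tau = float(t_end) - float(t_start)
        if tau <= 0:
            raise ValueError("cycle must have t_end > t_start")
        return cls(float(t_start), float(t_end), tau, float(lam), float(lam) / tau, index)


def _sample_std(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


@dataclass
class CellRecord:
    """A cell's cycles plus within-cell summary statistics.

    The cell mean velocity is the ratio of means, v̄ = λ̄/τ̄, not the mean
    of per-cycle ratios.  CVs are in percent with the sample (n−1) standard
    deviation.
    """

    cell_id: str
    cycles: list
    lambda_mean: float = field(init=False)
    lambda_std: float = field(init=False)
    tau_mean: float = field(init=False)
    tau_std: float = field(init=False)
    v_mean: float = field(init=False)
    cv_lambda: float = field(init=False)
    cv_tau: float = field(init=False)

    #: minimum number of complete cycles for population-level inclusion
    MIN_CYCLES_POPULATION = 4

    def __post_init__(self):
        if not self.cycles:
            raise ValueError("CellRecord requires at least one cycle")
        lams = np.array([c.lam for c in self.cycles])
        taus = np.array([c.tau for c in self.cycles])
        self.lambda_mean = float(np.mean(lams))
        self.lambda_std = _sample_std(lams)
        self.tau_mean = float(np.mean(taus))
        self.tau_std = _sample_std(taus)
        self.v_mean = self.lambda_mean / self.tau_mean
        self.cv_lambda = 100.0 * self.lambda_std / self.lambda_mean
        self.cv_tau = 100.0 * self.tau_std / self.tau_mean

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def eligible(self) -> bool:
        """True when the cell has enough cycles for population analyses."""
        return self.n_cycles >= self.MIN_CYCLES_POPULATION

    def to_frame(self) -> pd.DataFrame:
        """Per-cycle table (cell_id, cycle_index, t_start_s, tau_s, lambda_um, vbar_um_s)."""
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "cycle_index": [c.index for c in self.cycles],
                "t_start_s": [c.t_start for c in self.cycles],
                "tau_s": [c.tau for c in self.cycles],
                "lambda_um": [c.lam for c in self.cycles],
                "vbar_um_s": [c.vbar for c in self.cycles],
            }
        )


@dataclass
class PopulationStats:
    """Population-level summary over per-cell means.

    ``summary`` has one row per kinematic variable (wavelength, period,
    velocity) with range, mean, std and CV; ``correlations`` holds the
    pairwise Pearson coefficients over per-cell means; ``triplets`` is the
    (λ̄_k, τ̄_k, v̄_k) table, confined to the surface v = λ/τ by definition.
    """

    summary: pd.DataFrame
    correlations: dict
    triplets: pd.DataFrame
    n_cells: int
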