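"""End-to-end analysis orchestration: raw velocity records → run report.

Stages: smoothing → oscillatory-window selection → cycle segmentation →
cell and population summaries → per-cycle symmetry ratios → precision
estimates → (optionally) per-cycle bi-oscillator fits.  The resolved
parameter set is carried in :class:`PipelineParams` and persisted next to
the outputs, so every run is reproducible from its artefacts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinematics, precision, symmetry
from .model import fit_bioscillator, map_time_to_space
from .records import CellRecord, VelocityTimeSeries

logger = logging.getLogger("tubekin")

__all__ = ["PipelineParams", "CellAnalysis", "analyze_cell", "analyze_cells",
           "build_report", "REPORT_REQUIRED_KEYS"]


@dataclass
class PipelineParams:
    """Resolved analysis parameters (defaults match the module defaults)."""

    sg_window: int = kinematics.SG_WINDOW
    sg_order: int = kinematics.SG_ORDER
    ma_window: int = kinematics.MA_WINDOW
    prominence_frac: float = kinematics.PROMINENCE_FRAC
    window_min_repeats: int = 2
    window_amplitude_frac: float = 0.25
    min_cycles_population: int = CellRecord.MIN_CYCLES_POPULATION
    fit_cycles: bool = False
    fit_resample: int = 256
    symmetry_ds_points: int = 2048
    seed: int = 0


@dataclass
class CellAnalysis:
    """Everything the pipeline extracted from one cell's record."""

    cell_id: str
    record: CellRecord | None
    cycles: list
    windows: list
    excluded_fraction: float
    symmetry: pd.DataFrame
    fits: pd.DataFrame
    precision: dict | None


def analyze_cell(series: VelocityTimeSeries,
                 params: PipelineParams | None = None) -> CellAnalysis:
    """Run the full single-cell analysis on one raw velocity record."""
    params = params or PipelineParams()
    smoothed = kinematics.smooth_velocity(series, params.sg_window,
                                          params.sg_order, params.ma_window)
    windows, excluded = kinematics.select_oscillatory_windows(
        series, min_repeats=params.window_min_repeats,
        amplitude_frac=params.window_amplitude_frac,
        prominence_frac=params.prominence_frac, smoothed=smoothed)
    cycles = []
    for t0, t1 in windows:
        sm_win = smoothed.crop(t0, t1)
        boundaries = kinematics.detect_cycle_boundaries(sm_win,
                                                        params.prominence_frac)
        for c in kinematics.segment_cycles(series, boundaries):
            cycles.append(c)
    cycles = [type(c)(c.t_start, c.t_end, c.tau, c.lam, c.vbar, i)
              for i, c in enumerate(cycles)]

    sym_rows, fit_rows = [], []
    for c in cycles:
        if (c.t_end - c.t_start) < 3 * series.dt:
            continue
        crop = symmetry.interpolated_cycle(series, c.t_start, c.t_end)
        res = symmetry.symmetry_ratios(
            crop, ds=c.lam / params.symmetry_ds_points, cycle_index=c.index)
        sym_rows.append({"cell_id": series.cell_id, "cycle_index": c.index,
                         "tau_s": c.tau, "S_time": res.S_time,
                         "S_space": res.S_space})
        if params.fit_cycles:
            sm_crop = smoothed.crop(c.t_start, c.t_end)
            profile = map_time_to_space(
                sm_crop, ds=c.lam / params.fit_resample, policy="floor")
            fit = fit_bioscillator(profile, n_resample=params.fit_resample)
            row = {"cell_id": series.cell_id, "cycle_index": c.index,
                   "oscillatory": fit is not None}
            if fit is not None:
                row.update(fit.to_dict())
            fit_rows.append(row)

    record = None
    prec = None
    if cycles:
        record = kinematics.summarize_cell(series.cell_id, cycles)
        prec = precision.precision_report(record, smoothed)
    logger.info("cell %s: %d window(s), %d cycle(s), %.0f%% excluded",
                series.cell_id, len(windows), len(cycles), 100 * excluded)
    return CellAnalysis(series.cell_id, record, cycles, windows, excluded,
                        pd.DataFrame(sym_rows), pd.DataFrame(fit_rows), prec)


def analyze_cells(series_list, params: PipelineParams | None = None):
    """Analyse many cells; returns (analyses, population or None)."""
    params = params or PipelineParams()
    analyses = [analyze_cell(s, params) for s in series_list]
    records = [a.record for a in analyses
               if a.record is not None
               and a.record.n_cycles >= params.min_cycles_population]
    population = None
    if len(records) >= 3:
        population = kinematics.population_statistics(
            records, min_cycles=params.min_cycles_population)
    return analyses, population


#: keys every run report must contain (checked instead of a JSON-Schema
#: validation; see the report writer)
REPORT_REQUIRED_KEYS = ("n_cells_in", "n_cells_analyzed", "n_cycles",
                        "population", "symmetry_curve", "precision", "params")


def build_report(analyses, population, params: PipelineParams) -> dict:
    """Assemble the single-run JSON report."""
    all_sym = [a.symmetry for a in analyses if len(a.symmetry)]
    sym_df = pd.concat(all_sym, ignore_index=True) if all_sym else pd.DataFrame()
    curve = []
    if len(sym_df) >= 100:
        curve = symmetry.population_symmetry_curve(sym_df).to_dict("records")
    pop_block = None
    if population is not None:
        pop_block = {
            "n_cells": population.n_cells,
            "variables": population.summary.to_dict("records"),
            "correlations": population.correlations,
        }
    precisions = [a.precision for a in analyses if a.precision]
    prec_block = None
    if precisions:
        prec_block = {
            "P_tau_pct_mean": float(np.mean([p["P_tau_pct"] for p in precisions])),
            "P_lambda_pct_mean": float(np.mean([p["P_lambda_pct"]
                                                for p in precisions])),
            "v_star_ratio_mean": float(np.mean([p["v_star_ratio"]
                                                for p in precisions])),
        }
    report = {
        "n_cells_in": len(analyses),
        "n_cells_analyzed": sum(1 for a in analyses if a.record is not None),
        "n_cycles": int(sum(len(a.cycles) for a in analyses)),
        "population": pop_block,
        "symmetry_curve": curve,
        "precision": prec_block,
        "params": params.__dict__,
    }
    missing = [k for k in REPORT_REQUIRED_KEYS if k not in report]
    assert not missing, f"report missing keys: {missing}"
    return report
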