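"""Smoothing, cycle segmentation, and kinematic statistics."""
import numpy as np
import pytest

from tubekin import GeneratorConfig, PopulationConfig, generate_cell, generate_population
from tubekin.kinematics import (detect_cycle_boundaries, ergodicity_comparison,
                                population_statistics, segment_cycles,
                                select_oscillatory_windows, smooth_velocity,
                                summarize_cell)
from tubekin.records import Cycle, VelocityTimeSeries
from tubekin.synthetic import true_cycles

DT = 2.0


def series_from(v, dt=DT):
    return VelocityTimeSeries(np.arange(len(v)) * dt, np.asarray(v, float), dt)


def sine_series(period=40.0, n=200, amp=0.05, mean=0.16, dt=DT, noise=0.0, seed=0):
    t = np.arange(n) * dt
    v = mean + amp * np.sin(2 * np.pi * t / period)
    if noise:
        v = v + np.random.default_rng(seed).normal(0, noise, n)
    return VelocityTimeSeries(t, v, dt)


class TestSmoothing:
    def test_constant_unchanged(self):
        s = series_from(np.full(100, 0.16))
        assert np.allclose(smooth_velocity(s).v, 0.16)

    def test_peak_spacing_preserved_on_sine(self):
        s = sine_series()
        sm = smooth_velocity(s)
        raw_peaks = detect_cycle_boundaries(
            VelocityTimeSeries(s.t, s.v, DT))
        smooth_peaks = detect_cycle_boundaries(sm)
        assert len(raw_peaks) == len(smooth_peaks)
        assert np.all(np.abs(np.diff(raw_peaks) - np.diff(smooth_peaks)) <= DT)

    def test_noise_reduction(self):
        clean = sine_series()
        noisy = sine_series(noise=0.01, seed=1)  # SNR 5
        sm = smooth_velocity(noisy)
        before = np.std(noisy.v - clean.v)
        after = np.std(sm.v - clean.v)
        assert after <= before / 2

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            smooth_velocity(series_from(np.ones(4)))
        with pytest.raises(ValueError):
            smooth_velocity(sine_series(), sg_window=6)


class TestBoundaryDetection:
    def test_noiseless_cycles_found(self):
        cfg = GeneratorConfig(seed=1, noise_sd=0.0, lambda_cv=0.05, vhat_cv=0.05)
        profile, series = generate_cell(cfg)
        truth = true_cycles(profile)
        b = detect_cycle_boundaries(smooth_velocity(series))
        # interior boundaries only: first/last maxima sit at the record edges
        assert len(b) == cfg.n_cycles - 1
        expect = truth.t_start_s.values[1:]
        assert np.all(np.abs(b - expect) <= DT)

    def test_constant_series_no_maxima(self):
        assert detect_cycle_boundaries(series_from(np.full(50, 0.2))).size == 0

    def test_subsample_refinement_on_sine(self):
        s = sine_series(period=41.0, n=400)  # maxima off the sample grid
        b = detect_cycle_boundaries(smooth_velocity(s))
        # analytic maxima at t = 41(k + 1/4)
        analytic = 41.0 * (np.round(b / 41.0 - 0.25) + 0.25)
        assert np.all(np.abs(b - analytic) < DT / 4)

    def test_secondary_peak_filtered_when_prominent_enough(self):
        # doubly-periodic waveform: large |b| puts two humps per wavelength
        cfg = GeneratorConfig(a=0.4, b=-0.45, seed=2, noise_sd=0.0,
                              lambda_cv=0.0, vhat_cv=0.0, n_cycles=5)
        profile, series = generate_cell(cfg)
        sm = smooth_velocity(series)
        # a permissive prominence sees both humps ...
        assert len(detect_cycle_boundaries(sm, prominence_frac=0.05)) \
            == 2 * cfg.n_cycles - 1
        # ... the default-ish 0.3 keeps only the dominant maximum
        assert len(detect_cycle_boundaries(sm, prominence_frac=0.3)) \
            == cfg.n_cycles - 1


class TestSegmentation:
    def test_recovery_against_generator(self):
        lam_err = []
        for seed in range(5):
            cfg = GeneratorConfig(seed=seed, noise_sd=0.0, lambda_cv=0.05,
                                  vhat_cv=0.05)
            profile, series = generate_cell(cfg)
            truth = true_cycles(profile).iloc[1:-1]
            cycles = segment_cycles(
                series, detect_cycle_boundaries(smooth_velocity(series)))
            assert len(cycles) == len(truth)
            for c, (_, row) in zip(cycles, truth.iterrows()):
                assert abs(c.tau - row.tau_s) <= DT
                lam_err.append(abs(c.lam - row.lambda_um) / row.lambda_um)
        assert np.median(lam_err) < 0.02

    def test_constant_cycle_arithmetic(self):
        s = series_from(np.full(200, 0.16))
        cycles = segment_cycles(s, [0.0, 39.375])
        assert cycles[0].lam == pytest.approx(6.3, rel=1e-9)
        assert cycles[0].vbar == pytest.approx(0.16)

    def test_wavelengths_sum_to_total_displacement(self):
        from tubekin.kinematics import integrate_displacement
        cfg = GeneratorConfig(seed=6, noise_sd=0.004)
        _, series = generate_cell(cfg)
        b = detect_cycle_boundaries(smooth_velocity(series))
        cycles = segment_cycles(series, b)
        total = integrate_displacement(series, b[0], b[-1])
        assert sum(c.lam for c in cycles) == pytest.approx(total, rel=1e-9)

    def test_segmentation_idempotent(self):
        cfg = GeneratorConfig(seed=8, noise_sd=0.0)
        _, series = generate_cell(cfg)
        b = detect_cycle_boundaries(smooth_velocity(series))
        cycles = segment_cycles(series, b)
        again = segment_cycles(series, [c.t_start for c in cycles] +
                               [cycles[-1].t_end])
        assert len(again) == len(cycles)
        for c1, c2 in zip(cycles, again):
            assert c1.tau == pytest.approx(c2.tau)
            assert c1.lam == pytest.approx(c2.lam)

    def test_non_monotone_boundaries_rejected(self):
        s = series_from(np.full(50, 0.2))
        with pytest.raises(ValueError):
            segment_cycles(s, [0.0, 20.0, 10.0])


class TestWindowSelection:
    def test_fully_oscillatory_record_kept_whole(self):
        _, series = generate_cell(GeneratorConfig(seed=2, noise_sd=0.004))
        windows, excluded = select_oscillatory_windows(series)
        assert len(windows) == 1
        assert excluded == pytest.approx(0.0, abs=0.02)

    def test_constant_record_empty(self):
        windows, excluded = select_oscillatory_windows(
            series_from(np.full(120, 0.16)))
        assert windows == []
        assert excluded == 1.0

    def test_flat_splice_yields_two_windows(self):
        cfg = GeneratorConfig(seed=2, noise_sd=0.0, lambda_cv=0.0,
                              vhat_cv=0.0, n_cycles=5)
        _, osc = generate_cell(cfg)
        n_flat = int(round(0.4 / 0.6 * 2 * len(osc)))
        flat = np.full(n_flat, float(osc.v.mean()))
        spliced = series_from(np.concatenate([osc.v, flat, osc.v]))
        windows, excluded = select_oscillatory_windows(spliced)
        assert len(windows) == 2
        assert excluded == pytest.approx(0.4, abs=0.1)


class TestCellSummary:
    def make_cycles(self, lams, taus):
        t = 0.0
        cycles = []
        for i, (lam, tau) in enumerate(zip(lams, taus)):
            cycles.append(Cycle.make(t, t + tau, lam, i))
            t += tau
        return cycles

    def test_identical_cycles_zero_cv(self):
        cycles = self.make_cycles([6.3] * 5, [39.375] * 5)
        rec = summarize_cell("c", cycles)
        assert rec.cv_lambda == 0 and rec.cv_tau == 0
        assert rec.v_mean == pytest.approx(0.16)

    def test_cv_arithmetic_wavelength(self):
        # sample mean 6.3 μm, sample sd 1.7 μm → CV 27%
        x = 1.7 / np.sqrt(2)
        cycles = self.make_cycles([6.3 - x, 6.3 + x], [40.0, 40.0])
        rec = summarize_cell("c", cycles)
        assert round(rec.cv_lambda) == 27

    def test_cv_arithmetic_period(self):
        # sample mean 39.1 s, sample sd 17.6 s → CV 45%
        x = 17.6 / np.sqrt(2)
        cycles = self.make_cycles([6.3, 6.3], [39.1 - x, 39.1 + x])
        rec = summarize_cell("c", cycles)
        assert round(rec.cv_tau) == 45

    def test_v_mean_is_ratio_of_means(self):
        cycles = self.make_cycles([4.0, 8.0], [20.0, 60.0])
        rec = summarize_cell("c", cycles)
        assert rec.v_mean == pytest.approx(6.0 / 40.0)
        assert rec.v_mean != pytest.approx(np.mean([4 / 20, 8 / 60]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_cell("c", [])


class TestPopulationStats:
    def _population_records(self, n_cells=40, seed=3):
        from tubekin.pipeline import analyze_cell
        cells = generate_population(PopulationConfig(n_cells=n_cells, seed=seed))
        recs = []
        for _, _, series in cells:
            a = analyze_cell(series)
            if a.record is not None:
                recs.append(a.record)
        return recs

    def test_zero_variance_correlations_flagged(self):
        cycles = [Cycle.make(40.0 * i, 40.0 * (i + 1), 6.3, i) for i in range(5)]
        recs = [summarize_cell(f"c{i}", cycles) for i in range(4)]
        stats = population_statistics(recs)
        assert np.isnan(stats.correlations["R_lambda_tau"])

    def test_correlation_structure_and_surface(self):
        recs = self._population_records(n_cells=60, seed=5)
        stats = population_statistics(recs)
        assert stats.correlations["R_lambda_tau"] > 0.5
        assert stats.correlations["R_v_tau"] < -0.4
        tri = stats.triplets
        assert np.allclose(tri.v_mean * tri.tau_mean, tri.lambda_mean)

    def test_too_few_cells_rejected(self):
        recs = self._population_records(n_cells=10, seed=1)[:2]
        with pytest.raises(ValueError):
            population_statistics(recs)

    def test_within_cell_period_cv_exceeds_wavelength_cv(self):
        recs = self._population_records(n_cells=40, seed=2)
        tri = population_statistics(recs).triplets
        assert tri.cv_tau.median() > tri.cv_lambda.median()


class TestErgodicity:
    def _long_cell(self, seed=2, n_cycles=40, lam=6.3):
        # per-cycle dispersion matching the population dispersion of means,
        # and the spatial-mean velocity matching the population draw scale
        from tubekin.model import harmonic_velocity_factor
        from tubekin.pipeline import analyze_cell
        h = harmonic_velocity_factor(0.5, -0.3)
        cfg = GeneratorConfig(seed=seed, n_cycles=n_cycles, lambda_mean=lam,
                              lambda_cv=0.27, vhat_cv=0.24,
                              vhat_mean=0.16 / h)
        _, series = generate_cell(cfg)
        return analyze_cell(series).record

    def _population(self, seed=4):
        from tubekin.pipeline import analyze_cell
        cells = generate_population(PopulationConfig(n_cells=40, seed=seed))
        recs = [analyze_cell(s).record for _, _, s in cells]
        return population_statistics([r for r in recs if r is not None])

    def test_matched_cell_is_ergodic_consistent(self):
        report = ergodicity_comparison(self._long_cell(), self._population())
        assert report["ergodic_consistent"]
        for key in ("lambda", "tau", "v"):
            assert report[key]["range_overlap"] >= 0.8

    def test_shifted_cell_flagged(self):
        pop = self._population()
        shift = 3 * pop.triplets.lambda_mean.std()
        long_cell = self._long_cell(lam=6.3 + 3 * shift)
        report = ergodicity_comparison(long_cell, pop)
        assert not report["ergodic_consistent"]

    def test_self_comparison_ks_zero(self):
        long_cell = self._long_cell()
        pop = self._population()
        # degenerate: population means replaced by the cell's own values
        pop.triplets = pop.triplets.iloc[:long_cell.n_cycles].copy()
        pop.triplets["lambda_mean"] = [c.lam for c in long_cell.cycles]
        pop.triplets["tau_mean"] = [c.tau for c in long_cell.cycles]
        pop.triplets["v_mean"] = [c.vbar for c in long_cell.cycles]
        report = ergodicity_comparison(long_cell, pop)
        for key in ("lambda", "tau", "v"):
            assert report[key]["ks_statistic"] == 0.0

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValueError):
            ergodicity_comparison(self._long_cell(n_cycles=8), self._population())
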