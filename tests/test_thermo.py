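"""Arrhenius transforms, segmented fits, model selection and mcrA normalization."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from methanotherm import thermo
from methanotherm.kinetics import RateEstimate
from methanotherm.thermo import (
    BOLTZMANN_EV_PER_K,
    ArrheniusPoint,
    FTestUndefinedError,
    QpcrTable,
    ThermoError,
    arrhenius_transform,
    fit_segmented,
    fit_single,
    normalize_rates,
    select_model,
)


def points_from_law(temps, E, M, boltzmann=BOLTZMANN_EV_PER_K, noise=None, rng=None):
    pts = []
    for T in temps:
        x = -1.0 / (boltzmann * (T + 273.15))
        y = E * x + M
        if noise:
            y += rng.normal(0, noise)
        pts.append(arrhenius_transform(T, math.exp(y), boltzmann))
    return pts


class TestTransform:
    def test_reference_point(self):
        p = arrhenius_transform(25.0, 1.0)
        assert p.x == pytest.approx(-1.0 / (8.623e-5 * 298.15), rel=1e-12)
        assert p.x == pytest.approx(-38.8958, abs=1e-3)
        assert p.y == 0.0

    def test_ln_identity(self):
        assert arrhenius_transform(10.0, math.e).y == pytest.approx(1.0)

    def test_default_boltzmann_constant(self):
        assert BOLTZMANN_EV_PER_K == 8.623e-5

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ThermoError):
            arrhenius_transform(25.0, 0.0)

    def test_nonpositive_rates_excluded_with_warning(self, caplog):
        rates = [
            RateEstimate(10.0, "ch4", 0.0, (0, 1), 1.0),
            RateEstimate(20.0, "ch4", 1.0, (0, 1), 1.0),
        ]
        with caplog.at_level("WARNING"):
            pts = thermo.transform_rates(rates)
        assert len(pts) == 1
        assert "excluding" in caplog.text


class TestSingleFit:
    def test_exact_interpolation(self):
        fit = fit_single(points_from_law([15, 25, 35], E=1.0, M=0.0))
        assert fit.E == pytest.approx(1.0, abs=1e-9)
        assert fit.M == pytest.approx(0.0, abs=1e-7)
        assert fit.rss == pytest.approx(0.0, abs=1e-9)

    def test_rate_rescaling_shifts_only_intercept(self):
        pts = points_from_law([10, 20, 30], E=0.7, M=2.0)
        c = 37.5
        scaled = [arrhenius_transform(p.temperature_K - 273.15, p.rate * c) for p in pts]
        f0, f1 = fit_single(pts), fit_single(scaled)
        assert f1.E == pytest.approx(f0.E, rel=1e-12)
        assert f1.M == pytest.approx(f0.M + math.log(c), rel=1e-9)

    def test_flat_law(self):
        fit = fit_single(points_from_law([10, 20, 30], E=0.0, M=1.5))
        assert fit.E == pytest.approx(0.0, abs=1e-12)
        assert fit.M == pytest.approx(1.5)

    def test_two_points_have_no_se(self):
        fit = fit_single(points_from_law([10, 30], E=1.0, M=0.0))
        assert fit.se_E is None and fit.n == 2

    def test_duplicate_temperature_only_rejected(self):
        pts = points_from_law([20, 20], E=1.0, M=0.0)
        with pytest.raises(ThermoError):
            fit_single(pts)

    def test_boltzmann_constant_choice_negligible(self):
        """Swapping 8.623e-5 for CODATA 8.617e-5 moves E by < 0.1%."""
        temps = [10, 15, 20, 25, 30, 35]
        rng = np.random.default_rng(0)
        rates = [math.exp(1.1 * -1 / (8.623e-5 * (T + 273.15)) + 40) for T in temps]
        e1 = fit_single([arrhenius_transform(T, r, 8.623e-5) for T, r in zip(temps, rates)]).E
        e2 = fit_single([arrhenius_transform(T, r, 8.617e-5) for T, r in zip(temps, rates)]).E
        assert abs(e2 - e1) / e1 < 1e-3


def brute_force_segmented(points, min_points=2):
    """Oracle: pooled RSS of every admissible temperature cut."""
    pts = sorted(points, key=lambda p: p.temperature_K)
    temps = sorted({p.temperature_K for p in pts})
    results = {}
    for cut in temps[:-1]:
        low = [p for p in pts if p.temperature_K <= cut]
        high = [p for p in pts if p.temperature_K > cut]
        if len(low) < min_points or len(high) < min_points:
            continue
        if len({p.x for p in low}) < 2 or len({p.x for p in high}) < 2:
            continue
        results[cut - 273.15] = fit_single(low).rss + fit_single(high).rss
    return results


class TestSegmentedFit:
    def test_exact_two_regime_recovery(self):
        low = points_from_law([10, 15], E=3.9, M=0.0)
        # continuity not required: use a different intercept above the break
        high = points_from_law([20, 25, 30, 35], E=1.1, M=5.0)
        fit = fit_segmented(low + high)
        assert fit.break_after_temperature_C == pytest.approx(15.0)
        assert fit.low.E == pytest.approx(3.9, abs=1e-7)
        assert fit.high.E == pytest.approx(1.1, abs=1e-7)
        assert fit.pooled_rss == pytest.approx(0.0, abs=1e-9)

    def test_single_regime_tie_breaks_to_balanced_cut(self):
        pts = points_from_law([10, 15, 20, 25, 30, 35], E=0.6, M=1.0)
        fit = fit_segmented(pts)
        # every cut has pooled RSS ~ 0; most balanced split is 3|3 (cut after 20)
        assert fit.pooled_rss == pytest.approx(0.0, abs=1e-9)
        assert fit.break_after_temperature_C == pytest.approx(20.0)

    def test_too_few_points(self):
        with pytest.raises(ThermoError):
            fit_segmented(points_from_law([10, 20, 30], E=1.0, M=0.0))

    @settings(deadline=None, max_examples=40)
    @given(
        n=st.integers(4, 12),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_pooled_rss_minimal_over_all_cuts(self, n, seed):
        rng = np.random.default_rng(seed)
        temps = np.sort(rng.choice(np.arange(5, 40), size=n, replace=False)).astype(float)
        pts = points_from_law(temps, E=1.5, M=3.0, noise=0.3, rng=rng)
        oracle = brute_force_segmented(pts)
        if not oracle:
            return
        fit = fit_segmented(pts)
        assert fit.pooled_rss <= min(oracle.values()) + 1e-9
        assert fit.pooled_rss == pytest.approx(oracle[fit.break_after_temperature_C], rel=1e-9)

    def test_stochastic_break_recovery(self, default_config):
        """Two-regime truth at 5% lognormal rate noise: correct break >= 90%."""
        rng = np.random.default_rng(123)
        cfg = default_config
        hits = 0
        reps = 200
        for _ in range(reps):
            pts = []
            for T in cfg.temperatures_C:
                rate = cfg.ch4_rate(T) * math.exp(rng.normal(0, 0.05))
                pts.append(arrhenius_transform(T, rate))
            fit = fit_segmented(pts)
            hits += fit.break_after_temperature_C == pytest.approx(15.0)
        assert hits / reps >= 0.90


class TestModelSelection:
    def test_equal_rss_chooses_single(self):
        pts = points_from_law([10, 15, 20, 25, 30, 35], E=0.6, M=1.0, noise=0.1,
                              rng=np.random.default_rng(1))
        single = fit_single(pts)
        seg = fit_segmented(pts)
        seg.pooled_rss = single.rss  # forced tie
        assert select_model(single, seg) == "single"

    def test_zero_both_chooses_single(self):
        pts = points_from_law([10, 15, 20, 25, 30, 35], E=0.6, M=1.0)
        assert select_model(fit_single(pts), fit_segmented(pts)) == "single"

    def test_perfect_segmented_forced(self):
        low = points_from_law([10, 15], E=3.9, M=0.0)
        high = points_from_law([20, 25, 30, 35], E=1.1, M=5.0)
        pts = low + high
        assert select_model(fit_single(pts), fit_segmented(pts)) == "segmented"

    def test_undefined_below_five_points(self):
        pts = points_from_law([10, 15, 20, 25], E=1.0, M=0.0, noise=0.2,
                              rng=np.random.default_rng(2))
        with pytest.raises(FTestUndefinedError):
            select_model(fit_single(pts), fit_segmented(pts))

    def test_f_statistic_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        pts = points_from_law([10, 15, 20, 25, 30, 35], E=0.8, M=2.0, noise=0.2, rng=rng)
        single, seg = fit_single(pts), fit_segmented(pts)
        select_model(single, seg)
        n = single.n
        f_expect = ((single.rss - seg.pooled_rss) / 2) / (seg.pooled_rss / (n - 4))
        assert seg.f_stat == pytest.approx(max(f_expect, 0.0), rel=1e-9)
        assert seg.p_value == pytest.approx(float(stats.f.sf(seg.f_stat, 2, n - 4)), rel=1e-9)


class TestParameterRecovery:
    def test_bias_and_ci_coverage(self, default_config):
        """200 triplicate experiments, 5% noise: |bias| < 0.05 eV and 95% CI
        coverage of both segment energies within [0.90, 0.99]."""
        cfg = default_config
        rng = np.random.default_rng(77)
        e_low, e_high = [], []
        cov_low = cov_high = 0
        reps = 200
        for _ in range(reps):
            pts = []
            for T in cfg.temperatures_C:
                for _r in range(3):
                    rate = cfg.ch4_rate(T) * math.exp(rng.normal(0, 0.05))
                    pts.append(arrhenius_transform(T, rate))
            fit = fit_segmented(pts)
            e_low.append(fit.low.E)
            e_high.append(fit.high.E)
            lo = fit.low.ci_E()
            hi = fit.high.ci_E()
            cov_low += lo[0] <= cfg.E_low <= lo[1]
            cov_high += hi[0] <= cfg.E_high <= hi[1]
        assert abs(np.mean(e_low) - cfg.E_low) < 0.05
        assert abs(np.mean(e_high) - cfg.E_high) < 0.05
        assert 0.90 <= cov_low / reps <= 0.99
        assert 0.90 <= cov_high / reps <= 0.99


def make_qpcr(columns: dict[float, list], days=(3, 24, 49, 65, 81)) -> QpcrTable:
    means = pd.DataFrame({t: vals for t, vals in columns.items()},
                         index=pd.Index(list(days)[: len(next(iter(columns.values())))], name="day"))
    return QpcrTable(means=means, ses=means * 0)


class TestNormalization:
    def test_division_by_column_maximum(self):
        # table column with peak detected abundance 59.42 (x1e6 copies)
        qpcr = make_qpcr({35.0: [np.nan, 6.12, 7.50, 59.42, 55.37]})
        rates = [RateEstimate(35.0, "ch4", 11.884, (0, 1), 1.0)]
        normed = normalize_rates(rates, qpcr)
        assert normed[0].p_max == pytest.approx(0.2, rel=1e-3)

    def test_single_detected_value_is_divisor(self):
        qpcr = make_qpcr({20.0: [np.nan, np.nan, 4.0, np.nan, np.nan]})
        normed = normalize_rates([RateEstimate(20.0, "ch4", 2.0, (0, 1), 1.0)], qpcr)
        assert normed[0].p_max == pytest.approx(0.5)

    def test_all_nd_column_errors(self):
        qpcr = make_qpcr({10.0: [np.nan] * 5})
        with pytest.raises(ThermoError):
            normalize_rates([RateEstimate(10.0, "ch4", 1.0, (0, 1), 1.0)], qpcr)

    def test_scaling_qpcr_leaves_fitted_E_unchanged(self, default_config):
        cfg = default_config
        temps = cfg.temperatures_C
        rates = [RateEstimate(T, "ch4", cfg.ch4_rate(T), (0, 1), 1.0) for T in temps]
        base = make_qpcr({float(T): [1.0 + 0.1 * i + T / 10 for i in range(5)] for T in temps})
        scaled = make_qpcr({float(T): base.means[float(T)] * 10 for T in temps})
        n1 = normalize_rates(rates, base)
        n2 = normalize_rates(rates, scaled)
        for a, b in zip(n1, n2):
            assert b.p_max == pytest.approx(a.p_max / 10, rel=1e-12)
        f1 = fit_single(thermo.transform_rates(n1))
        f2 = fit_single(thermo.transform_rates(n2))
        assert f2.E == pytest.approx(f1.E, rel=1e-9)
        assert f2.M == pytest.approx(f1.M - math.log(10), rel=1e-6)
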