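"""Estimator tests: lag time, diffusivities, binding constant, partition
coefficient, degenerate-record handling and noise robustness."""

import numpy as np
import pytest

from gelcell import (
    ConcentrationTrace,
    EstimationError,
    NoiseModel,
    TransportParams,
    analyze_single,
    analyze_trace_pair,
    apparent_equilibrium_constant,
    closed_form_lag,
    d_from_lag,
    effective_diffusivity,
    estimate_lag_time,
    flux_series,
    lag_time_uncertainty,
    partition_coefficient,
    simulate_cell,
)

L = 5.0e-3


def piecewise_lag_trace(geometry, t0=5000.0, rate=1.0e-9, n=200, dt=120.0):
    """Exact two-stage trace: acceptor flat until t0, then Q rises linearly.

    The acceptor stays far below the (constant) donor so the driving force
    is constant and the time-lag intercept must be exactly t0.
    """
    t = np.arange(n) * dt
    c_a = np.where(t > t0, rate * (t - t0), 0.0)
    c_d = np.full(n, 25.0)
    return ConcentrationTrace(t, c_d, c_a)


class TestLagTime:
    def test_exact_on_constructed_piecewise_trace(self, geometry):
        split = estimate_lag_time(piecewise_lag_trace(geometry), geometry)
        assert split.t_L == pytest.approx(5000.0, rel=1e-6)
        # the stage ranges partition the trace at the first time > t_L
        assert split.first_stage.stop == split.second_stage.start
        assert split.second_stage.stop == 200

    def test_recovers_inert_lag(self, big_reservoir_geometry, inert_trace_big, lag_inert):
        split = estimate_lag_time(inert_trace_big, big_reservoir_geometry)
        assert split.t_L == pytest.approx(lag_inert, rel=0.05)

    def test_recovers_retarded_lag(self, big_reservoir_geometry, reactive_trace_big, lag_reactive):
        """K = 1.92 stretches the lag to (1 + K) x 8013 s ~ 390 min."""
        split = estimate_lag_time(reactive_trace_big, big_reservoir_geometry)
        assert split.t_L == pytest.approx(lag_reactive, rel=0.05)
        assert split.t_L / 60.0 == pytest.approx(390.0, rel=0.05)

    def test_threshold_method_close_to_extrapolation(self, big_reservoir_geometry, inert_trace_big):
        split = estimate_lag_time(
            inert_trace_big, big_reservoir_geometry, method="threshold", noise_floor=1e-3
        )
        assert 0.5 * 8013 < split.t_L < 1.5 * 8013

    def test_no_breakthrough_raises(self, geometry):
        t = np.arange(50.0)
        trace = ConcentrationTrace(t, np.full(50, 25.0), np.zeros(50))
        with pytest.raises(EstimationError, match="breakthrough"):
            estimate_lag_time(trace, geometry)

    def test_monte_carlo_uncertainty_is_reproducible(self, geometry, inert_trace_bench):
        noise = NoiseModel(0.01, 0.02, seed=11)
        est1, samples1 = lag_time_uncertainty(inert_trace_bench, geometry, noise, 10)
        est2, samples2 = lag_time_uncertainty(inert_trace_bench, geometry, noise, 10)
        np.testing.assert_array_equal(samples1, samples2)
        assert est1.sd > 0

    def test_median_lag_robust_to_measurement_noise(self, geometry, inert_trace_bench, lag_inert):
        """1% relative + 0.02 g/m3 noise, 25 replicates: median within 10%."""
        noise = NoiseModel(0.01, 0.02, seed=42)
        est, _ = lag_time_uncertainty(inert_trace_bench, geometry, noise, 25)
        assert abs(est.value - lag_inert) / lag_inert < 0.10


class TestDFromLag:
    @pytest.mark.parametrize(
        "t_l_min,expected",
        [(390.0, 1.78e-10), (606.0, 1.15e-10), (134.0, 5.20e-10)],
    )
    def test_reported_lag_diffusivity_pairs(self, t_l_min, expected):
        assert d_from_lag(t_l_min * 60.0, L) == pytest.approx(expected, rel=0.005)

    def test_scaling(self):
        assert d_from_lag(4 * 3600.0, L) == pytest.approx(d_from_lag(3600.0, L) / 4.0)

    def test_roundtrip_with_closed_form(self):
        for d in (1e-10, 2.5e-10, 5e-10):
            assert d_from_lag(closed_form_lag(L, d), L) == pytest.approx(d, rel=1e-12)

    def test_rejects_non_positive(self):
        from gelcell import ValidationError

        with pytest.raises(ValidationError):
            d_from_lag(0.0, L)
        with pytest.raises(ValidationError):
            d_from_lag(100.0, -L)


class TestFluxSeries:
    def test_constant_trace_all_flagged(self, geometry):
        t = np.arange(10.0) * 60
        trace = ConcentrationTrace(t, np.full(10, 12.5), np.full(10, 12.5))
        fx = flux_series(trace, geometry)
        assert not fx.valid.any()
        assert np.isnan(fx.d_e).all()
        assert np.all(fx.flux_j == 0.0)

    def test_constructed_steady_state_recovers_diffusivity(self, geometry):
        """Donor drained at exactly j = D* (c_d - c_a) / L: every record
        yields D_E = D*."""
        d_star = 3.0e-10
        dt, n = 60.0, 50
        c_d, c_a = 20.0, 5.0
        j = d_star * (c_d - c_a) / L
        drain = j * geometry.exposed_area * dt / geometry.donor_volume
        t = np.arange(n) * dt
        # keep delta_c fixed by draining donor and acceptor identically
        cd = c_d - drain * np.arange(n)
        ca = c_a - drain * np.arange(n)
        fx = flux_series(ConcentrationTrace(t, cd, ca), geometry)
        np.testing.assert_allclose(fx.d_e, d_star, rtol=1e-9)

    def test_second_stage_mean_matches_gel_diffusivity(self, geometry, inert_trace_bench):
        split = estimate_lag_time(inert_trace_bench, geometry)
        fx = flux_series(inert_trace_bench, geometry)
        d_e = effective_diffusivity(fx, split)
        assert d_e.value == pytest.approx(5.20e-10, rel=0.05)

    def test_single_valid_record(self, geometry):
        t = np.array([0.0, 60.0])
        j = 2e-10 * (20.0 - 0.0) / L
        drop = j * geometry.exposed_area * 60.0 / geometry.donor_volume
        trace = ConcentrationTrace(t, np.array([20.0, 20.0 - drop]), np.array([0.0, 0.0]))
        fx = flux_series(trace, geometry)
        from gelcell.estimate import StageSplit

        split = StageSplit(t_L=1.0, n_samples=2, split_index=1, method="manual")
        est = effective_diffusivity(fx, split)
        assert est.sd == 0.0
        assert est.value == pytest.approx(2e-10, rel=1e-6)

    def test_interface_partition_scales_effective_diffusivity(self, big_reservoir_geometry):
        """epsilon = 0.5 halves the interface concentration jump and hence
        the quasi-steady flux: D_E -> epsilon * D_gel."""
        geo = big_reservoir_geometry
        params = TransportParams(d_gel=5.2e-10, c0_donor=25.0, epsilon=0.5)
        trace = simulate_cell(geo, params, 8.0e4, 60.0)
        split = estimate_lag_time(trace, geo)
        d_e = effective_diffusivity(flux_series(trace, geo), split)
        assert d_e.value == pytest.approx(0.5 * 5.2e-10, rel=0.05)

    def test_empty_second_stage_raises(self, geometry):
        t = np.arange(10.0) * 60
        trace = ConcentrationTrace(t, np.full(10, 12.5), np.full(10, 12.5))
        fx = flux_series(trace, geometry)
        from gelcell.estimate import StageSplit

        split = StageSplit(t_L=1.0, n_samples=10, split_index=1, method="manual")
        with pytest.raises(EstimationError):
            effective_diffusivity(fx, split)


class TestApparentEquilibriumConstant:
    def test_first_stage_sulphapyridine(self):
        est = apparent_equilibrium_constant(5.20e-10, 1.78e-10, "first")
        assert est.k_hat == pytest.approx(1.92, abs=0.005)

    def test_identical_media_give_zero(self):
        assert apparent_equilibrium_constant(3e-10, 3e-10).k_hat == 0.0

    def test_second_stage_diclofenac(self):
        est = apparent_equilibrium_constant(1.86e-10, 1.46e-10, "second")
        assert est.k_hat == pytest.approx(0.274, abs=0.001)

    def test_rejects_non_positive(self):
        from gelcell import ValidationError

        with pytest.raises(ValidationError):
            apparent_equilibrium_constant(0.0, 1e-10)


class TestPartitionCoefficient:
    def test_nothing_left_donor_gives_zero(self, geometry):
        t = np.arange(5.0) * 60
        trace = ConcentrationTrace(t, np.full(5, 25.0), np.zeros(5))
        est = partition_coefficient(trace, geometry, 25.0, "final")
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_inert_gel_partition_is_unity(self, geometry, inert_trace_bench):
        """epsilon = 1, K = 0: the mass balance late in the second stage
        returns 1.00 within 0.01."""
        est = partition_coefficient(inert_trace_bench, geometry, 25.0, "final")
        assert est.value == pytest.approx(1.00, abs=0.01)

    def test_binding_inflates_apparent_partition(self, geometry):
        """K = 0.10 at epsilon = 1: bound drug is counted in the gel, so the
        estimator converges to epsilon (1 + K) = 1.10."""
        params = TransportParams(d_gel=5.2e-10, c0_donor=25.0, k_binding=0.10)
        trace = simulate_cell(geometry, params, 1.2e5, 120.0)
        est = partition_coefficient(trace, geometry, 25.0, "final")
        assert est.value == pytest.approx(1.10, abs=0.02)

    def test_window_evaluation_reports_spread(self, geometry, inert_trace_bench):
        split = estimate_lag_time(inert_trace_bench, geometry)
        est = partition_coefficient(inert_trace_bench, geometry, 25.0, "window", split=split)
        assert est.value == pytest.approx(1.00, abs=0.01)
        assert est.sd >= 0.0

    def test_mass_balance_violation_raises(self, geometry):
        from gelcell import ValidationError

        t = np.arange(5.0) * 60
        trace = ConcentrationTrace(t, np.full(5, 30.0), np.full(5, 5.0))
        with pytest.raises(ValidationError, match="mass balance"):
            partition_coefficient(trace, geometry, 25.0, "final")


class TestAnalyzePair:
    def test_identical_traces_give_zero_k(self, big_reservoir_geometry, inert_trace_big):
        df = analyze_trace_pair(inert_trace_big, inert_trace_big, big_reservoir_geometry)
        row = df[df["sample"] == "reactive"].iloc[0]
        assert row["K_first"] == pytest.approx(0.0, abs=1e-9)
        assert row["K_second"] == pytest.approx(0.0, abs=1e-9)

    def test_recovers_binding_constant(
        self, big_reservoir_geometry, inert_trace_big, reactive_trace_big
    ):
        df = analyze_trace_pair(inert_trace_big, reactive_trace_big, big_reservoir_geometry)
        row = df[df["sample"] == "reactive"].iloc[0]
        assert row["K_first"] == pytest.approx(1.92, rel=0.10)

    def test_report_layout(self, big_reservoir_geometry, inert_trace_big, reactive_trace_big):
        """Columns use bench units: lag in minutes, diffusivities in 1e-10 m2/s."""
        df = analyze_trace_pair(inert_trace_big, reactive_trace_big, big_reservoir_geometry)
        assert list(df.columns[:7]) == [
            "sample", "t_L_min", "D_L_e10", "D_E_e10", "K_first", "K_second", "epsilon",
        ]
        inert = df[df["sample"] == "inert"].iloc[0]
        assert inert["t_L_min"] == pytest.approx(134.0, rel=0.05)
        assert inert["D_L_e10"] == pytest.approx(5.20, rel=0.05)

    def test_estimators_scale_invariant(self, big_reservoir_geometry, inert_trace_big):
        """Rescaling all concentrations by a constant leaves t_L, D_L, D_E,
        and epsilon unchanged (calibration-factor invariance)."""
        geo = big_reservoir_geometry
        a = analyze_single(inert_trace_big, geo)
        b = analyze_single(inert_trace_big.scaled(3.7), geo, c0=25.0 * 3.7)
        assert b.t_l.value == pytest.approx(a.t_l.value, rel=1e-9)
        assert b.d_l.value == pytest.approx(a.d_l.value, rel=1e-9)
        assert b.d_e.value == pytest.approx(a.d_e.value, rel=1e-9)
        assert b.epsilon_hat.value == pytest.approx(a.epsilon_hat.value, rel=1e-9)
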