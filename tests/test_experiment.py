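"""Pipeline runs: determinism, reporting instants, short-protocol physics."""

import numpy as np
import pytest

import pfasim as pf


@pytest.fixture(scope="module")
def short_run(reference_mesh, materials, short_protocol):
    cfg = pf.RunConfig()
    return pf.run_simulation(reference_mesh, materials, short_protocol, "cht", cfg)


class TestRunSimulation:
    def test_zero_amplitude_stays_at_body_temperature(self, reference_mesh, materials):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # amplitude outside usual band
            proto = pf.PulseProtocol(0.0, 0.1, 2)
        res = pf.run_simulation(reference_mesh, materials, proto, "cht", pf.RunConfig())
        assert res.maxT_myo_pulse_end == pytest.approx(37.0, abs=1e-9)
        assert res.report.ire_volume_mm3 == 0.0
        assert res.report.temp_volume_mm3 == 0.0
        assert res.report.arrhenius_volume_mm3 == 0.0

    def test_repeated_run_is_bit_identical(self, reference_mesh, materials, short_protocol):
        cfg = pf.RunConfig()
        a = pf.run_simulation(reference_mesh, materials, short_protocol, "cht", cfg)
        b = pf.run_simulation(reference_mesh, materials, short_protocol, "cht", cfg)
        np.testing.assert_array_equal(a.T_final, b.T_final)
        np.testing.assert_array_equal(a.trace_max_myo, b.trace_max_myo)
        np.testing.assert_array_equal(a.E_max, b.E_max)
        np.testing.assert_array_equal(a.omega_pulse_end, b.omega_pulse_end)

    def test_reporting_instants_match_protocol_arithmetic(self, short_run, short_protocol):
        assert short_run.pulse_end_time == pytest.approx(
            short_protocol.last_pulse_end, rel=1e-9
        )
        assert short_run.interval_end_time == pytest.approx(
            short_protocol.last_interval_end, rel=1e-9
        )
        assert short_run.trace_time[0] == 0.0
        assert short_run.trace_time[-1] == pytest.approx(short_protocol.duration, rel=1e-9)

    def test_final_interval_cools_the_peak(self, short_run):
        assert short_run.maxT_myo_interval_end <= short_run.maxT_myo_pulse_end

    def test_trace_is_sawtooth_like(self, short_run):
        # temperature rises during each pulse and decays in the interval
        t = short_run.trace_time
        m = short_run.trace_max_myo
        first_pulse_end = np.argmin(np.abs(t - 100e-6))
        assert m[first_pulse_end] > m[0]
        mid_interval = np.argmin(np.abs(t - 0.05))
        assert m[mid_interval] < m[first_pulse_end]

    def test_energy_balance_diagnostic(self, short_run):
        assert short_run.diagnostics["energy_residual_rel"] < 0.01

    def test_cfd_mode_runs_and_reports_flow(self, reference_mesh, materials,
                                            short_protocol, cycle_velocity):
        res = pf.run_simulation(reference_mesh, materials, short_protocol, "cfd",
                                pf.RunConfig(), cycle_velocity=cycle_velocity)
        assert res.diagnostics["flow_max_speed"] > 0
        assert res.maxT_myo_pulse_end > 37.0

    def test_unknown_method_rejected(self, reference_mesh, materials, short_protocol):
        with pytest.raises(ValueError):
            pf.run_simulation(reference_mesh, materials, short_protocol, "fem")


class TestTimeGridRefinement:
    def test_peak_temperature_stable_under_dt_refinement(
        self, reference_mesh, materials
    ):
        # halving both step sizes changes the peak excess by well under
        # the 0.5% mesh-sensitivity style criterion
        proto = pf.PulseProtocol(1000.0, 0.1, 2)
        coarse = pf.run_simulation(reference_mesh, materials, proto, "cht",
                                   pf.RunConfig(fine_dt=10e-6, coarse_dt=10e-3))
        fine = pf.run_simulation(reference_mesh, materials, proto, "cht",
                                 pf.RunConfig(fine_dt=5e-6, coarse_dt=5e-3))
        rel = abs(fine.maxT_myo_pulse_end - coarse.maxT_myo_pulse_end) \
            / coarse.maxT_myo_pulse_end
        assert rel < 0.005


class TestSweep:
    def test_linear_differences_give_unit_correlation(self):
        from pfasim.experiment import _pearson

        assert _pearson([1.0, 2.0, 3.0], [0.5, 1.0, 1.5]) == pytest.approx(1.0)
        assert _pearson([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == pytest.approx(-1.0)

    def test_significance_thresholds(self, reference_mesh, materials):
        # 0.8 degC / 1.5 mm^3 straddle the published significance bands
        from pfasim.experiment import SIGNIFICANT_DT_C, SIGNIFICANT_DVOL_MM3

        assert not abs(0.8) > SIGNIFICANT_DT_C
        assert abs(1.5) > SIGNIFICANT_DVOL_MM3

    def test_sweep_requires_three_values(self, reference_mesh, materials):
        with pytest.raises(ValueError):
            pf.sweep_and_correlate("amplitude", [1000.0, 2000.0],
                                   pf.PulseProtocol(1000.0, 0.1, 2),
                                   reference_mesh, materials)

    def test_unknown_parameter_rejected(self, reference_mesh, materials):
        with pytest.raises(ValueError):
            pf.sweep_and_correlate("width", [1, 2, 3],
                                   pf.PulseProtocol(1000.0, 0.1, 2),
                                   reference_mesh, materials)


class TestMeshSensitivity:
    def test_identical_levels_pass_trivially(self, materials):
        proto = pf.PulseProtocol(1000.0, 0.1, 1)
        out = pf.mesh_sensitivity_check([1.5, 1.5], proto, "cht",
                                        materials=materials)
        assert out["passed"]
        assert out["levels"][1]["rel_change"] == pytest.approx(0.0, abs=1e-12)

    def test_refinement_table_structure(self, materials):
        # cell counts grow, every level after the first reports its
        # relative change, and the pass flag reflects the criterion
        proto = pf.PulseProtocol(1000.0, 0.1, 1)
        out = pf.mesh_sensitivity_check([2.0, 1.4, 1.0], proto, "cht",
                                        materials=materials)
        counts = [row["n_cells"] for row in out["levels"]]
        assert counts[0] < counts[1] < counts[2]
        changes = [row["rel_change"] for row in out["levels"][1:]]
        assert all(c >= 0 for c in changes)
        assert out["passed"] == (changes[-1] < out["criterion"])
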