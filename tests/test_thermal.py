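"""Bioheat stepping, convective coefficients, enthalpy phase change."""

import numpy as np
import pytest

import pfasim as pf
from pfasim.domain import Boundary, Region, uniform_block
from pfasim.thermal import AMBIENT_C, ThermalState, ThermalSystem


class TestConvectiveCoefficients:
    def test_tissue_interface_coefficient(self):
        # 984 W/m^2/K at the 15.22 cm/s cycle-mean speed
        assert round(pf.compute_h_m(0.1522, 0.24, 1417.0)) == 984

    def test_identity_at_reference_speed(self):
        assert pf.compute_h_m(0.24) == pytest.approx(1417.0, rel=1e-12)

    def test_power_law_scaling(self):
        assert pf.compute_h_m(0.12) == pytest.approx(
            pf.compute_h_m(0.24) * 2**-0.8, rel=1e-12
        )

    def test_catheter_interface_coefficient(self):
        h, prov = pf.compute_h_c(0.1522, 7e-3 / 3, 1000.0, 4180.0, 0.541, 2.1e-3)
        assert h == pytest.approx(4372.0, rel=0.005)
        assert prov["Re"] == pytest.approx(169.1, rel=0.005)

    def test_catheter_coefficient_diameter_scaling(self):
        h1, _ = pf.compute_h_c(0.1522, 2e-3)
        h2, _ = pf.compute_h_c(0.1522, 4e-3)
        assert h2 / h1 == pytest.approx(2 ** (0.466 - 1.0), rel=1e-9)

    def test_default_and_alternate_presets(self):
        c = pf.default_coefficients()
        assert round(c.h_m) == 984
        assert c.h_c == pytest.approx(4372.0, rel=0.005)
        alt = pf.ref5_coefficients()
        assert (alt.h_m, alt.h_c) == (610.0, 3346.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pf.compute_h_m(-0.1)
        with pytest.raises(ValueError):
            pf.compute_h_c(0.15, d=-1e-3)


@pytest.fixture(scope="module")
def mat():
    return pf.default_materials()


class TestStepThermal:
    def test_equilibrium_is_preserved(self, mat):
        mesh = uniform_block(4, 4, 4e-3, 4e-3, Region.MYOCARDIUM)
        state = ThermalState.initial(mesh)
        out = pf.step_thermal(mesh, mat, state, 0.01, 0.0, mode="cht",
                              coeffs=pf.default_coefficients())
        assert np.max(np.abs(out.T - AMBIENT_C)) < 1e-12

    def test_insulated_uniform_heating_rate(self, mat):
        mesh = uniform_block(3, 3, 3e-3, 3e-3, Region.MYOCARDIUM)
        system = ThermalSystem(mesh, mat, mode="cfd")  # no interfaces: insulated
        state = ThermalState.initial(mesh)
        q = 5e6
        state = system.step(state, 1e-3, q)
        rate = (state.T[0] - AMBIENT_C) / 1e-3
        assert rate == pytest.approx(q / mat.myocardium.volumetric_heat_capacity, rel=1e-9)

    def test_lumped_robin_cooling_matches_exponential(self, mat):
        # small uniform block, Robin everywhere, Biot << 1
        mesh = uniform_block(3, 3, 3e-3, 3e-3, Region.BLOOD)
        h = 500.0
        system = ThermalSystem(
            mesh, mat, mode="cfd",
            robin_exterior={b: (h, AMBIENT_C) for b in
                            (Boundary.EPICARDIUM, Boundary.WALL,
                             Boundary.INLET, Boundary.OUTLET)},
        )
        state = ThermalState.from_field(mesh, np.full(9, 80.0), 0.0)
        rhoc = mat.blood.volumetric_heat_capacity
        tau = rhoc * 9e-6 / (h * 4 * 3e-3)  # rho c V / (h A), per unit depth
        t_end, n = 2.0, 400
        for _ in range(n):
            state = system.step(state, t_end / n)
        predicted = AMBIENT_C + 43.0 * np.exp(-t_end / tau)
        assert state.T.mean() == pytest.approx(predicted, abs=0.02 * 43.0)

    def test_cht_mode_requires_coefficients(self, mat):
        mesh = uniform_block(3, 3, 3e-3, 3e-3, Region.MYOCARDIUM)
        with pytest.raises(ValueError):
            ThermalSystem(mesh, mat, mode="cht")

    def test_larger_h_cools_harder(self, reference_mesh, mat, reference_potential):
        peaks = []
        for scale in (1.0, 3.0):
            c = pf.default_coefficients()
            coeffs = pf.ConvectiveCoefficients(c.h_m * scale, c.h_c * scale)
            system = ThermalSystem(reference_mesh, mat, mode="cht", coeffs=coeffs)
            state = ThermalState.initial(reference_mesh)
            for _ in range(10):
                state = system.step(state, 10e-6, reference_potential.Q)
            for _ in range(20):
                state = system.step(state, 5e-3, 0.0)
            peaks.append(state.max_T_myocardium)
        assert peaks[1] <= peaks[0]

    def test_minimum_stays_at_ambient(self, reference_mesh, mat, reference_potential):
        system = ThermalSystem(reference_mesh, mat, mode="cht",
                               coeffs=pf.default_coefficients())
        state = ThermalState.initial(reference_mesh)
        for _ in range(10):
            state = system.step(state, 10e-6, reference_potential.Q)
        for _ in range(10):
            state = system.step(state, 5e-3, 0.0)
        assert state.T.min() >= AMBIENT_C - 1e-6

    def test_energy_balance_closes(self, reference_mesh, mat, reference_potential):
        system = ThermalSystem(reference_mesh, mat, mode="cht",
                               coeffs=pf.default_coefficients())
        state = ThermalState.initial(reference_mesh)
        e0 = system.stored_energy(state)
        for _ in range(10):
            state = system.step(state, 10e-6, reference_potential.Q)
        for _ in range(50):
            state = system.step(state, 5e-3, 0.0)
        e1 = system.stored_energy(state)
        residual = abs((e1 - e0) - (system.energy_source - system.energy_boundary))
        assert residual < 0.01 * max(abs(system.energy_source), abs(e1 - e0))


class TestPhaseChange:
    def test_plateau_duration_matches_latent_heat(self):
        res = pf.phase_change_plateau_check(power=1.0, volume=1e-9)
        assert res["simulated_s"] == pytest.approx(res["predicted_s"], rel=0.02)
        # closed form: Hfg * C * V * 1K / P
        assert res["predicted_s"] == pytest.approx(2.162e9 * 0.75 * 1e-9, rel=1e-12)

    def test_plateau_time_halves_with_doubled_power(self):
        a = pf.phase_change_plateau_check(power=1.0, volume=1e-9)
        b = pf.phase_change_plateau_check(power=2.0, volume=1e-9)
        assert b["simulated_s"] == pytest.approx(a["simulated_s"] / 2, rel=0.02)

    def test_tiny_water_content_removes_plateau(self):
        mat = pf.default_materials().with_overrides(water_content=1e-6)
        res = pf.phase_change_plateau_check(power=1.0, volume=1e-9, materials=mat,
                                            dt=1e-4)
        assert res["simulated_s"] < 0.01 * 2.162e9 * 0.75 * 1e-9
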