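"""Arrhenius damage integral, probability mapping, threshold volumes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pfasim as pf
from pfasim.damage import DamageAccumulator, KELVIN_OFFSET
from pfasim.synthetic import make_field_snapshot, make_temperature_trace


class TestArrhenius:
    def test_constant_temperature_closed_form(self):
        times, temps = make_temperature_trace("constant", temp_c=50.0,
                                              duration_s=312.0, dt=0.1)
        acc = DamageAccumulator.zeros(1)
        for t in temps:
            acc.accumulate(np.array([t]), 0.1)
        t_k = 50.0 + KELVIN_OFFSET
        expected = acc.A * 312.0 * np.exp(-acc.delta_e / (acc.r_gas * t_k))
        assert acc.omega[0] == pytest.approx(expected, rel=0.005)

    def test_two_segment_additivity(self):
        times, temps = make_temperature_trace(
            "two_step", temp1_c=60.0, duration1_s=10.0,
            temp2_c=80.0, duration2_s=5.0, dt=0.05,
        )
        acc = DamageAccumulator.zeros(1)
        for t in temps:
            acc.accumulate(np.array([t]), 0.05)

        def closed(temp, dur):
            return acc.A * dur * np.exp(-acc.delta_e / (acc.r_gas * (temp + KELVIN_OFFSET)))

        assert acc.omega[0] == pytest.approx(closed(60.0, 10.0) + closed(80.0, 5.0),
                                             rel=1e-9)

    def test_refinement_convergence_on_decaying_trace(self):
        # omega from a smooth trace changes by < 0.5% under dt halving
        def run(dt):
            t = np.arange(dt, 10.0 + dt / 2, dt)
            temps = 37.0 + 43.0 * np.exp(-t / 3.0)
            acc = DamageAccumulator.zeros(1)
            for temp in temps:
                acc.accumulate(np.array([temp]), dt)
            return acc.omega[0]

        coarse, fine = run(0.005), run(0.0025)
        assert abs(fine - coarse) / fine < 0.005

    def test_omega_monotone_nondecreasing(self):
        times, temps = make_temperature_trace("pulse_train", count=4, dt=0.05)
        acc = DamageAccumulator.zeros(1)
        history = []
        for t in temps:
            acc.accumulate(np.array([t]), 0.05)
            history.append(acc.omega[0])
        assert np.all(np.diff(history) >= 0)

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            DamageAccumulator.zeros(1).accumulate(np.array([50.0]), -1.0)


class TestDamageProbability:
    def test_omega_one_is_63_percent(self):
        assert pf.damage_probability(1.0) == pytest.approx(63.212, abs=0.001)
        assert pf.damage_probability(1.0) >= 63.0

    def test_limits(self):
        assert pf.damage_probability(0.0) == 0.0
        assert pf.damage_probability(1e6) == pytest.approx(100.0)

    @given(st.floats(min_value=0, max_value=50), st.floats(min_value=0, max_value=50))
    def test_monotone(self, a, b):
        lo, hi = sorted([a, b])
        assert pf.damage_probability(lo) <= pf.damage_probability(hi) + 1e-12

    def test_negative_omega_rejected(self):
        with pytest.raises(ValueError):
            pf.damage_probability(-0.1)


class TestThresholdVolume:
    def test_uniform_field_above_threshold(self, reference_mesh):
        field = make_field_snapshot(reference_mesh, "uniform", value=2e5)
        vol = pf.threshold_volume(reference_mesh, field, 1e5)
        myo_vol = reference_mesh.region_measure(pf.Region.MYOCARDIUM) \
            * reference_mesh.extrusion_depth * 1e9
        assert vol == pytest.approx(myo_vol, rel=1e-9)

    def test_uniform_field_below_threshold(self, reference_mesh):
        field = make_field_snapshot(reference_mesh, "uniform", value=5e4)
        assert pf.threshold_volume(reference_mesh, field, 1e5) == 0.0

    def test_linear_ramp_half_exceedance(self):
        mesh = pf.uniform_block(64, 4, 64e-3, 4e-3, pf.Region.MYOCARDIUM)
        field = make_field_snapshot(mesh, "linear_ramp", lo=0.0, hi=2e5)
        vol = pf.threshold_volume(mesh, field, 1e5)
        total = mesh.cell_measures.sum() * mesh.extrusion_depth * 1e9
        one_layer = total / 64
        assert abs(vol - total / 2) <= one_layer

    def test_monotone_nonincreasing_in_threshold(self, reference_mesh):
        field = make_field_snapshot(reference_mesh, "dipole_like")
        thresholds = np.linspace(field.min(), field.max(), 20)
        vols = [pf.threshold_volume(reference_mesh, field, t, restrict_to=None)
                for t in thresholds]
        assert np.all(np.diff(vols) <= 1e-12)

    def test_dipole_exceedance_near_poles(self, reference_mesh):
        field = make_field_snapshot(reference_mesh, "dipole_like", strength=1e5)
        hot = field > np.percentile(field, 99)
        centers = reference_mesh.cell_centers[hot]
        cx = 0.5 * (reference_mesh.x_edges[0] + reference_mesh.x_edges[-1])
        assert np.all(np.abs(centers[:, 0] - cx) < 8e-3)


class TestContainment:
    def test_empty_inner_is_contained(self, reference_mesh):
        n = reference_mesh.n_cells
        inner = np.zeros(n, dtype=bool)
        outer = np.zeros(n, dtype=bool)
        ok, vol = pf.containment_check(reference_mesh, inner, outer)
        assert ok and vol == 0.0

    def test_equal_sets_are_contained(self, reference_mesh):
        mask = reference_mesh.region == int(pf.Region.MYOCARDIUM)
        ok, vol = pf.containment_check(reference_mesh, mask, mask)
        assert ok and vol == 0.0

    def test_single_escaping_cell_reports_its_volume(self, reference_mesh):
        myo_cells = np.flatnonzero(reference_mesh.region == int(pf.Region.MYOCARDIUM))
        n = reference_mesh.n_cells
        inner = np.zeros(n, dtype=bool)
        inner[myo_cells[0]] = True
        outer = np.zeros(n, dtype=bool)
        ok, vol = pf.containment_check(reference_mesh, inner, outer)
        assert not ok
        assert vol == pytest.approx(
            reference_mesh.cell_volumes()[myo_cells[0]] * 1e9, rel=1e-12
        )
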