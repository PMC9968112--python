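"""Geometry construction, labels, waveform synthesis and mesh I/O."""

import numpy as np
import pytest

import pfasim as pf
from pfasim.domain import FRENCH
from pfasim.vtkio import MeshFormatError, read_mesh, write_mesh


class TestMakeDomain:
    def test_all_regions_present(self, reference_mesh):
        present = set(np.unique(reference_mesh.region))
        assert present == {int(r) for r in pf.Region}

    def test_all_boundary_labels_present(self, reference_mesh):
        present = set(np.unique(reference_mesh.facet_label))
        assert present == {int(b) for b in pf.Boundary}

    def test_myocardium_area_matches_constructive_geometry(self, reference_mesh):
        p = pf.GeometryParams()
        analytic = p.domain_length * p.wall_thickness - p.catheter_length * p.insertion_depth
        area = reference_mesh.region_measure(pf.Region.MYOCARDIUM)
        assert area == pytest.approx(analytic, rel=1e-9)

    def test_electrode_areas(self, reference_mesh):
        p = pf.GeometryParams()
        expected = p.electrode_length * p.catheter_diameter
        for r in (pf.Region.ELECTRODE_LEFT, pf.Region.ELECTRODE_RIGHT):
            assert reference_mesh.region_measure(r) == pytest.approx(expected, rel=1e-9)

    def test_region_measures_tile_domain(self, reference_mesh):
        p = pf.GeometryParams()
        lx, ly = p.domain_extent
        total = sum(reference_mesh.region_measure(r) for r in pf.Region)
        assert total == pytest.approx(lx * ly, rel=1e-10)

    def test_electrode_facets_cover_exposed_perimeter(self, reference_mesh):
        # the tip electrode exposes its top (blood), bottom (tissue) and
        # bare end face; the ground electrode sits between the insulated
        # gap and shaft and exposes only top and bottom
        p = pf.GeometryParams()
        lengths = reference_mesh.facet_measures()
        active = lengths[reference_mesh.facets_of(pf.Boundary.ELECTRODE_ACTIVE)].sum()
        assert active == pytest.approx(2 * p.electrode_length + p.catheter_diameter,
                                       rel=1e-9)
        ground = lengths[reference_mesh.facets_of(pf.Boundary.ELECTRODE_GROUND)].sum()
        assert ground == pytest.approx(2 * p.electrode_length, rel=1e-9)

    def test_symmetric_catheter_variant(self):
        p = pf.GeometryParams(tip_electrode=False)
        mesh = pf.make_domain(p)
        lengths = mesh.facet_measures()
        for label in (pf.Boundary.ELECTRODE_ACTIVE, pf.Boundary.ELECTRODE_GROUND):
            s = lengths[mesh.facets_of(label)].sum()
            assert s == pytest.approx(2 * p.electrode_length, rel=1e-9)

    def test_cell_sizes_near_catheter_within_band(self, reference_mesh):
        p = pf.GeometryParams()
        hmin, hmax = p.target_cell_size
        x0 = (p.domain_length - p.catheter_length) / 2
        near = (reference_mesh.x_edges[:-1] >= x0) & (reference_mesh.x_edges[1:] <= x0 + p.catheter_length)
        assert np.all(reference_mesh.dx[near] <= hmax + 1e-12)
        assert np.all(reference_mesh.dx[near] >= hmin - 1e-12)

    def test_zero_insertion_keeps_tissue_plane_clean(self):
        mesh = pf.make_domain(pf.GeometryParams(insertion_depth=0.0))
        p = pf.GeometryParams(insertion_depth=0.0)
        myo_cells = mesh.cell_centers[mesh.region == pf.Region.MYOCARDIUM]
        assert np.all(myo_cells[:, 1] < p.wall_thickness)

    def test_refinement_increases_cell_count(self):
        base = pf.make_domain(pf.GeometryParams())
        fine = pf.make_domain(pf.GeometryParams(target_cell_size=(0.2e-3, 0.5e-3)))
        assert fine.n_cells > base.n_cells

    def test_blood_myo_interface_separates_the_right_regions(self, reference_mesh):
        idx = reference_mesh.facets_of(pf.Boundary.BLOOD_MYO_INTERFACE)
        pairs = reference_mesh.facet_cells[idx]
        regions = np.sort(reference_mesh.region[pairs], axis=1)
        assert np.all(regions[:, 0] == int(pf.Region.MYOCARDIUM))
        assert np.all(regions[:, 1] == int(pf.Region.BLOOD))

    def test_degenerate_channel_rejected(self):
        with pytest.raises(pf.GeometryError, match="thinner"):
            pf.GeometryParams(blood_channel_height=1e-3)

    def test_invalid_insertion_rejected(self):
        with pytest.raises(pf.GeometryError):
            pf.GeometryParams(insertion_depth=3e-3)

    def test_catheter_diameter_is_seven_french(self):
        assert pf.GeometryParams().catheter_diameter == pytest.approx(7e-3 / 3)
        assert FRENCH == pytest.approx(1e-3 / 3)

    def test_slab3d_extrusion_volumes(self):
        p = pf.GeometryParams(dimensionality="slab3d", n_layers_3d=2)
        mesh = pf.make_domain(p)
        lx, ly = p.domain_extent
        assert mesh.dim == 3
        assert mesh.cell_measures.sum() == pytest.approx(lx * ly * p.volume_depth, rel=1e-10)
        # per-region volumes are the planar areas times the depth
        planar = pf.make_domain(pf.GeometryParams())
        for r in pf.Region:
            assert mesh.region_measure(r) == pytest.approx(
                planar.region_measure(r) * p.volume_depth, rel=1e-9
            )


class TestWaveform:
    def test_mean_speed_matches_request(self):
        wf = pf.make_waveform(0.8, 0.1522, 1.5, 64)
        mean = np.mean(wf.speeds)
        assert mean == pytest.approx(0.1522, rel=1e-9)

    def test_biphasic_character(self):
        wf = pf.make_waveform()
        assert wf.local_maxima_count() == 2
        peaks = wf.peak_speeds()
        assert peaks[0] >= peaks[1]  # E-peak at least the A-peak
        assert np.all(wf.speeds >= 0)

    def test_equal_peaks_at_unit_ratio(self):
        wf = pf.make_waveform(e_to_a_ratio=1.0)
        peaks = wf.peak_speeds()
        assert peaks[0] == pytest.approx(peaks[1], rel=0.02)

    def test_rescaling_is_linear(self):
        wf = pf.make_waveform()
        doubled = wf.rescaled(2.0)
        assert np.mean(doubled.speeds) == pytest.approx(2 * np.mean(wf.speeds))

    def test_mean_invariant_to_sampling(self):
        means = [np.mean(pf.make_waveform(n_samples=n).speeds) for n in (32, 64, 256)]
        assert np.ptp(means) < 0.01 * 0.1522

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pf.make_waveform(n_samples=4)

    def test_csv_roundtrip(self, tmp_path):
        wf = pf.make_waveform()
        path = tmp_path / "wf.csv"
        wf.to_csv(path)
        back = pf.WaveformProfile.from_csv(path)
        np.testing.assert_allclose(back.speeds, wf.speeds, rtol=1e-12)
        assert back.cycle_duration == pytest.approx(wf.cycle_duration)

    def test_periodic_interpolation(self):
        wf = pf.make_waveform()
        assert wf(0.0) == pytest.approx(wf(wf.cycle_duration))
        assert wf(0.3) == pytest.approx(wf(0.3 + 5 * wf.cycle_duration))


class TestMeshIO:
    def test_roundtrip_preserves_everything(self, reference_mesh, tmp_path):
        path = tmp_path / "mesh.vtk"
        write_mesh(reference_mesh, path)
        back = read_mesh(path)
        np.testing.assert_array_equal(back.node_coords, reference_mesh.node_coords)
        np.testing.assert_array_equal(back.cells, reference_mesh.cells)
        np.testing.assert_array_equal(back.region, reference_mesh.region)
        np.testing.assert_array_equal(back.facet_label, reference_mesh.facet_label)
        np.testing.assert_array_equal(back.facet_cells, reference_mesh.facet_cells)

    def test_3d_roundtrip_preserves_cell_volumes(self, tmp_path):
        mesh = pf.make_domain(pf.GeometryParams(dimensionality="slab3d", n_layers_3d=2))
        path = tmp_path / "slab.vtk"
        write_mesh(mesh, path)
        back = read_mesh(path)
        np.testing.assert_array_equal(back.cell_measures, mesh.cell_measures)

    def test_missing_region_array_is_a_labelled_error(self, reference_mesh, tmp_path):
        path = tmp_path / "mesh.vtk"
        write_mesh(reference_mesh, path)
        text = path.read_text().replace("SCALARS region int 1", "SCALARS reg int 1")
        bad = tmp_path / "bad.vtk"
        bad.write_text(text)
        with pytest.raises(MeshFormatError, match="region"):
            read_mesh(bad)

    def test_field_snapshot_is_writable(self, reference_mesh, tmp_path):
        from pfasim.vtkio import write_fields

        path = tmp_path / "fields.vtk"
        write_fields(reference_mesh, path,
                     cell_data={"T": np.full(reference_mesh.n_cells, 37.0)},
                     point_data={"V": np.zeros(len(reference_mesh.node_coords))})
        assert "SCALARS T double" in path.read_text()
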