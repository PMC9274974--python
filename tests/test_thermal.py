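"""Bio-heat solver: geometry, sources, physics oracles and threshold report."""

import numpy as np
import pytest

from magnetoadrenal import thermal
from magnetoadrenal.thermal import (
    ADRENAL_TISSUE,
    FAT_TISSUE,
    LABEL_ADRENAL,
    LABEL_FAT,
    LABEL_OUTSIDE,
    GlandGeometry,
    InjectionSpec,
    PerfusionProperties,
    SimGrid,
    build_geometry,
    build_source,
    simulate,
    stability_limit,
    threshold_report,
)


def small_uniform_setup(spacing=0.5, half=3.0, duration=5.0, dt=None):
    grid = SimGrid(
        spacing=spacing, half_extents=(half, half, half),
        dt=dt or 0.9 * stability_limit(spacing, ADRENAL_TISSUE.diffusivity),
        duration=duration,
    )
    labels = np.full(grid.shape, LABEL_ADRENAL, dtype=np.int8)
    return grid, labels


class TestGeometry:
    def test_adrenal_volume_matches_analytic_ellipsoid(self):
        gland = GlandGeometry(axis_lengths=(5.5, 2.2, 2.2), fat_shell_thickness=0.5)
        grid = SimGrid.for_gland(gland, spacing=0.1)
        labels = build_geometry(gland, grid)
        vol = np.sum(labels == LABEL_ADRENAL) * grid.voxel_volume_mm3
        analytic = 4.0 / 3.0 * np.pi * 2.75 * 1.1 * 1.1
        assert vol == pytest.approx(analytic, rel=0.05)

    def test_zero_shell_gives_no_fat(self):
        gland = GlandGeometry(fat_shell_thickness=0.0)
        grid = SimGrid.for_gland(gland, spacing=0.2)
        labels = build_geometry(gland, grid)
        assert np.sum(labels == LABEL_FAT) == 0

    def test_origin_is_adrenal(self):
        gland = GlandGeometry()
        grid = SimGrid.for_gland(gland, spacing=0.2)
        labels = build_geometry(gland, grid)
        center = tuple(s // 2 for s in grid.shape)
        assert labels[center] == LABEL_ADRENAL

    def test_too_coarse_grid_rejected(self):
        gland = GlandGeometry()
        grid = SimGrid(spacing=0.5, half_extents=(5, 4, 4), dt=0.01, duration=1.0)
        with pytest.raises(ValueError, match="too coarse"):
            build_geometry(gland, grid)

    def test_fat_shell_between_ellipsoids(self):
        gland = GlandGeometry(fat_shell_thickness=0.5)
        grid = SimGrid.for_gland(gland, spacing=0.15)
        labels = build_geometry(gland, grid)
        assert np.sum(labels == LABEL_FAT) > 0
        # fat must not appear inside the inner ellipsoid
        xs, ys, zs = grid.axes()
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        a, b, c = gland.semi_axes
        inner = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
        assert not np.any((labels == LABEL_FAT) & inner)


class TestSource:
    def test_power_density_unit_conversion(self):
        # 600 W/g x 40 mg/ml = 2.4e7 W/m^3
        site = InjectionSpec(center=(0, 0, 0))
        assert site.power_density == pytest.approx(2.4e7)

    def test_sphere_radius_of_one_microliter(self):
        site = InjectionSpec(center=(0, 0, 0), volume_ul=1.0)
        assert site.radius_mm == pytest.approx(0.620, abs=0.001)

    def test_zero_slp_gives_zero_field(self):
        grid, labels = small_uniform_setup()
        src = build_source([InjectionSpec(center=(0, 0, 0), slp_w_per_g=0.0)],
                           grid, labels, gland=GlandGeometry(axis_lengths=(6, 6, 6)))
        assert np.all(src == 0.0)

    def test_total_power_within_discretization_error(self):
        gland = GlandGeometry()
        grid = SimGrid.for_gland(gland, spacing=0.1)
        labels = build_geometry(gland, grid)
        site = InjectionSpec(center=(1.0, 0, 0))
        src = build_source([site], grid, labels, gland=gland)
        total = src.sum() * (grid.spacing * 1e-3) ** 3
        assert total == pytest.approx(site.total_power, rel=0.02)

    def test_site_outside_gland_rejected(self):
        grid, labels = small_uniform_setup()
        with pytest.raises(ValueError, match="outside"):
            build_source([InjectionSpec(center=(5.0, 0, 0))], grid, labels,
                         gland=GlandGeometry())

    def test_overlapping_spheres_add(self):
        grid, labels = small_uniform_setup(spacing=0.2)
        gland = GlandGeometry(axis_lengths=(6, 6, 6))
        one = build_source([InjectionSpec(center=(0, 0, 0))], grid, labels, gland=gland)
        two = build_source([InjectionSpec(center=(0, 0, 0))] * 2, grid, labels, gland=gland)
        assert np.allclose(two, 2.0 * one)


class TestSimulate:
    def test_zero_source_is_invariant(self):
        grid, labels = small_uniform_setup(duration=2.0)
        src = np.zeros(grid.shape)
        f = simulate(labels, src, grid)
        assert np.all(f.snapshots[-1] == 37.0)
        assert np.all(f.probe_traces == 37.0)

    def test_energy_balance_ramp(self):
        # insulated, no perfusion, uniform source: dT/dt = q / (rho C)
        grid, labels = small_uniform_setup(duration=5.0)
        q = 1.0e5
        src = np.full(grid.shape, q)
        perf = PerfusionProperties(perfusion_rate=0.0)
        f = simulate(labels, src, grid, perfusion=perf, boundary="insulated",
                     tissue_map={LABEL_ADRENAL: ADRENAL_TISSUE})
        expected = 37.0 + q / ADRENAL_TISSUE.volumetric_heat_capacity * grid.n_steps * grid.dt
        assert np.mean(f.snapshots[-1]) == pytest.approx(expected, rel=1e-3)
        # uniform field stays uniform under the mirror boundary
        assert np.ptp(f.snapshots[-1]) < 1e-9

    def test_stability_violation_rejected(self):
        grid, labels = small_uniform_setup(
            dt=2.0 * stability_limit(0.5, ADRENAL_TISSUE.diffusivity))
        with pytest.raises(ValueError, match="stability"):
            simulate(labels, np.zeros(grid.shape), grid)

    def test_monotone_approach_with_constant_source(self):
        grid, labels = small_uniform_setup(spacing=0.4, duration=4.0)
        gland = GlandGeometry(axis_lengths=(5, 5, 5))
        src = build_source([InjectionSpec(center=(0, 0, 0))], grid, labels, gland=gland)
        f = simulate(labels, src, grid)
        diffs = np.diff(f.probe_traces, axis=1)
        assert diffs.min() > -1e-9

    def test_boundedness_by_steady_state(self):
        # max temperature never exceeds the infinite-medium steady bound
        grid, labels = small_uniform_setup(spacing=0.4, duration=4.0)
        gland = GlandGeometry(axis_lengths=(5, 5, 5))
        site = InjectionSpec(center=(0, 0, 0))
        src = build_source([site], grid, labels, gland=gland)
        perf = PerfusionProperties(perfusion_rate=0.0)
        f = simulate(labels, src, grid, perfusion=perf,
                     tissue_map={LABEL_ADRENAL: ADRENAL_TISSUE})
        a = site.radius_mm * 1e-3
        bound = 37.0 + site.power_density * a * a / (2 * ADRENAL_TISSUE.conductivity)
        assert f.peak_temperature <= bound + 1e-6

    def test_implicit_matches_explicit_on_coarse_grid(self):
        # both schemes at a dt well below the stability limit; the two
        # integrators differ at O(dt)
        grid, labels = small_uniform_setup(spacing=0.6, half=2.4, duration=3.0, dt=0.05)
        gland = GlandGeometry(axis_lengths=(4.5, 4.5, 4.5))
        src = build_source([InjectionSpec(center=(0, 0, 0))], grid, labels, gland=gland)
        fe = simulate(labels, src, grid)
        fi = simulate(labels, src, grid, scheme="implicit")
        assert fi.probe_traces[0, -1] == pytest.approx(fe.probe_traces[0, -1], abs=0.1)

    def test_grid_convergence_of_peak(self):
        # halving spacing changes the 60 s peak by < 3 %
        peaks = {}
        for spacing in (0.24, 0.12):
            _, rep = thermal.run_default_simulation(spacing=spacing, duration=60.0)
            peaks[spacing] = rep.peak_temperature
        assert abs(peaks[0.12] - peaks[0.24]) / peaks[0.24] < 0.03


class TestThresholdReport:
    def test_constant_field_below_threshold(self, coarse_gland_run):
        field, _ = coarse_gland_run
        grid, labels = small_uniform_setup(duration=2.0)
        f = simulate(labels, np.zeros(grid.shape), grid)
        rep = threshold_report(f, threshold=42.0, labels=labels)
        assert rep.time_to_threshold == [None]
        assert np.all(rep.volume_above_threshold_mm3 == 0.0)
        assert not rep.reached

    def test_threshold_at_initial_temperature_counts_whole_tissue(self):
        # boundary case documenting the >= comparison
        grid, labels = small_uniform_setup(duration=2.0)
        f = simulate(labels, np.zeros(grid.shape), grid)
        rep = threshold_report(f, threshold=37.0, labels=labels)
        assert rep.volume_above_threshold_mm3[-1] == pytest.approx(rep.tissue_volume_mm3)
        assert rep.time_to_threshold == [0.0]

    def test_threshold_below_initial_temperature_warns(self):
        grid, labels = small_uniform_setup(duration=2.0)
        f = simulate(labels, np.zeros(grid.shape), grid)
        with pytest.warns(UserWarning, match="below"):
            threshold_report(f, threshold=36.0, labels=labels)

    def test_study_configuration_heats_toward_threshold(self, coarse_gland_run):
        field, report = coarse_gland_run
        assert report.peak_temperature > 40.0
        assert report.volume_above_threshold_mm3[-1] <= report.tissue_volume_mm3
        # probes at the injection sites cross before the gland center
        site_cross = report.time_to_threshold[0]
        assert site_cross is not None and site_cross >= 0.0


def test_vtk_writer_roundtrip_header(tmp_path, coarse_gland_run):
    field, _ = coarse_gland_run
    path = tmp_path / "snap.vtk"
    thermal.write_vtk_structured_points(path, field)
    head = path.read_text().splitlines()[:6]
    assert head[0].startswith("# vtk DataFile")
    assert any(line.startswith("DIMENSIONS") for line in head)
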