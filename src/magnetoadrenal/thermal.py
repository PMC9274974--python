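"""Pennes bio-heat simulation of magnetic-nanoparticle heating in the
adrenal gland.

The gland is modelled as an ellipsoid of adrenal tissue wrapped in a fat
shell, embedded in a box of fat-like medium, with spherical nanoparticle
injection boluses acting as uniform volumetric heat sources.  The solver
integrates the Pennes equation per tissue

    rho C dT/dt = K lap(T) - rho_b C_b w_b (T - T_b) + P

on a cell-centered Cartesian grid (forward-time central-space by
default, backward Euler as an option) and reports whether and when the
tissue reaches the TRPV1 activation threshold (42 degC).

The blood-perfusion term is implemented as a heat sink for T > T_b, the
physically meaningful convention for perfused tissue.  Temperatures are
in degC throughout; the equation is offset-invariant so the Celsius /
Kelvin distinction only matters for the perfusion reference T_b.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "TissueProperties",
    "PerfusionProperties",
    "GlandGeometry",
    "InjectionSpec",
    "SimGrid",
    "TemperatureField",
    "ThresholdReport",
    "ADRENAL_TISSUE",
    "FAT_TISSUE",
    "TABLE_PERFUSION",
    "LABEL_OUTSIDE",
    "LABEL_ADRENAL",
    "LABEL_FAT",
    "TRPV1_THRESHOLD_C",
    "default_injection_sites",
    "build_geometry",
    "build_source",
    "simulate",
    "threshold_report",
    "write_vtk_structured_points",
]

LABEL_OUTSIDE = 0
LABEL_ADRENAL = 1
LABEL_FAT = 2

#: TRPV1 activation threshold used as the heating design target.
TRPV1_THRESHOLD_C = 42.0


@dataclass(frozen=True)
class TissueProperties:
    """Thermal properties of one tissue compartment (SI units)."""

    density: float  # kg/m^3
    heat_capacity: float  # J/(kg K)
    conductivity: float  # W/(m K)

    def __post_init__(self):
        if min(self.density, self.heat_capacity, self.conductivity) <= 0:
            raise ValueError("tissue properties must be strictly positive")

    @property
    def volumetric_heat_capacity(self) -> float:
        return self.density * self.heat_capacity

    @property
    def diffusivity(self) -> float:
        """Thermal diffusivity K/(rho C) in m^2/s."""
        return self.conductivity / (self.density * self.heat_capacity)


@dataclass(frozen=True)
class PerfusionProperties:
    """Blood-perfusion heat-exchange parameters."""

    blood_density: float = 1000.0  # kg/m^3
    blood_heat_capacity: float = 4180.0  # J/(kg K)
    perfusion_rate: float = 0.0064  # 1/s
    arterial_temperature: float = 37.0  # degC

    def __post_init__(self):
        if self.perfusion_rate < 0:
            raise ValueError("perfusion rate must be nonnegative")
        if not np.isfinite(self.arterial_temperature):
            raise ValueError("arterial temperature must be finite")

    @property
    def coefficient(self) -> float:
        """rho_b C_b w_b in W/(m^3 K)."""
        return self.blood_density * self.blood_heat_capacity * self.perfusion_rate


# Rat adrenal gland and perirenal fat thermal parameters.
ADRENAL_TISSUE = TissueProperties(density=1020.0, heat_capacity=3540.0, conductivity=0.52)
FAT_TISSUE = TissueProperties(density=911.0, heat_capacity=2348.0, conductivity=0.21)
TABLE_PERFUSION = PerfusionProperties()


@dataclass(frozen=True)
class GlandGeometry:
    """Ellipsoidal gland with a concentric fat shell.

    ``axis_lengths`` are full axis lengths in mm (the 5.5 x 2.2 x 2.2 mm
    gland has semi-axes 2.75/1.1/1.1 mm).
    """

    axis_lengths: tuple[float, float, float] = (5.5, 2.2, 2.2)
    fat_shell_thickness: float = 0.5  # mm

    def __post_init__(self):
        if min(self.axis_lengths) <= 0:
            raise ValueError("axis lengths must be strictly positive")
        if self.fat_shell_thickness < 0:
            raise ValueError("fat shell thickness must be nonnegative")

    @property
    def semi_axes(self) -> np.ndarray:
        return np.asarray(self.axis_lengths) / 2.0

    @property
    def outer_semi_axes(self) -> np.ndarray:
        return self.semi_axes + self.fat_shell_thickness

    def contains(self, point_mm) -> bool:
        p = np.asarray(point_mm, dtype=float)
        return float(np.sum((p / self.semi_axes) ** 2)) <= 1.0


@dataclass(frozen=True)
class InjectionSpec:
    """A nanoparticle injection bolus rendered as a uniform sphere."""

    center: tuple[float, float, float]  # mm, gland frame
    volume_ul: float = 1.0
    iron_concentration_mg_ml: float = 40.0
    slp_w_per_g: float = 600.0

    def __post_init__(self):
        if self.volume_ul <= 0 or self.iron_concentration_mg_ml <= 0:
            raise ValueError("volume and concentration must be positive")
        if self.slp_w_per_g < 0:
            raise ValueError("SLP must be nonnegative")

    @property
    def radius_mm(self) -> float:
        """Radius of the equivalent sphere: (3V / 4 pi)^(1/3), V in mm^3."""
        return float((3.0 * self.volume_ul / (4.0 * np.pi)) ** (1.0 / 3.0))

    @property
    def power_density(self) -> float:
        """Volumetric power SLP x [Fe] in W/m^3 (mg/ml == kg/m^3; 1000 g/kg)."""
        return self.slp_w_per_g * self.iron_concentration_mg_ml * 1000.0

    @property
    def total_power(self) -> float:
        """SLP x iron mass in W (mg/ml x ul = ug; 1e-6 g/ug)."""
        iron_mass_g = self.iron_concentration_mg_ml * self.volume_ul * 1e-6
        return self.slp_w_per_g * iron_mass_g


def default_injection_sites() -> list[InjectionSpec]:
    """Two 1-ul boluses on the gland's long axis at +/- 1 mm from center,
    mimicking the study's two-site injection protocol."""
    return [InjectionSpec(center=(-1.0, 0.0, 0.0)), InjectionSpec(center=(1.0, 0.0, 0.0))]


@dataclass(frozen=True)
class SimGrid:
    """Isotropic cell-centered grid and time stepping for the solver."""

    spacing: float  # mm
    half_extents: tuple[float, float, float]  # mm, box is [-h, h] per axis
    dt: float  # s
    duration: float = 60.0  # s
    initial_temperature: float = 37.0  # degC

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.dt <= 0 or self.duration < self.dt:
            raise ValueError("need 0 < dt <= duration")

    @classmethod
    def for_gland(
        cls,
        gland: GlandGeometry,
        spacing: float = 0.1,
        dt: float | None = None,
        duration: float = 60.0,
        margin: float = 1.0,
        initial_temperature: float = 37.0,
        safety: float = 0.9,
    ) -> "SimGrid":
        """Grid enclosing gland + shell + ``margin`` mm, with dt at
        ``safety`` times the explicit stability limit when not given."""
        half = tuple(float(a + margin) for a in gland.outer_semi_axes)
        if dt is None:
            alpha = max(ADRENAL_TISSUE.diffusivity, FAT_TISSUE.diffusivity)
            dt = safety * stability_limit(spacing, alpha)
        return cls(spacing=spacing, half_extents=half, dt=dt, duration=duration,
                   initial_temperature=initial_temperature)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cell-center coordinates (mm) along each axis."""
        out = []
        for h in self.half_extents:
            n = max(int(round(2.0 * h / self.spacing)), 1)
            # symmetric cell centers spanning [-h, h]
            out.append((np.arange(n) - (n - 1) / 2.0) * self.spacing)
        return tuple(out)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(len(a) for a in self.axes())

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing ** 3

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


def stability_limit(spacing_mm: float, diffusivity: float) -> float:
    """Explicit FTCS stability bound dt <= h^2 / (6 alpha), h in mm."""
    h = spacing_mm * 1e-3
    return h * h / (6.0 * diffusivity)


def build_geometry(gland: GlandGeometry, grid: SimGrid) -> np.ndarray:
    """Label voxels as adrenal, fat shell, or outside.

    A voxel is adrenal iff its center satisfies the inner-ellipsoid
    inequality, fat iff it lies between the inner and outer ellipsoids.
    Rejects grids coarser than 8 voxels across the smallest gland axis
    and boxes that do not enclose the fat shell with a 2-voxel margin.
    """
    min_axis = float(min(gland.axis_lengths))
    if min_axis / grid.spacing < 8.0:
        raise ValueError(
            f"grid too coarse: {min_axis / grid.spacing:.1f} voxels across the "
            f"smallest gland axis (need >= 8); reduce spacing below {min_axis / 8:.3f} mm"
        )
    outer = gland.outer_semi_axes
    for h, a in zip(grid.half_extents, outer):
        if h < a + 2.0 * grid.spacing:
            raise ValueError("grid bounds must enclose the fat shell with >= 2 voxels margin")
    xs, ys, zs = grid.axes()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    a, b, c = gland.semi_axes
    inner = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    ao, bo, co = outer
    outer_mask = (X / ao) ** 2 + (Y / bo) ** 2 + (Z / co) ** 2 <= 1.0
    labels = np.full(X.shape, LABEL_OUTSIDE, dtype=np.int8)
    labels[outer_mask] = LABEL_FAT
    labels[inner] = LABEL_ADRENAL
    return labels


def build_source(
    sites: list[InjectionSpec],
    grid: SimGrid,
    labels: np.ndarray,
    gland: GlandGeometry | None = None,
    profile: str = "sphere",
) -> np.ndarray:
    """Volumetric power density field (W/m^3) from injection boluses.

    Each site is a uniform sphere of the bolus volume with density
    SLP x [Fe]; overlapping spheres add.  ``profile='gaussian'`` renders
    an isotropic Gaussian with the same total power and sigma = r/2.
    Spheres truncated by the box are renormalized to conserve total
    power (with a warning).
    """
    xs, ys, zs = grid.axes()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    P = np.zeros(grid.shape, dtype=float)
    voxel_m3 = (grid.spacing * 1e-3) ** 3
    check = gland if gland is not None else GlandGeometry()
    for site in sites:
        if not check.contains(site.center):
            raise ValueError(f"injection site {site.center} lies outside the gland ellipsoid")
        cx, cy, cz = site.center
        r2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
        r = site.radius_mm
        if profile == "sphere":
            member = r2 <= r * r
            contrib = np.where(member, site.power_density, 0.0)
        elif profile == "gaussian":
            sigma = r / 2.0
            contrib = np.exp(-r2 / (2.0 * sigma**2))
            total = contrib.sum() * voxel_m3
            contrib *= site.total_power / total if total > 0 else 0.0
        else:
            raise ValueError("profile must be 'sphere' or 'gaussian'")
        if site.slp_w_per_g == 0:
            continue
        # truncation check: does the sphere poke out of the box?
        truncated = any(
            abs(c) + r > h for c, h in zip(site.center, (x.max() for x in (xs, ys, zs)))
        )
        if profile == "sphere":
            discrete_power = contrib.sum() * voxel_m3
            if truncated and discrete_power > 0:
                warnings.warn("injection sphere truncated by domain boundary; renormalizing power")
                contrib = contrib * (site.total_power / discrete_power)
        P += contrib
    return P


@dataclass
class TemperatureField:
    """Temperature trajectory: sparse snapshots plus dense probe traces."""

    snapshot_times: np.ndarray  # s
    snapshots: list  # list of 3-D arrays, degC
    probe_points: list  # mm coordinates
    probe_times: np.ndarray  # s, every step
    probe_traces: np.ndarray  # (n_probes, n_steps+1) degC
    peak_trace: np.ndarray  # max tissue temperature per step, degC
    grid: SimGrid | None = None
    labels: np.ndarray | None = None

    @property
    def peak_temperature(self) -> float:
        return float(self.peak_trace.max())

    def probe_trace_frame(self):
        import pandas as pd

        data = {"time_s": self.probe_times}
        for i, p in enumerate(self.probe_points):
            data[f"probe{i}_x{p[0]:g}_y{p[1]:g}_z{p[2]:g}"] = self.probe_traces[i]
        return pd.DataFrame(data)


def _nearest_index(axes, point_mm):
    return tuple(int(np.argmin(np.abs(ax - c))) for ax, c in zip(axes, point_mm))


def simulate(
    labels: np.ndarray,
    source: np.ndarray,
    grid: SimGrid,
    tissue_map: dict | None = None,
    perfusion: PerfusionProperties | None = None,
    probes: list | None = None,
    snapshot_times: list | None = None,
    boundary: str = "dirichlet",
    scheme: str = "explicit",
) -> TemperatureField:
    """Integrate the Pennes equation on the labeled grid.

    tissue_map maps label codes to :class:`TissueProperties`; unlabeled
    (outside) voxels default to fat, modelling the fat-embedded gland.
    Boundary is Dirichlet at the initial temperature on the outer box by
    default, or ``'insulated'`` (zero-flux).  The explicit scheme
    refuses dt above the stability limit; ``scheme='implicit'`` is an
    unconditionally stable backward-Euler alternative for coarse grids.
    Perfusion acts as a sink wherever T exceeds the arterial
    temperature, in every labeled and outside tissue alike.
    """
    if tissue_map is None:
        tissue_map = {LABEL_ADRENAL: ADRENAL_TISSUE, LABEL_FAT: FAT_TISSUE,
                      LABEL_OUTSIDE: FAT_TISSUE}
    if perfusion is None:
        perfusion = TABLE_PERFUSION
    if labels.shape != grid.shape or source.shape != grid.shape:
        raise ValueError("labels/source shape does not match the grid")
    if np.any(source < 0):
        raise ValueError("source field must be nonnegative")
    if boundary not in ("dirichlet", "insulated"):
        raise ValueError("boundary must be 'dirichlet' or 'insulated'")

    h = grid.spacing * 1e-3  # m
    K = np.zeros(grid.shape)
    rhoC = np.zeros(grid.shape)
    for code in np.unique(labels):
        props = tissue_map.get(int(code), tissue_map.get(LABEL_OUTSIDE, FAT_TISSUE))
        m = labels == code
        K[m] = props.conductivity
        rhoC[m] = props.volumetric_heat_capacity
    alpha_max = float((K / rhoC).max())
    if scheme == "explicit" and grid.dt > stability_limit(grid.spacing, alpha_max) * (1 + 1e-12):
        raise ValueError(
            f"dt = {grid.dt:.4g} s violates the explicit stability limit "
            f"{stability_limit(grid.spacing, alpha_max):.4g} s; reduce dt or use scheme='implicit'"
        )
    if scheme not in ("explicit", "implicit"):
        raise ValueError("scheme must be 'explicit' or 'implicit'")

    xs, ys, zs = grid.axes()
    if probes is None:
        probes = [(0.0, 0.0, 0.0)]
    probe_idx = [_nearest_index((xs, ys, zs), p) for p in probes]
    n_steps = grid.n_steps
    if snapshot_times is None:
        snapshot_times = [grid.duration]
    snap_steps = sorted({min(int(round(t / grid.dt)), n_steps) for t in snapshot_times})

    T0 = grid.initial_temperature
    Tb = perfusion.arterial_temperature
    T = np.full(grid.shape, T0, dtype=float)
    tissue_mask = labels != LABEL_OUTSIDE
    if not tissue_mask.any():
        tissue_mask = np.ones_like(labels, dtype=bool)

    perf = perfusion.coefficient  # W/(m^3 K)
    traces = np.empty((len(probe_idx), n_steps + 1))
    peak = np.empty(n_steps + 1)
    for j, idx in enumerate(probe_idx):
        traces[j, 0] = T[idx]
    peak[0] = T[tissue_mask].max()
    snapshots, snap_times_out = [], []
    if 0 in snap_steps:
        snapshots.append(T.copy())
        snap_times_out.append(0.0)

    if scheme == "implicit":
        A = _backward_euler_matrix(K, rhoC, perf, grid, boundary)
        lu = spla.splu(A.tocsc())

    inv_rhoC_dt = grid.dt / rhoC
    for step in range(1, n_steps + 1):
        if scheme == "explicit":
            if boundary == "insulated":
                Tp = np.pad(T, 1, mode="edge")
            else:
                Tp = np.pad(T, 1, mode="constant", constant_values=T0)
            lap = (
                Tp[:-2, 1:-1, 1:-1] + Tp[2:, 1:-1, 1:-1]
                + Tp[1:-1, :-2, 1:-1] + Tp[1:-1, 2:, 1:-1]
                + Tp[1:-1, 1:-1, :-2] + Tp[1:-1, 1:-1, 2:]
                - 6.0 * T
            ) / (h * h)
            T = T + inv_rhoC_dt * (K * lap - perf * (T - Tb) + source)
        else:
            rhs = (rhoC / grid.dt) * T + source + perf * Tb
            if boundary == "dirichlet":
                rhs = rhs + _dirichlet_rhs(K, grid, T0)
            T = lu.solve(rhs.ravel()).reshape(grid.shape)
        if not np.all(np.isfinite(T)):
            raise FloatingPointError(f"non-finite temperature at step {step}")
        for j, idx in enumerate(probe_idx):
            traces[j, step] = T[idx]
        peak[step] = T[tissue_mask].max()
        if step in snap_steps:
            snapshots.append(T.copy())
            snap_times_out.append(step * grid.dt)

    return TemperatureField(
        snapshot_times=np.asarray(snap_times_out),
        snapshots=snapshots,
        probe_points=list(probes),
        probe_times=np.arange(n_steps + 1) * grid.dt,
        probe_traces=traces,
        peak_trace=peak,
        grid=grid,
        labels=labels,
    )


def _backward_euler_matrix(K, rhoC, perf, grid, boundary):
    """(rhoC/dt + perf) I - div(K grad) with the requested boundary."""
    h = grid.spacing * 1e-3
    nx, ny, nz = grid.shape
    n = nx * ny * nz
    idx = np.arange(n).reshape(grid.shape)
    diag = rhoC.ravel() / grid.dt + perf
    rows, cols, vals = [], [], []
    kflat = K.ravel()
    for axis in range(3):
        for shift in (-1, 1):
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if shift == 1:
                src[axis] = slice(0, -1)
                dst[axis] = slice(1, None)
            else:
                src[axis] = slice(1, None)
                dst[axis] = slice(0, -1)
            i_src = idx[tuple(src)].ravel()
            i_dst = idx[tuple(dst)].ravel()
            w = kflat[i_src] / (h * h)
            rows.append(i_src)
            cols.append(i_dst)
            vals.append(-w)
            diag = diag.copy()
            np.add.at(diag, i_src, w)
    # boundary faces: dirichlet adds a link to the fixed exterior value
    # (handled in the rhs); insulated adds nothing (mirror)
    if boundary == "dirichlet":
        for axis in range(3):
            for face in (0, -1):
                sl = [slice(None)] * 3
                sl[axis] = face
                i_face = idx[tuple(sl)].ravel()
                w = kflat[i_face] / (h * h)
                diag = diag.copy()
                np.add.at(diag, i_face, w)
    A = sp.coo_matrix(
        (np.concatenate(vals + [diag]),
         (np.concatenate(rows + [np.arange(n)]), np.concatenate(cols + [np.arange(n)]))),
        shape=(n, n),
    )
    return A


def _dirichlet_rhs(K, grid, T0):
    h = grid.spacing * 1e-3
    add = np.zeros(grid.shape)
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            add[tuple(sl)] += K[tuple(sl)] * T0 / (h * h)
    return add


@dataclass
class ThresholdReport:
    """Did the tissue reach the activation threshold, where and when."""

    threshold: float  # degC
    peak_temperature: float  # degC
    time_to_threshold: list  # per probe, s or None
    volume_above_threshold_mm3: np.ndarray  # per snapshot
    snapshot_times: np.ndarray
    tissue_volume_mm3: float

    @property
    def reached(self) -> bool:
        return self.peak_temperature >= self.threshold

    def to_dict(self) -> dict:
        return {
            "threshold_c": float(self.threshold),
            "peak_temperature_c": float(self.peak_temperature),
            "reached": bool(self.reached),
            "time_to_threshold_s": [None if t is None else float(t) for t in self.time_to_threshold],
            "snapshot_times_s": self.snapshot_times.tolist(),
            "volume_above_threshold_mm3": self.volume_above_threshold_mm3.tolist(),
            "tissue_volume_mm3": float(self.tissue_volume_mm3),
        }


def threshold_report(
    field: TemperatureField,
    threshold: float = TRPV1_THRESHOLD_C,
    labels: np.ndarray | None = None,
) -> ThresholdReport:
    """First-crossing times, volume above threshold and peak temperature.

    The comparison is >= (a sample exactly at threshold counts as
    above).  Probe crossing times are linearly interpolated between
    steps.
    """
    if labels is None:
        labels = field.labels
    grid = field.grid
    if len(field.snapshots) == 0:
        raise ValueError("temperature field has no snapshots")
    if threshold < field.probe_traces[:, 0].min():
        warnings.warn("threshold below the initial temperature: everything is 'above' at t=0")
    tissue = labels != LABEL_OUTSIDE if labels is not None else None

    t2t = []
    for trace in field.probe_traces:
        above = trace >= threshold
        if not above.any():
            t2t.append(None)
            continue
        k = int(np.argmax(above))
        if k == 0:
            t2t.append(0.0)
        else:
            t0, t1 = field.probe_times[k - 1], field.probe_times[k]
            y0, y1 = trace[k - 1], trace[k]
            frac = (threshold - y0) / (y1 - y0) if y1 != y0 else 0.0
            t2t.append(float(t0 + frac * (t1 - t0)))

    vol = np.empty(len(field.snapshots))
    voxel = grid.voxel_volume_mm3 if grid is not None else 1.0
    for i, snap in enumerate(field.snapshots):
        hot = snap >= threshold
        if tissue is not None:
            hot = hot & tissue
        vol[i] = hot.sum() * voxel
    tissue_volume = float(tissue.sum()) * voxel if tissue is not None else float(np.prod(field.snapshots[0].shape)) * voxel
    return ThresholdReport(
        threshold=threshold,
        peak_temperature=field.peak_temperature,
        time_to_threshold=t2t,
        volume_above_threshold_mm3=vol,
        snapshot_times=field.snapshot_times,
        tissue_volume_mm3=tissue_volume,
    )


def write_vtk_structured_points(path, field: TemperatureField, snapshot_index: int = -1):
    """Write one snapshot as legacy ASCII VTK structured points (for
    external visualization)."""
    snap = field.snapshots[snapshot_index]
    grid = field.grid
    nx, ny, nz = snap.shape
    h = grid.spacing
    xs, ys, zs = grid.axes()
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("temperature snapshot (degC)\nASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        f.write(f"ORIGIN {xs[0]} {ys[0]} {zs[0]}\n")
        f.write(f"SPACING {h} {h} {h}\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        f.write("SCALARS temperature_c float 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, snap.ravel(order="F")[:, None], fmt="%.6g")


def run_default_simulation(
    spacing: float = 0.1,
    duration: float = 60.0,
    sites: list | None = None,
    gland: GlandGeometry | None = None,
    threshold: float = TRPV1_THRESHOLD_C,
    snapshot_times: list | None = None,
    dt: float | None = None,
):
    """Convenience wrapper: study-parameter simulation of the two-site
    1-ul injection protocol, returning (field, report)."""
    gland = gland or GlandGeometry()
    sites = sites if sites is not None else default_injection_sites()
    grid = SimGrid.for_gland(gland, spacing=spacing, duration=duration, dt=dt)
    labels = build_geometry(gland, grid)
    source = build_source(sites, grid, labels, gland=gland)
    probes = [s.center for s in sites] + [(0.0, 0.0, 0.0)]
    if snapshot_times is None:
        snapshot_times = [duration / 2, duration]
    field = simulate(labels, source, grid, probes=probes, snapshot_times=snapshot_times)
    report = threshold_report(field, threshold=threshold, labels=labels)
    return field, report
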