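"""Bioheat solver and temperature-sensor model for the implanted device.

The in-vivo heating problem is reduced to a 2-D axisymmetric cylindrical
domain: a stack of horizontal layers (overlying muscle, the encapsulated
device, dura, spinal cord, lamina) with the µ-LED heat load applied as a
volumetric source in an equal-area disc inside the device layer.  The
governing equation is the Pennes bioheat equation with the blood-perfusion
and metabolic-heat terms dropped,

    rho c dT/dt = div(k grad T) + q(t),

discretised by a conservative finite-volume scheme and integrated with
backward Euler (unconditionally stable).  The device layer is a flexible
copper/polyimide laminate and is modelled anisotropically: low
through-plane conductivity (polyimide) but high effective in-plane
conductivity (metal interconnects), which spreads the LED heat laterally
before it enters the cord — the feature that keeps such implants within
the 2 K biocompatibility bound.  The laminate patch has a finite radius;
beyond it the row reverts to the overlying tissue.

The simulation tracks the temperature *perturbation* about the
thermoregulated 37 C baseline: the outer-surface exchange applied is the
convective + radiative flux net of its value at 37 C, since the baseline
heat loss of the animal is balanced by the perfusion and metabolism the
simplified equation omits.  With zero load the field therefore stays at
exactly 37 C, and the reported "rise" needs no reference run.  Convection
is treated implicitly; the (small) radiative term is evaluated from the
previous step so the system matrix is factorised once.

Internal solver units are SI (m, W, s, K); the public surface uses the
package conventions (mm, mW, degrees C).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

__all__ = [
    "LayerSpec",
    "ThermalBoundary",
    "DutyCycleLoad",
    "TemperatureTrace",
    "SensorCal",
    "SensorReading",
    "Grid",
    "default_stack",
    "led_heat_power",
    "electrical_input_power",
    "build_grid",
    "simulate",
    "peak_rise_by_duty",
    "sensor_resistance",
    "sensor_temperature",
]

KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class LayerSpec:
    """One horizontal layer of the device/tissue stack.

    thickness in mm; conductivity W m^-1 K^-1; density kg m^-3; specific
    heat J kg^-1 K^-1.  ``conductivity`` is the through-plane (axial)
    value; ``conductivity_radial`` defaults to it (isotropic) and is
    raised for laminate layers that spread heat in-plane.
    """

    name: str
    thickness: float
    conductivity: float
    density: float
    specific_heat: float
    conductivity_radial: float | None = None

    def __post_init__(self) -> None:
        for attr in ("thickness", "conductivity", "density", "specific_heat"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"layer {self.name}: {attr} must be > 0")
        if self.conductivity_radial is not None and self.conductivity_radial <= 0:
            raise ValueError(f"layer {self.name}: conductivity_radial must be > 0")

    @property
    def k_radial(self) -> float:
        return (
            self.conductivity
            if self.conductivity_radial is None
            else self.conductivity_radial
        )


def default_stack() -> list[LayerSpec]:
    """Literature-default device/tissue stack, top (outer) to bottom (deep).

    The device sits under ~2 mm of paravertebral muscle; its Cu/polyimide
    laminate layer hosts the heat source (through-plane k of polyimide,
    in-plane effective k of the copper interconnect traces by a rule of
    mixtures); below lie dura, spinal cord, and the laminar bone shelf.
    Tissue conductivities are standard soft-tissue/bone values; every
    value is config-overridable.
    """
    return [
        LayerSpec("muscle", 2.0, 0.50, 1090.0, 3421.0),
        LayerSpec("device", 0.1, 0.20, 2000.0, 1100.0, conductivity_radial=30.0),
        LayerSpec("dura", 0.3, 0.44, 1174.0, 3364.0),
        LayerSpec("cord", 3.0, 0.51, 1075.0, 3630.0),
        LayerSpec("lamina", 1.0, 0.32, 1908.0, 1313.0),
    ]


@dataclass(frozen=True)
class ThermalBoundary:
    """Environmental boundary constants for the outer surface."""

    ambient_T: float = 25.0  # C
    convection_h: float = 27.0  # W m^-2 K^-1
    emissivity: float = 0.8
    stefan_boltzmann: float = 5.67e-8  # W m^-2 K^-4
    core_T: float = 37.0  # C, initial field and deep-boundary clamp

    def __post_init__(self) -> None:
        if not 0.0 <= self.emissivity <= 1.0:
            raise ValueError("emissivity must lie in [0, 1]")
        if self.convection_h < 0:
            raise ValueError("convection_h must be >= 0")


@dataclass(frozen=True)
class DutyCycleLoad:
    """Duty-cycled heat load: on for on_duration, off for off_duration."""

    heat_power_mW: float
    on_duration: float = 60.0  # s
    off_duration: float = 90.0  # s
    duty: float = 1.0  # PWM duty this load corresponds to (bookkeeping)

    def __post_init__(self) -> None:
        if self.on_duration <= 0 or self.off_duration <= 0:
            raise ValueError("on/off durations must be > 0")
        if self.heat_power_mW < 0:
            raise ValueError("heat_power_mW must be >= 0")

    def is_on(self, t: float) -> bool:
        """True while the LED is driven within the periodic cycle."""
        period = self.on_duration + self.off_duration
        return (t % period) < self.on_duration


@dataclass
class TemperatureTrace:
    """Probe traces from one simulation run."""

    times: np.ndarray  # s
    probes: dict[str, np.ndarray]  # name -> temperature (C) per time
    peak_rise: float  # K, max over the cord probe minus core_T
    time_of_peak: float  # s

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.times})
        for name, trace in self.probes.items():
            df[f"T_{name}_C"] = trace
        return df


def led_heat_power(electrical_power_mW: float, luminous_power_mW: float) -> float:
    """Heat dissipated by the LED: electrical input minus luminous output."""
    if luminous_power_mW < 0 or electrical_power_mW < 0:
        raise ValueError("powers must be >= 0")
    if luminous_power_mW > electrical_power_mW:
        raise ValueError(
            "luminous power exceeds electrical input (efficiency > 1 is unphysical)"
        )
    return electrical_power_mW - luminous_power_mW


def electrical_input_power(
    duty: float, full_luminous_power_mW: float, wall_plug_efficiency: float = 0.30
) -> float:
    """Electrical input at a PWM duty, from luminous power and efficiency."""
    if not 0 < wall_plug_efficiency <= 1:
        raise ValueError("wall_plug_efficiency must lie in (0, 1]")
    return duty * full_luminous_power_mW / wall_plug_efficiency


class Grid:
    """Axisymmetric cell-centred finite-volume grid over the layer stack.

    Material fields are stored per cell, so a layer can be restricted to a
    finite radial patch (the implanted device) with the overlying tissue
    filling the remainder of the row.
    """

    def __init__(
        self,
        layers: Sequence[LayerSpec],
        radial_extent: float = 4.0,
        dr: float = 0.1,
        dz: float = 0.05,
        source_layer: str = "device",
        source_radius: float = 0.597,
        device_radius: float | None = 1.75,
    ) -> None:
        if len(layers) == 0:
            raise ValueError("need at least one layer")
        if dr <= 0 or dz <= 0 or radial_extent <= 0:
            raise ValueError("grid spacings and extent must be > 0")
        self.layers = list(layers)
        self.dr_m = dr * 1e-3
        self.dz_m = dz * 1e-3
        self.nr = int(round(radial_extent / dr))

        nz_per_layer: list[int] = []
        for lay in self.layers:
            n = int(round(lay.thickness / dz))
            if n < 1:
                raise ValueError(
                    f"layer {lay.name} ({lay.thickness} mm) thinner than one "
                    f"cell (dz = {dz} mm)"
                )
            nz_per_layer.append(n)
        self.nz = sum(nz_per_layer)
        self.n_cells = self.nr * self.nz

        # cell centres (m)
        self.r_centers = (np.arange(self.nr) + 0.5) * self.dr_m
        self.z_centers = (np.arange(self.nz) + 0.5) * self.dz_m
        # cell volumes (m^3): 2 pi r dr dz
        self.cell_volume = np.broadcast_to(
            2.0 * np.pi * self.r_centers[None, :] * self.dr_m * self.dz_m,
            (self.nz, self.nr),
        ).copy()

        # per-cell material maps
        self.k_r = np.empty((self.nz, self.nr))
        self.k_z = np.empty((self.nz, self.nr))
        self.rho_c = np.empty((self.nz, self.nr))
        self.layer_rows: dict[str, slice] = {}
        row = 0
        for idx, (lay, n) in enumerate(zip(self.layers, nz_per_layer)):
            sl = slice(row, row + n)
            self.k_r[sl, :] = lay.k_radial
            self.k_z[sl, :] = lay.conductivity
            self.rho_c[sl, :] = lay.density * lay.specific_heat
            self.layer_rows[lay.name] = sl
            row += n

        # device patch: outside device_radius the source layer's row reverts
        # to the material of the layer above it (the surgical pocket tissue)
        if source_layer not in self.layer_rows:
            raise ValueError(f"source layer {source_layer!r} not in stack")
        if device_radius is not None:
            names = [lay.name for lay in self.layers]
            i_dev = names.index(source_layer)
            if i_dev > 0:
                outside = self.layers[i_dev - 1]
                sl = self.layer_rows[source_layer]
                out_cols = self.r_centers > device_radius * 1e-3
                self.k_r[sl, out_cols] = outside.k_radial
                self.k_z[sl, out_cols] = outside.conductivity
                self.rho_c[sl, out_cols] = outside.density * outside.specific_heat

        # heat-source mask: disc of source_radius inside the device layer
        self.source_mask = np.zeros((self.nz, self.nr), dtype=bool)
        sl = self.layer_rows[source_layer]
        rmask = self.r_centers <= source_radius * 1e-3
        self.source_mask[sl, :] = rmask[None, :]
        if not self.source_mask.any():
            raise ValueError("source disc contains no cells; refine the grid")
        self.source_volume = float(self.cell_volume[self.source_mask].sum())

    def index(self, j: int, i: int) -> int:
        """Flat index of cell at row j (depth), column i (radius)."""
        return j * self.nr + i


def build_grid(
    layers: Sequence[LayerSpec] | None = None,
    radial_extent: float = 4.0,
    dr: float = 0.1,
    dz: float = 0.05,
    source_layer: str = "device",
    source_radius: float = 0.597,
    device_radius: float | None = 1.75,
) -> Grid:
    """Discretise the layer stack into an axisymmetric (r, z) grid.

    ``source_radius`` (mm) is the equal-area disc of the 2x2 µ-LED array
    envelope (1.4 mm x 0.8 mm); ``device_radius`` bounds the laminate
    patch (the implant's main module).
    """
    return Grid(
        layers if layers is not None else default_stack(),
        radial_extent=radial_extent,
        dr=dr,
        dz=dz,
        source_layer=source_layer,
        source_radius=source_radius,
        device_radius=device_radius,
    )


def _harmonic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return 2.0 * a * b / (a + b)


def _assemble(
    grid: Grid,
    boundary: ThermalBoundary,
    *,
    clamp_bottom: bool,
    clamp_lateral: bool,
    convective_top: bool,
) -> tuple[sparse.csc_matrix, np.ndarray]:
    """Conduction operator K (W/K) acting on the perturbation field, plus
    the top-surface area vector used for the explicit radiation term.

    Clamped faces hold the perturbation at 0 (i.e. T = core_T) through a
    half-cell conductance, so no Dirichlet source vector is needed.
    """
    nr, nz = grid.nr, grid.nz
    n = grid.n_cells
    dr, dz = grid.dr_m, grid.dz_m
    idx = np.arange(n).reshape(nz, nr)

    rows_l: list[np.ndarray] = []
    cols_l: list[np.ndarray] = []
    vals_l: list[np.ndarray] = []
    diag = np.zeros(n)

    def add_pairs(a: np.ndarray, b: np.ndarray, g: np.ndarray) -> None:
        a, b, g = a.ravel(), b.ravel(), g.ravel()
        rows_l.extend((a, b))
        cols_l.extend((b, a))
        vals_l.extend((-g, -g))
        np.add.at(diag, a, g)
        np.add.at(diag, b, g)

    # radial faces between columns i and i+1: area 2 pi r_face dz
    r_face = (np.arange(1, nr)) * dr  # face radii
    g_r = _harmonic(grid.k_r[:, :-1], grid.k_r[:, 1:]) * (
        2.0 * np.pi * r_face[None, :] * dz
    ) / dr
    add_pairs(idx[:, :-1], idx[:, 1:], g_r)

    # vertical faces between rows j and j+1: area 2 pi r dr
    g_z = _harmonic(grid.k_z[:-1, :], grid.k_z[1:, :]) * (
        2.0 * np.pi * grid.r_centers[None, :] * dr
    ) / dz
    add_pairs(idx[:-1, :], idx[1:, :], g_z)

    ring_area = 2.0 * np.pi * grid.r_centers * dr
    top_area = np.zeros(n)
    top_area[idx[0, :]] = ring_area
    if convective_top:
        np.add.at(diag, idx[0, :], boundary.convection_h * ring_area)
    if clamp_bottom:
        np.add.at(diag, idx[-1, :], grid.k_z[-1, :] * ring_area / (dz / 2.0))
    if clamp_lateral:
        side_area = 2.0 * np.pi * (nr * dr) * dz
        np.add.at(diag, idx[:, -1], grid.k_r[:, -1] * side_area / (dr / 2.0))

    rows = np.concatenate(rows_l + [np.arange(n)])
    cols = np.concatenate(cols_l + [np.arange(n)])
    vals = np.concatenate(vals_l + [diag])
    K = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    return K, top_area


def simulate(
    grid: Grid,
    boundary: ThermalBoundary,
    load: DutyCycleLoad,
    t_end: float = 150.0,
    dt: float = 0.1,
    *,
    clamp_bottom: bool = True,
    clamp_lateral: bool = True,
    convective_top: bool = True,
    radiative_top: bool = True,
    cord_layer: str = "cord",
    led_layer: str = "device",
) -> TemperatureTrace:
    """Integrate the duty-cycled heating problem from a uniform 37 C field.

    Returns probe traces at the LED (axis cell of the device layer) and at
    the hottest cord cell (the dorsal cord surface under the LED), plus
    the peak cord rise and its time.  Boundary flags exist to insulate the
    domain for conservation checks.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    K, top_area = _assemble(
        grid,
        boundary,
        clamp_bottom=clamp_bottom,
        clamp_lateral=clamp_lateral,
        convective_top=convective_top,
    )
    n = grid.n_cells
    mass = (grid.rho_c * grid.cell_volume).ravel() / dt  # W/K per cell
    A = (sparse.diags(mass) + K).tocsc()
    lu = splu(A)

    q_cell = np.zeros(n)
    q_cell[grid.source_mask.ravel()] = (
        load.heat_power_mW * 1e-3 / grid.source_volume
    )  # W m^-3 while on
    q_cell = q_cell * grid.cell_volume.ravel()  # W per cell

    sigma_eps = boundary.emissivity * boundary.stefan_boltzmann
    core_K4 = (boundary.core_T + KELVIN_OFFSET) ** 4

    theta = np.zeros(n)  # perturbation about core_T
    n_steps = int(round(t_end / dt))
    sl = grid.layer_rows[led_layer]
    led_idx = grid.index(sl.start + (sl.stop - sl.start) // 2, 0)

    # cord probe: fixed physical point on the axis, 0.05 mm below the
    # dorsal cord surface, z-interpolated between cell centres so the
    # probe does not move with the mesh (dT/dr = 0 on the axis, so the
    # first-column value converges quadratically to r = 0)
    z_probe = grid.z_centers[grid.layer_rows[cord_layer].start] - grid.dz_m / 2.0 \
        + 0.05e-3
    j_hi = int(np.searchsorted(grid.z_centers, z_probe))
    j_lo = max(j_hi - 1, 0)
    j_hi = min(j_hi, grid.nz - 1)
    if j_hi == j_lo:
        w_hi = 0.0
    else:
        w_hi = (z_probe - grid.z_centers[j_lo]) / (
            grid.z_centers[j_hi] - grid.z_centers[j_lo]
        )
    probe_lo, probe_hi = grid.index(j_lo, 0), grid.index(j_hi, 0)

    times = np.empty(n_steps + 1)
    t_led = np.empty(n_steps + 1)
    t_cord = np.empty(n_steps + 1)
    times[0], t_led[0], t_cord[0] = 0.0, boundary.core_T, boundary.core_T

    for step in range(n_steps):
        t_mid = (step + 0.5) * dt
        rhs = mass * theta
        if load.is_on(t_mid):
            rhs = rhs + q_cell
        if radiative_top and convective_top:
            # explicit radiative exchange net of the 37 C baseline
            surf_K = theta + (boundary.core_T + KELVIN_OFFSET)
            rhs = rhs - sigma_eps * top_area * (surf_K**4 - core_K4)
        theta = lu.solve(rhs)
        times[step + 1] = (step + 1) * dt
        t_led[step + 1] = boundary.core_T + theta[led_idx]
        t_cord[step + 1] = boundary.core_T + (
            (1.0 - w_hi) * theta[probe_lo] + w_hi * theta[probe_hi]
        )

    rise = t_cord - boundary.core_T
    ipk = int(np.argmax(rise))
    return TemperatureTrace(
        times=times,
        probes={"led": t_led, "cord": t_cord},
        peak_rise=float(rise[ipk]),
        time_of_peak=float(times[ipk]),
    )


def peak_rise_by_duty(
    duty_ladder: Sequence[float],
    *,
    full_luminous_power_mW: float = 4.69,
    wall_plug_efficiency: float = 0.30,
    grid: Grid | None = None,
    boundary: ThermalBoundary | None = None,
    on_duration: float = 60.0,
    off_duration: float = 90.0,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Peak cord temperature rise for each PWM duty over one on/off cycle.

    The heat power at duty d is the electrical input d*P/eta minus the
    luminous output d*P.  Columns: duty, heat_power_mW, peak_rise_K,
    time_of_peak_s.
    """
    grid = grid if grid is not None else build_grid()
    boundary = boundary if boundary is not None else ThermalBoundary()
    rows = []
    for duty in duty_ladder:
        lum = duty * full_luminous_power_mW
        elec = electrical_input_power(duty, full_luminous_power_mW, wall_plug_efficiency)
        heat = led_heat_power(elec, lum)
        if heat == 0.0:
            rows.append(
                {"duty": duty, "heat_power_mW": 0.0, "peak_rise_K": 0.0,
                 "time_of_peak_s": 0.0}
            )
            continue
        load = DutyCycleLoad(heat, on_duration, off_duration, duty)
        trace = simulate(grid, boundary, load, t_end=on_duration + off_duration, dt=dt)
        rows.append(
            {
                "duty": duty,
                "heat_power_mW": heat,
                "peak_rise_K": trace.peak_rise,
                "time_of_peak_s": trace.time_of_peak,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# resistive temperature sensor


@dataclass(frozen=True)
class SensorCal:
    """Linear RTD calibration R(T) = R0 (1 + alpha (T - T0)), valid on the
    device's calibrated working band (31-43 C)."""

    R0: float = 1000.0  # ohm
    T0: float = 0.0  # C
    tcr_alpha: float = 3.9e-3  # K^-1
    valid_range: tuple[float, float] = (31.0, 43.0)

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("R0 must be > 0")


class SensorReading(NamedTuple):
    value: float
    in_range: bool


def sensor_resistance(T: float, cal: SensorCal) -> SensorReading:
    """Resistance (ohm) at temperature T; flags outside the calibrated band."""
    lo, hi = cal.valid_range
    return SensorReading(cal.R0 * (1.0 + cal.tcr_alpha * (T - cal.T0)), lo <= T <= hi)


def sensor_temperature(R: float, cal: SensorCal) -> SensorReading:
    """Exact inverse of :func:`sensor_resistance`."""
    T = cal.T0 + (R / cal.R0 - 1.0) / cal.tcr_alpha
    if not -50.0 < T < 150.0:
        raise ValueError(f"resistance {R} ohm implies unphysical {T:.1f} C")
    lo, hi = cal.valid_range
    return SensorReading(T, lo <= T <= hi)
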