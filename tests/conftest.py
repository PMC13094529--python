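import pytest

from optocord import control, optics, thermal


@pytest.fixture(scope="session")
def source():
    return optics.LEDSource()


@pytest.fixture(scope="session")
def tissue():
    return optics.TissueOptics()


@pytest.fixture(scope="session")
def boundary():
    return thermal.ThermalBoundary()


@pytest.fixture(scope="session")
def coarse_grid():
    """Fast grid for behaviour (not accuracy) checks."""
    return thermal.build_grid(dr=0.2, dz=0.1)


@pytest.fixture(scope="session")
def full_duty_heat():
    return thermal.led_heat_power(
        thermal.electrical_input_power(1.0, 4.69, 0.30), 4.69
    )


@pytest.fixture(scope="session")
def default_trace(boundary, full_duty_heat):
    """One full-duty 60/90 cycle on the default grid (shared across tests)."""
    grid = thermal.build_grid()
    return thermal.simulate(
        grid, boundary, thermal.DutyCycleLoad(full_duty_heat), t_end=150.0, dt=0.1
    )


@pytest.fixture(scope="session")
def solver_rise_table(coarse_grid, boundary):
    """Rise-by-duty table from the PDE solver on the coarse grid."""
    df = thermal.peak_rise_by_duty(
        (0.25, 0.5, 0.75, 1.0), grid=coarse_grid, boundary=boundary, dt=0.2
    )
    return dict(zip(df["duty"], df["peak_rise_K"]))


@pytest.fixture(scope="session")
def guard():
    """Thermal guard on the cached default rise model."""
    return control.ThermalGuard(thermal_cap_K=2.0)
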