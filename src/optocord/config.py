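"""Validated run configuration for all modules.

The configuration is a flat registry of dotted keys, each with a default,
a provenance tag (``device`` for constants printed for the physical
device, ``model`` for artifact modelling defaults), and a validator.
A YAML file overrides any subset; unknown keys and out-of-range values
raise with the offending key path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import yaml

from . import control, optics, physio, policy, thermal

__all__ = ["RunConfig", "load_config", "ConfigError", "DEFAULT_LAYERS"]


class ConfigError(ValueError):
    """Configuration parse or validation failure."""


def _fraction(v: float) -> bool:
    return 0.0 <= float(v) <= 1.0


def _positive(v: float) -> bool:
    return float(v) > 0


def _nonneg(v: float) -> bool:
    return float(v) >= 0


def _ladder(v: Any) -> bool:
    return (
        isinstance(v, (list, tuple))
        and len(v) > 0
        and all(0.0 <= float(d) <= 1.0 for d in v)
        and list(v) == sorted(v)
    )


DEFAULT_LAYERS: list[dict[str, Any]] = [
    {"name": lay.name, "thickness_mm": lay.thickness, "k": lay.conductivity,
     "rho": lay.density, "c": lay.specific_heat,
     **({"k_radial": lay.conductivity_radial}
        if lay.conductivity_radial is not None else {})}
    for lay in thermal.default_stack()
]


def _layers_ok(v: Any) -> bool:
    if not isinstance(v, list) or not v:
        return False
    for item in v:
        if not isinstance(item, dict):
            return False
        if not {"name", "thickness_mm", "k", "rho", "c"} <= set(item):
            return False
    return True


# key -> (default, provenance, validator)
_SCHEMA: dict[str, tuple[Any, str, Callable[[Any], bool]]] = {
    "led.rho_mm": (0.508, "device", _positive),
    "led.H_mm": (0.150, "device", _positive),
    "led.full_power_mW": (4.69, "device", _positive),
    "led.divergence_deg": (154.0, "device", lambda v: 0 < float(v) < 180),
    "tissue.scattering_per_mm": (10.3, "device", _nonneg),
    "tissue.opsin_threshold_mW_mm2": (1.0, "device", _positive),
    "pwm.ladder": ([0.25, 0.50, 0.75, 1.00], "device", _ladder),
    "thermal.layers": (DEFAULT_LAYERS, "model", _layers_ok),
    "thermal.boundary.ambient_C": (25.0, "device", lambda v: True),
    "thermal.boundary.h_W_m2K": (27.0, "device", _nonneg),
    "thermal.boundary.emissivity": (0.8, "device", _fraction),
    "thermal.boundary.stefan_boltzmann": (5.67e-8, "device", _positive),
    "thermal.boundary.core_C": (37.0, "device", lambda v: True),
    "thermal.efficiency": (0.30, "model", lambda v: 0 < float(v) <= 1),
    "thermal.dt_s": (0.1, "model", _positive),
    "thermal.on_s": (60.0, "device", _positive),
    "thermal.off_s": (90.0, "device", _positive),
    "thermal.grid.radial_extent_mm": (4.0, "model", _positive),
    "thermal.grid.dr_mm": (0.1, "model", _positive),
    "thermal.grid.dz_mm": (0.05, "model", _positive),
    "thermal.source_radius_mm": (0.597, "model", _positive),
    "thermal.device_radius_mm": (1.75, "model", _positive),
    "sensor.R0_ohm": (1000.0, "model", _positive),
    "sensor.T0_C": (0.0, "model", lambda v: True),
    "sensor.alpha_per_K": (3.9e-3, "model", _positive),
    "physio.k_per_day": (0.15, "model", _nonneg),
    "physio.D50_mJ": (200.0, "model", _positive),
    "physio.r0": (0.05, "model", _fraction),
    "physio.A_max_mV": (8.0, "model", _positive),
    "physio.noise_sd_frac": (0.05, "model", _nonneg),
    "physio.theta_sigma": (0.5, "model", _nonneg),
    "physio.ref_k_per_day": (0.25, "model", _positive),
    "controller.start_duty": (0.5, "device", _fraction),
    "controller.gap_threshold": (0.15, "model", _positive),
    "controller.decision_period_days": (7, "device", lambda v: int(v) >= 1),
    "controller.sessions_per_day": (3, "device", lambda v: int(v) >= 1),
    "controller.session_length_s": (60.0, "device", _positive),
    "controller.thermal_cap_K": (2.0, "device", _positive),
    "controller.max_duty": (1.0, "model", _fraction),
    "controller.deescalate": (True, "model", lambda v: isinstance(v, bool)),
    "rl.gamma": (0.95, "model", _fraction),
    "rl.w_bbb": (1.0, "model", _nonneg),
    "rl.w_emg": (0.5, "model", _nonneg),
    "rl.w_thermal_penalty": (10.0, "model", _nonneg),
    "rl.episode_length": (4, "device", lambda v: int(v) >= 1),
    "rl.gap_bins": (5, "model", lambda v: int(v) >= 1),
    "rl.rise_bins": (3, "model", lambda v: int(v) >= 1),
}


def _flatten(tree: dict, prefix: str = "") -> dict[str, Any]:
    flat: dict[str, Any] = {}
    for key, val in tree.items():
        path = f"{prefix}{key}"
        # descend only where the schema has no leaf at this path
        if isinstance(val, dict) and path not in _SCHEMA:
            flat.update(_flatten(val, prefix=f"{path}."))
        else:
            flat[path] = val
    return flat


@dataclass
class RunConfig:
    """Merged, validated configuration for every module."""

    values: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = {k: v for k, (v, _, _) in _SCHEMA.items()}
        for key, val in self.values.items():
            if key not in _SCHEMA:
                raise ConfigError(f"unknown configuration key: {key}")
            merged[key] = val
        for key, val in merged.items():
            _, _, ok = _SCHEMA[key]
            try:
                valid = ok(val)
            except (TypeError, ValueError):
                valid = False
            if not valid:
                raise ConfigError(f"invalid value for {key}: {val!r}")
        self.values = merged

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def provenance(self) -> dict[str, str]:
        """Provenance tag per key: device constant vs modelling default."""
        return {k: tag for k, (_, tag, _) in _SCHEMA.items()}

    # -- domain-object builders ---------------------------------------------
    def led_source(self) -> optics.LEDSource:
        return optics.LEDSource(
            crown_radius_rho=self["led.rho_mm"],
            crown_height_H=self["led.H_mm"],
            divergence_angle=self["led.divergence_deg"],
            full_luminous_power_mW=self["led.full_power_mW"],
        )

    def tissue_optics(self) -> optics.TissueOptics:
        return optics.TissueOptics(
            scattering_S=self["tissue.scattering_per_mm"],
            opsin_threshold=self["tissue.opsin_threshold_mW_mm2"],
        )

    def duty_ladder(self) -> tuple[float, ...]:
        return tuple(self["pwm.ladder"])

    def layers(self) -> list[thermal.LayerSpec]:
        return [
            thermal.LayerSpec(
                name=item["name"],
                thickness=item["thickness_mm"],
                conductivity=item["k"],
                density=item["rho"],
                specific_heat=item["c"],
                conductivity_radial=item.get("k_radial"),
            )
            for item in self["thermal.layers"]
        ]

    def grid(self) -> thermal.Grid:
        return thermal.build_grid(
            self.layers(),
            radial_extent=self["thermal.grid.radial_extent_mm"],
            dr=self["thermal.grid.dr_mm"],
            dz=self["thermal.grid.dz_mm"],
            source_layer=self["thermal.layers"][1]["name"]
            if len(self["thermal.layers"]) > 1
            else self["thermal.layers"][0]["name"],
            source_radius=self["thermal.source_radius_mm"],
            device_radius=self["thermal.device_radius_mm"],
        )

    def boundary(self) -> thermal.ThermalBoundary:
        return thermal.ThermalBoundary(
            ambient_T=self["thermal.boundary.ambient_C"],
            convection_h=self["thermal.boundary.h_W_m2K"],
            emissivity=self["thermal.boundary.emissivity"],
            stefan_boltzmann=self["thermal.boundary.stefan_boltzmann"],
            core_T=self["thermal.boundary.core_C"],
        )

    def sensor_cal(self) -> thermal.SensorCal:
        return thermal.SensorCal(
            R0=self["sensor.R0_ohm"],
            T0=self["sensor.T0_C"],
            tcr_alpha=self["sensor.alpha_per_K"],
        )

    def recovery_params(self) -> physio.RecoveryParams:
        return physio.RecoveryParams(
            k=self["physio.k_per_day"],
            D50=self["physio.D50_mJ"],
            r0=self["physio.r0"],
            A_max=self["physio.A_max_mV"],
        )

    def controller_config(self) -> control.ControllerConfig:
        return control.ControllerConfig(
            duty_ladder=self.duty_ladder(),
            start_duty=self["controller.start_duty"],
            gap_threshold_delta=self["controller.gap_threshold"],
            decision_period_days=int(self["controller.decision_period_days"]),
            sessions_per_day=int(self["controller.sessions_per_day"]),
            session_length_s=self["controller.session_length_s"],
            thermal_cap_K=self["controller.thermal_cap_K"],
            max_duty=self["controller.max_duty"],
            deescalate=self["controller.deescalate"],
        )

    def mdp_config(self) -> policy.MDPConfig:
        return policy.MDPConfig(
            gamma=self["rl.gamma"],
            w_bbb=self["rl.w_bbb"],
            w_emg=self["rl.w_emg"],
            w_thermal_penalty=self["rl.w_thermal_penalty"],
            episode_length=int(self["rl.episode_length"]),
            action_set=(0.0,) + self.duty_ladder(),
            gap_bins=int(self["rl.gap_bins"]),
            rise_bins=int(self["rl.rise_bins"]),
        )


def load_config(path: str | None = None) -> RunConfig:
    """Load and validate a YAML configuration; missing keys get defaults."""
    if path is None:
        return RunConfig()
    try:
        with open(path) as fh:
            tree = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if tree is None:
        return RunConfig()
    if not isinstance(tree, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return RunConfig(_flatten(tree))
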