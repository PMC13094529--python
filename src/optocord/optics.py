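"""Spherical-crown light-propagation model for an implanted µ-LED array.

The emitting surface of the µ-LED array is idealised as a spherical cap of
radius ``rho`` and height ``H``; the spinal cord is a flat, uniform diffuser
illuminated from one side.  Three quantities follow in closed form:

* surface power density  ``I0 = P / (2 pi rho H)``  (cap lateral area),
* geometric attenuation with depth ``rho^2 / (z + rho)^2``,
* scattering loss ``1 / (S z + 1)`` with per-thickness scattering
  coefficient ``S``.

The effective (opsin-exciting) depth is the root of
``I(z) = I0 * rho^2 / ((S z + 1)(z + rho)^2) = threshold`` where the
channelrhodopsin-2 excitation threshold is 1 mW mm^-2.  All lengths are in
mm, powers in mW, densities in mW mm^-2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "LEDSource",
    "TissueOptics",
    "PWMSetting",
    "DepthProfile",
    "DEFAULT_DUTY_LADDER",
    "duty_scaled_power",
    "surface_power_density",
    "attenuation_geometric",
    "attenuation_full",
    "power_density_at_depth",
    "effective_depth",
    "effective_area",
    "depth_profile",
    "pwm_summary_table",
    "fit_scattering",
]

#: PWM duty ladder used throughout the device firmware model.
DEFAULT_DUTY_LADDER: tuple[float, ...] = (0.25, 0.50, 0.75, 1.00)


@dataclass(frozen=True)
class LEDSource:
    """Geometry and emission of the µ-LED array.

    Defaults are the device constants: a 470 nm array whose emitting
    surface is a spherical crown of radius 0.508 mm and height 0.150 mm,
    emitting 4.69 mW at 100% PWM duty.
    """

    footprint_length: float = 0.600  # mm
    footprint_width: float = 0.200  # mm
    crown_radius_rho: float = 0.508  # mm
    crown_height_H: float = 0.150  # mm
    divergence_angle: float = 154.0  # degrees; stated device property,
    # not used by the crown formulas
    wavelength_nm: float = 470.0
    full_luminous_power_mW: float = 4.69

    def __post_init__(self) -> None:
        for name in (
            "footprint_length",
            "footprint_width",
            "crown_radius_rho",
            "crown_height_H",
            "full_luminous_power_mW",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 < self.divergence_angle < 180:
            raise ValueError("divergence_angle must lie in (0, 180) degrees")

    @property
    def crown_area_mm2(self) -> float:
        """Lateral area of the spherical crown, 2*pi*rho*H."""
        return 2.0 * math.pi * self.crown_radius_rho * self.crown_height_H


@dataclass(frozen=True)
class TissueOptics:
    """Optical properties of cord tissue at 470 nm."""

    scattering_S: float = 10.3  # per mm
    opsin_threshold: float = 1.0  # mW mm^-2, hChR2 excitation threshold

    def __post_init__(self) -> None:
        if self.scattering_S < 0:
            raise ValueError("scattering_S must be >= 0")
        if self.opsin_threshold <= 0:
            raise ValueError("opsin_threshold must be > 0")


@dataclass(frozen=True)
class PWMSetting:
    """A PWM duty-cycle setting; mean luminous power scales with duty."""

    duty: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.duty <= 1.0:
            raise ValueError(f"duty must lie in [0, 1], got {self.duty}")


@dataclass(frozen=True)
class DepthProfile:
    """Power density versus depth, with the opsin-effective depth and area."""

    depths_z: np.ndarray  # mm, ordered
    densities_I: np.ndarray  # mW mm^-2
    effective_depth_zmax: float  # mm; 0.0 when sub-threshold
    effective_area_A: float  # mm^2, model-default area
    above_threshold: bool  # False when the surface density never reaches it


def duty_scaled_power(source: LEDSource, pwm: PWMSetting | float) -> float:
    """Mean luminous power (mW) at a PWM duty: duty x full power."""
    duty = pwm.duty if isinstance(pwm, PWMSetting) else PWMSetting(float(pwm)).duty
    return duty * source.full_luminous_power_mW


def surface_power_density(source: LEDSource, power_mW: float) -> float:
    """Surface optical power density I0 = P / (2 pi rho H), in mW mm^-2."""
    if power_mW < 0:
        raise ValueError("power must be >= 0")
    return power_mW / source.crown_area_mm2


def attenuation_geometric(z, source: LEDSource):
    """Geometric intensity attenuation rho^2 / (z + rho)^2 at depth z (mm)."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth z must be >= 0")
    rho = source.crown_radius_rho
    out = rho**2 / (z + rho) ** 2
    return float(out) if out.ndim == 0 else out


def attenuation_full(z, source: LEDSource, optics: TissueOptics):
    """Combined geometric and scattering attenuation rho^2/((Sz+1)(z+rho)^2)."""
    z = np.asarray(z, dtype=float)
    geo = attenuation_geometric(z, source)
    out = geo / (optics.scattering_S * z + 1.0)
    return float(out) if np.ndim(out) == 0 else out


def power_density_at_depth(
    z, source: LEDSource, optics: TissueOptics, power_mW: float
):
    """I(z) = surface density x full attenuation, in mW mm^-2."""
    return attenuation_full(z, source, optics) * surface_power_density(
        source, power_mW
    )


def effective_depth(
    source: LEDSource,
    optics: TissueOptics,
    power_mW: float,
    *,
    z_upper: float = 10.0,
    xtol: float = 1e-9,
) -> tuple[float, bool]:
    """Depth (mm) at which I(z) falls to the opsin threshold.

    Returns ``(z_max, above_threshold)``.  When the surface density does
    not exceed the threshold the depth is 0.0 and the flag is False — the
    setting delivers no effective dose but is not an error, so the
    controller can treat it as "dose = 0".

    I(z) is continuous and strictly decreasing, so the root is unique;
    Brent's method on [0, z_upper] resolves it well below 1e-6 mm.
    """
    i0 = surface_power_density(source, power_mW)
    if i0 <= optics.opsin_threshold:
        return 0.0, False

    def gap(z: float) -> float:
        return attenuation_full(z, source, optics) * i0 - optics.opsin_threshold

    if gap(z_upper) > 0:
        raise ValueError(f"I({z_upper} mm) still above threshold; enlarge z_upper")
    z = brentq(gap, 0.0, z_upper, xtol=xtol)
    return float(z), True


def effective_area(zmax: float, source: LEDSource) -> float:
    """Model-default effective illuminated area pi (rho + zmax)^2, mm^2.

    The growing-cap default assumes the illuminated front expands radially
    with depth at the same rate it penetrates.  Alternative area models can
    be supplied where a table is built (see :func:`pwm_summary_table`);
    outputs are labelled model-default.
    """
    if zmax < 0:
        raise ValueError("zmax must be >= 0")
    return math.pi * (source.crown_radius_rho + zmax) ** 2


def depth_profile(
    source: LEDSource,
    optics: TissueOptics,
    power_mW: float,
    *,
    z_grid: np.ndarray | None = None,
    area_model: Callable[[float, LEDSource], float] = effective_area,
) -> DepthProfile:
    """Full I(z) profile plus effective depth/area for one power level."""
    zmax, ok = effective_depth(source, optics, power_mW)
    if z_grid is None:
        z_grid = np.linspace(0.0, max(2.0 * zmax, 0.5), 201)
    dens = power_density_at_depth(z_grid, source, optics, power_mW)
    return DepthProfile(
        depths_z=np.asarray(z_grid, dtype=float),
        densities_I=np.asarray(dens, dtype=float),
        effective_depth_zmax=zmax,
        effective_area_A=area_model(zmax, source),
        above_threshold=ok,
    )


def pwm_summary_table(
    source: LEDSource,
    optics: TissueOptics,
    duty_ladder: Sequence[float] = DEFAULT_DUTY_LADDER,
    *,
    area_model: Callable[[float, LEDSource], float] = effective_area,
) -> pd.DataFrame:
    """One row per PWM duty: power, surface density, effective depth/area.

    Column names are the CSV schema used by the ``optics table`` command.
    """
    if len(duty_ladder) == 0:
        raise ValueError("duty ladder must be non-empty")
    rows = []
    for duty in duty_ladder:
        p = duty_scaled_power(source, PWMSetting(duty))
        zmax, _ = effective_depth(source, optics, p)
        rows.append(
            {
                "duty": duty,
                "luminous_power_mW": p,
                "surface_density_mW_mm2": surface_power_density(source, p),
                "effective_depth_mm": zmax,
                "effective_area_mm2": area_model(zmax, source),
            }
        )
    return pd.DataFrame(rows)


def fit_scattering(
    depths_z: np.ndarray,
    densities_I: np.ndarray,
    source: LEDSource,
    power_mW: float,
    *,
    s0: float = 5.0,
) -> float:
    """Least-squares estimate of the scattering coefficient S from an
    I(z) profile measured (or simulated) at known power.

    The model is linear in S after rearrangement, but a direct scalar
    least-squares fit keeps it robust to noisy profiles too.
    """
    from scipy.optimize import least_squares

    z = np.asarray(depths_z, dtype=float)
    i_obs = np.asarray(densities_I, dtype=float)

    def resid(params):
        s = params[0]
        opt = TissueOptics(scattering_S=max(s, 0.0))
        return power_density_at_depth(z, source, opt, power_mW) - i_obs

    sol = least_squares(resid, x0=[s0], bounds=([0.0], [np.inf]))
    return float(sol.x[0])
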