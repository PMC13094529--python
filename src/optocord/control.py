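"""Customized closed-loop illumination strategy.

The device treats daily (three 60 s sessions at the current PWM duty) and
re-evaluates weekly: evoked EMG is measured, compared with the
standardized reference trajectory, and the duty is stepped up one ladder
rung when the relative gap exceeds a threshold — "turn up the light if
there is a significant gap" — with a hard limitation: the duty never
exceeds the ladder maximum and never violates the 2 K thermal cap, which
a real-time guard enforces on every session.  De-escalation when the
subject runs ahead of the standard is symmetric and enabled by default
(a documented extension; only escalation is strictly required).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import physio
from .physio import RecoveryParams, RecoveryState

__all__ = [
    "ControllerConfig",
    "GuardDecision",
    "ThermalGuard",
    "emg_gap",
    "adjust_duty",
    "run_closed_loop",
    "DEFAULT_RISE_AT_FULL_K",
]

#: Peak cord rise at 100% duty computed by the bioheat solver at its
#: default calibration (thermal.peak_rise_by_duty); cached here so cheap
#: consumers need not re-run the PDE.  The perturbation PDE is linear, so
#: the rise scales proportionally with heat power, hence with duty.
DEFAULT_RISE_AT_FULL_K = 1.171


@dataclass(frozen=True)
class ControllerConfig:
    """Duty ladder, gap threshold, cadence, and safety cap."""

    duty_ladder: tuple[float, ...] = (0.25, 0.50, 0.75, 1.00)
    start_duty: float = 0.50
    gap_threshold_delta: float = 0.15
    decision_period_days: int = 7
    sessions_per_day: int = 3
    session_length_s: float = 60.0
    thermal_cap_K: float = 2.0
    max_duty: float = 1.0
    deescalate: bool = True

    def __post_init__(self) -> None:
        if list(self.duty_ladder) != sorted(self.duty_ladder):
            raise ValueError("duty ladder must be sorted ascending")
        if self.start_duty not in self.duty_ladder:
            raise ValueError("start_duty must be a ladder value")
        if self.thermal_cap_K <= 0:
            raise ValueError("thermal_cap_K must be > 0")


class GuardDecision(NamedTuple):
    duty: float  # the duty actually allowed to run
    predicted_rise_K: float  # rise predicted for that duty
    downgraded: bool  # True when the requested duty was unsafe


class ThermalGuard:
    """Real-time thermal safety check over a cached rise-by-duty table.

    ``rise_table`` maps duty -> predicted peak cord rise (K).  Build it
    from the bioheat solver with :meth:`from_thermal`, or rely on the
    linearity of the perturbation PDE via the cached default.
    """

    def __init__(
        self,
        rise_table: Mapping[float, float] | None = None,
        *,
        rise_at_full_K: float = DEFAULT_RISE_AT_FULL_K,
        thermal_cap_K: float = 2.0,
    ) -> None:
        self.thermal_cap_K = thermal_cap_K
        self._table = dict(rise_table) if rise_table is not None else None
        self._rise_at_full = rise_at_full_K

    @classmethod
    def from_thermal(
        cls, duty_ladder: Sequence[float], thermal_cap_K: float = 2.0, **kwargs
    ) -> "ThermalGuard":
        """Compute the rise table with the bioheat solver (one PDE run per
        duty) and cache it."""
        from . import thermal

        df = thermal.peak_rise_by_duty(list(duty_ladder) + [1.0], **kwargs)
        table = dict(zip(df["duty"], df["peak_rise_K"]))
        return cls(
            table, rise_at_full_K=table[1.0], thermal_cap_K=thermal_cap_K
        )

    def predicted_rise(self, duty: float) -> float:
        if self._table is not None and duty in self._table:
            return self._table[duty]
        return duty * self._rise_at_full

    def check(self, duty: float, ladder: Sequence[float]) -> GuardDecision:
        """Allow the duty, or downgrade to the largest safe ladder duty.

        When no ladder duty is safe the session is skipped (duty 0).
        """
        if not 0.0 <= duty <= 1.0:
            raise ValueError("duty must lie in [0, 1]")
        rise = self.predicted_rise(duty)
        if rise <= self.thermal_cap_K:
            return GuardDecision(duty, rise, False)
        for cand in sorted(ladder, reverse=True):
            if cand < duty and self.predicted_rise(cand) <= self.thermal_cap_K:
                return GuardDecision(cand, self.predicted_rise(cand), True)
        return GuardDecision(0.0, 0.0, True)


def emg_gap(measured_mV: float, reference_mV: float) -> float:
    """Relative shortfall (reference - measured) / reference.

    Positive means the subject is below the standardized trajectory.
    """
    if reference_mV <= 0:
        raise ValueError("reference must be > 0")
    return (reference_mV - measured_mV) / reference_mV


def adjust_duty(current: float, gap: float, config: ControllerConfig) -> float:
    """One weekly ladder adjustment from the EMG gap.

    gap > delta: one rung up (clamped at max_duty); gap < -delta and
    de-escalation enabled: one rung down; otherwise unchanged.
    """
    ladder = [d for d in config.duty_ladder if d <= config.max_duty]
    if current not in ladder:
        raise ValueError(f"current duty {current} not in ladder {ladder}")
    i = ladder.index(current)
    if gap > config.gap_threshold_delta:
        i = min(i + 1, len(ladder) - 1)
    elif config.deescalate and gap < -config.gap_threshold_delta:
        i = max(i - 1, 0)
    return ladder[i]


def run_closed_loop(
    subject: RecoveryParams,
    config: ControllerConfig | None = None,
    seed: int = 0,
    days: int = 28,
    *,
    guard: ThermalGuard | None = None,
    noise_sd_frac: float = 0.05,
    full_power_mW: float = 4.69,
) -> pd.DataFrame:
    """Simulate one subject's 28-day closed-loop treatment course.

    Daily: three thermal-guarded sessions at the current duty accumulate
    dose and advance the latent recovery.  On the last day of each
    decision period: measure evoked EMG (noisy, seeded), compare with the
    standardized reference, and adjust the duty for the next period.

    Returns the per-day loop log with columns subject-free: day, duty,
    dose_mJ, state, emg_mV, reference_mV, gap, predicted_rise_K,
    guard_triggered.
    """
    config = config if config is not None else ControllerConfig()
    guard = guard if guard is not None else ThermalGuard(
        thermal_cap_K=config.thermal_cap_K
    )
    rng = np.random.default_rng(seed)
    state = RecoveryState(subject.r0, day=0)
    duty = config.start_duty
    rows = []
    emg, ref, gap = np.nan, np.nan, np.nan
    for day in range(1, days + 1):
        decision = guard.check(duty, config.duty_ladder)
        dose = physio.daily_dose_mJ(
            decision.duty,
            full_power_mW=full_power_mW,
            sessions_per_day=config.sessions_per_day,
            session_length_s=config.session_length_s,
        )
        state = physio.recovery_step(state, dose, subject)
        is_decision_day = day % config.decision_period_days == 0
        emg = ref = gap = np.nan
        if is_decision_day:
            trace = physio.evoked_emg(
                state,
                noise_sd=noise_sd_frac * subject.A_max,
                seed=int(rng.integers(2**31 - 1)),
                params=subject,
            )
            emg = physio.emg_metric(trace)
            ref = physio.standard_reference(day)
            gap = emg_gap(emg, ref)
        rows.append(
            {
                "day": day,
                "duty": decision.duty,
                "dose_mJ": dose,
                "state": state.value,
                "emg_mV": emg,
                "reference_mV": ref,
                "gap": gap,
                "predicted_rise_K": decision.predicted_rise_K,
                "guard_triggered": decision.downgraded,
            }
        )
        if is_decision_day:
            duty = adjust_duty(duty, gap, config)
    return pd.DataFrame(rows)
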