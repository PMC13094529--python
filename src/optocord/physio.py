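"""Synthetic physiology for the closed loop: recovery dynamics, evoked EMG.

The latent variable is a recovery fraction r in [0, 1] (0 = complete
transection, 1 = the standardized best-recovery condition).  Daily
illumination dose drives logistic regrowth,

    dr/dt = k * theta * sigma(dose) * r (1 - r),
    sigma(dose) = dose / (dose + D50),

where k is the reference recovery rate (per day), D50 the half-saturating
daily dose (mJ), and theta a per-subject responsiveness drawn log-normally
to emulate inter-animal variability.  The day update uses the exact
logistic solution, so trajectories match the closed form and stay in
[0, 1] for any step.

Stimulation-evoked EMG is modelled as a train of compound-muscle-action-
potential-shaped transients (Gaussian-windowed biphasic waves) whose
peak-to-peak amplitude is A_max * r, plus additive Gaussian measurement
noise; the EMG feature extracted by the device is the mean post-stimulus
peak-to-peak amplitude.  The standardized reference trajectory is the
noiseless metric of the best-recovery parameter set, and a BBB-like proxy
(0-21, half-point resolution) maps r linearly for the policy module's
reward.  These constructs link dose to feedback for the controller and RL
environments; they do not claim biological fidelity beyond monotone,
saturating recovery with measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "StimPattern",
    "RecoveryState",
    "RecoveryParams",
    "EMGTrace",
    "REFERENCE_PARAMS",
    "recovery_step",
    "recovery_closed_form",
    "evoked_emg",
    "emg_metric",
    "standard_reference",
    "bbb_proxy",
    "daily_dose_mJ",
    "draw_subject",
    "generate_cohort",
    "fit_recovery_params",
]


@dataclass(frozen=True)
class StimPattern:
    """Intermittent, rhythmic electrical stimulation used to evoke EMG."""

    pulse_amplitude_mA: float = 1.0
    pulse_width_ms: float = 0.2
    burst_rate_Hz: float = 1.0  # stimulus repetition rate
    burst_count: int = 5
    inter_burst_gap_s: float = 1.0

    def __post_init__(self) -> None:
        if min(
            self.pulse_amplitude_mA,
            self.pulse_width_ms,
            self.burst_rate_Hz,
            self.inter_burst_gap_s,
        ) <= 0 or self.burst_count < 1:
            raise ValueError("all stimulation-pattern fields must be positive")

    @property
    def onsets_s(self) -> np.ndarray:
        """Stimulus onset times within one recording."""
        return 0.05 + np.arange(self.burst_count) * self.inter_burst_gap_s


@dataclass(frozen=True)
class RecoveryState:
    """Latent recovery fraction on a given post-injury day."""

    value: float
    day: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("recovery value must lie in [0, 1]")


@dataclass(frozen=True)
class RecoveryParams:
    """Dose-response parameters of one subject.

    k: recovery rate at saturating dose (per day); D50: half-saturating
    daily dose (mJ); theta: subject responsiveness multiplier; r0: initial
    recovery fraction; baseline_rate: dose-independent (spontaneous)
    recovery rate, zero by default for a complete transection; A_max:
    sham-level peak-to-peak CMAP amplitude (mV).
    """

    k: float = 0.15
    D50: float = 200.0
    theta: float = 1.0
    r0: float = 0.05
    baseline_rate: float = 0.0
    A_max: float = 8.0

    def __post_init__(self) -> None:
        if self.k < 0 or self.D50 <= 0 or self.theta < 0 or self.A_max <= 0:
            raise ValueError("invalid recovery parameters")
        if not 0.0 <= self.r0 <= 1.0:
            raise ValueError("r0 must lie in [0, 1]")


#: Parameters of the standardized (best-recovery) reference subject: a
#: fully responsive animal under saturating dose.
REFERENCE_PARAMS = RecoveryParams(k=0.25, theta=1.0, r0=0.05)


@dataclass(frozen=True)
class EMGTrace:
    """One evoked-EMG recording."""

    sample_rate: float  # Hz
    samples: np.ndarray  # mV
    stimulus_onsets: np.ndarray  # s

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


def _growth_rate(dose_mJ: float, params: RecoveryParams) -> float:
    if dose_mJ < 0:
        raise ValueError("dose must be >= 0")
    sigma = dose_mJ / (dose_mJ + params.D50)
    return params.theta * (params.k * sigma + params.baseline_rate)


def recovery_step(
    state: RecoveryState, daily_dose_mJ: float, params: RecoveryParams
) -> RecoveryState:
    """Advance the latent recovery by one day under the given dose.

    Uses the exact logistic update r' = r e^g / (1 - r + r e^g) with
    g = theta (k sigma(dose) + baseline), so repeated steps reproduce the
    closed-form logistic trajectory exactly.
    """
    g = _growth_rate(daily_dose_mJ, params)
    r = state.value
    if r in (0.0, 1.0) or g == 0.0:
        return RecoveryState(r, state.day + 1)
    eg = math.exp(g)
    return RecoveryState(r * eg / (1.0 - r + r * eg), state.day + 1)


def recovery_closed_form(t_days, r0: float, g: float):
    """Closed-form logistic r(t) = r0 e^{gt} / (1 - r0 + r0 e^{gt})."""
    t = np.asarray(t_days, dtype=float)
    egt = np.exp(g * t)
    out = r0 * egt / (1.0 - r0 + r0 * egt)
    return float(out) if out.ndim == 0 else out


def _cmap_template(sample_rate: float, duration_s: float = 0.040) -> np.ndarray:
    """Biphasic Gaussian-windowed wave, peak-to-peak normalised to 1.

    Latency 5 ms, envelope width 3 ms, 120 Hz carrier — CMAP-like shape;
    normalisation is on the sampled grid so the amplitude contract
    (p2p = A_max * r, noiseless) is exact by construction.
    """
    t = np.arange(int(round(duration_s * sample_rate))) / sample_rate
    lat, tau, f = 0.005, 0.003, 120.0
    w = np.exp(-0.5 * ((t - lat - 2 * tau) / tau) ** 2) * np.sin(
        2 * np.pi * f * (t - lat)
    )
    p2p = w.max() - w.min()
    return w / p2p


def evoked_emg(
    state: RecoveryState,
    stim: StimPattern | None = None,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    *,
    params: RecoveryParams | None = None,
    sample_rate: float = 2000.0,
) -> EMGTrace:
    """Synthesize one stimulation-evoked EMG recording.

    Each stimulus elicits a CMAP-shaped transient with peak-to-peak
    amplitude ``A_max * state.value``; Gaussian noise of SD ``noise_sd``
    (mV) is added throughout.  Deterministic for a given seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    stim = stim if stim is not None else StimPattern()
    params = params if params is not None else RecoveryParams()
    onsets = stim.onsets_s
    duration = onsets[-1] + 0.3
    n = int(round(duration * sample_rate))
    samples = np.zeros(n)
    template = _cmap_template(sample_rate) * params.A_max * state.value
    for onset in onsets:
        i0 = int(round(onset * sample_rate))
        seg = min(template.size, n - i0)
        samples[i0 : i0 + seg] += template[:seg]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd, size=n)
    return EMGTrace(sample_rate=sample_rate, samples=samples, stimulus_onsets=onsets)


def emg_metric(trace: EMGTrace, window: tuple[float, float] = (0.0, 0.040)) -> float:
    """Mean post-stimulus peak-to-peak amplitude (mV) across stimuli."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty metric window")
    p2ps = []
    for onset in trace.stimulus_onsets:
        i0 = int(round((onset + lo) * trace.sample_rate))
        i1 = int(round((onset + hi) * trace.sample_rate))
        i0, i1 = max(i0, 0), min(i1, trace.samples.size)
        if i1 <= i0:
            raise ValueError("metric window lies outside the trace")
        seg = trace.samples[i0:i1]
        p2ps.append(seg.max() - seg.min())
    return float(np.mean(p2ps))


def standard_reference(day: int, params: RecoveryParams = REFERENCE_PARAMS) -> float:
    """Standardized EMG metric (mV) of the reference subject on a given day.

    The reference is the noiseless metric of the best-recovery parameter
    set under saturating dose (sigma = 1); non-decreasing in day and
    asymptoting at the sham amplitude A_max.
    """
    if day < 0:
        raise ValueError("day must be >= 0")
    g = params.theta * (params.k + params.baseline_rate)
    return params.A_max * float(recovery_closed_form(day, params.r0, g))


def bbb_proxy(state: RecoveryState | float) -> float:
    """BBB-like locomotor proxy: 21 * r, rounded to the half point."""
    r = state.value if isinstance(state, RecoveryState) else float(state)
    if not 0.0 <= r <= 1.0:
        raise ValueError("recovery fraction must lie in [0, 1]")
    return round(21.0 * r * 2.0) / 2.0


def daily_dose_mJ(
    duty: float,
    *,
    full_power_mW: float = 4.69,
    sessions_per_day: int = 3,
    session_length_s: float = 60.0,
    effective: bool = True,
) -> float:
    """Daily illumination dose: sessions x duty x full power x length.

    With ``effective=True``, a duty whose surface power density is below
    the opsin-excitation threshold contributes zero dose (the light never
    excites the transplanted cells).
    """
    if effective:
        from . import optics

        src = optics.LEDSource(full_luminous_power_mW=full_power_mW)
        p = optics.duty_scaled_power(src, duty)
        if optics.surface_power_density(src, p) <= optics.TissueOptics().opsin_threshold:
            return 0.0
    return sessions_per_day * duty * full_power_mW * session_length_s


def draw_subject(
    rng: np.random.Generator,
    base: RecoveryParams | None = None,
    *,
    theta_sigma: float = 0.5,
) -> RecoveryParams:
    """One synthetic subject: responsiveness theta scaled LogNormal(0, sigma).

    The draw multiplies the base theta, so a low-responder cohort is set
    up by lowering the base responsiveness.
    """
    base = base if base is not None else RecoveryParams()
    return replace(
        base, theta=base.theta * float(rng.lognormal(mean=0.0, sigma=theta_sigma))
    )


def generate_cohort(
    n_subjects: int,
    seed: int,
    *,
    days: int = 28,
    duty: float = 0.5,
    base: RecoveryParams | None = None,
    noise_sd_frac: float = 0.05,
    sessions_per_day: int = 3,
    session_length_s: float = 60.0,
) -> pd.DataFrame:
    """Simulate a cohort under a fixed PWM duty with daily EMG readout.

    Columns: subject, day, dose_mJ, state, emg_metric_mV, bbb_proxy.
    """
    rng = np.random.default_rng(seed)
    base = base if base is not None else RecoveryParams()
    rows = []
    for s in range(n_subjects):
        params = draw_subject(rng, base)
        state = RecoveryState(params.r0, day=0)
        dose = daily_dose_mJ(
            duty,
            sessions_per_day=sessions_per_day,
            session_length_s=session_length_s,
        )
        for day in range(days + 1):
            trace = evoked_emg(
                state,
                noise_sd=noise_sd_frac * params.A_max,
                seed=int(rng.integers(2**31 - 1)),
                params=params,
            )
            rows.append(
                {
                    "subject": s,
                    "day": day,
                    "dose_mJ": dose if day > 0 else 0.0,
                    "state": state.value,
                    "emg_metric_mV": emg_metric(trace),
                    "bbb_proxy": bbb_proxy(state),
                }
            )
            state = recovery_step(state, dose, params)
    return pd.DataFrame(rows)


def generate_metric_courses(
    seed: int,
    *,
    n_subjects: int = 10,
    days: int = 28,
    duties: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0),
    base: RecoveryParams | None = None,
    noise_sd_frac: float = 0.05,
) -> pd.DataFrame:
    """Noisy daily EMG-metric courses for dose-response calibration.

    Subjects are assigned duties cycling through ``duties`` so the dose
    varies across the cohort (at a single dose, k and D50 enter only
    through their product with sigma and cannot be separated).  Noise is
    additive on the metric, emulating an unbiased amplitude readout.
    """
    rng = np.random.default_rng(seed)
    base = base if base is not None else RecoveryParams()
    rows = []
    for s in range(n_subjects):
        duty = duties[s % len(duties)]
        dose = daily_dose_mJ(duty)
        state = RecoveryState(base.r0, day=0)
        for day in range(days + 1):
            noisy = base.A_max * state.value + rng.normal(
                0.0, noise_sd_frac * base.A_max
            )
            rows.append(
                {
                    "subject": s,
                    "day": day,
                    "dose_mJ": dose if day > 0 else 0.0,
                    "emg_metric_mV": noisy,
                }
            )
            state = recovery_step(state, dose, base)
    return pd.DataFrame(rows)


def fit_recovery_params(
    courses: pd.DataFrame,
    *,
    base: RecoveryParams | None = None,
    k0: float = 0.05,
    d50_0: float = 500.0,
) -> tuple[float, float]:
    """Least-squares recovery of (k, D50) from noisy EMG courses.

    ``courses`` needs columns subject, day, dose_mJ, emg_metric_mV; doses
    must vary across subjects or days, otherwise k and D50 are confounded
    (only k * sigma(dose) is identifiable at a single dose).  r0, A_max
    and theta are taken as known (the calibration setting).
    """
    from scipy.optimize import least_squares

    base = base if base is not None else RecoveryParams()

    def predict(k: float, d50: float) -> np.ndarray:
        preds = []
        for _, grp in courses.groupby("subject", sort=True):
            grp = grp.sort_values("day")
            r = base.r0
            for _, row in grp.iterrows():
                if row["day"] > 0:
                    sigma = row["dose_mJ"] / (row["dose_mJ"] + d50)
                    g = base.theta * (k * sigma + base.baseline_rate)
                    eg = math.exp(g)
                    r = r * eg / (1.0 - r + r * eg)
                preds.append(base.A_max * r)
        return np.asarray(preds)

    obs = (
        courses.sort_values(["subject", "day"])["emg_metric_mV"].to_numpy(dtype=float)
    )

    def resid(x):
        return predict(x[0], x[1]) - obs

    sol = least_squares(
        resid, x0=[k0, d50_0], bounds=([1e-6, 1e-3], [5.0, 1e5])
    )
    return float(sol.x[0]), float(sol.x[1])
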