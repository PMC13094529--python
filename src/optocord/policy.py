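"""Treatment-policy environment and tabular learner over the digital twin.

The treatment course is cast as a finite-horizon decision process
M = <S, A, T, O, R, gamma>: one episode is a 28-day course with four
weekly decisions; the action is the PWM duty for the coming week (the
ladder plus "off"); the observation is the discretized EMG gap, recent
peak temperature rise, and week index — the temperature/EMG feedback the
implanted device actually sees, making the real-world problem partially
observable while the twin exposes the full state.  The reward combines
the behavioural proxy gain, the EMG shortfall, and a thermal penalty:

    r = w_bbb * dBBB + w_emg * (-gap) - w_thermal * max(0, rise - cap).

The return is the discounted sum J = sum_t gamma^t r_t.  The baseline
learner is tabular Q-learning with an epsilon-greedy exploration decay —
a deliberately simple, reproducible reference policy-optimiser for the
twin, not a claim about in vivo optimality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import physio
from .control import ControllerConfig, ThermalGuard, emg_gap
from .physio import RecoveryParams, RecoveryState

__all__ = [
    "MDPConfig",
    "Observation",
    "EpisodeLog",
    "TreatmentEnv",
    "discounted_return",
    "q_learning_train",
    "greedy_policy",
    "evaluate_policy",
    "fixed_duty_policy",
]


@dataclass(frozen=True)
class MDPConfig:
    """Discount, reward weights, horizon, and action set."""

    gamma: float = 0.95
    w_bbb: float = 1.0
    w_emg: float = 0.5
    w_thermal_penalty: float = 10.0
    episode_length: int = 4  # weekly decisions over a 28-day course
    action_set: tuple[float, ...] = (0.0, 0.25, 0.50, 0.75, 1.00)
    gap_bins: int = 5  # gap discretized over [-1, 1]
    rise_bins: int = 3  # rise discretized over [0, thermal_cap]

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.episode_length < 1:
            raise ValueError("episode_length must be >= 1")
        if len(self.action_set) == 0:
            raise ValueError("action set must be non-empty")


class Observation(NamedTuple):
    """What the device observes between decisions."""

    gap: float  # EMG shortfall vs the standardized reference
    peak_rise_K: float  # largest predicted rise over the past week
    week: int


class EpisodeLog(NamedTuple):
    """Per-step records and the discounted return of one episode."""

    observations: list[Observation]
    actions: list[float]
    rewards: list[float]
    J: float


def discounted_return(rewards: Sequence[float], gamma: float) -> float:
    """J = sum_t gamma^t r_t, t starting at 0."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    return float(sum(r * gamma**t for t, r in enumerate(rewards)))


class TreatmentEnv:
    """Weekly-decision treatment environment over the physiology twin.

    Each step runs one decision period (7 days x 3 sessions) at the chosen
    duty through the thermal guard and the recovery dynamics, then returns
    the new observation, the reward, and the done flag.  Deterministic for
    a given reset seed.
    """

    def __init__(
        self,
        subject: RecoveryParams | None = None,
        mdp: MDPConfig | None = None,
        controller: ControllerConfig | None = None,
        guard: ThermalGuard | None = None,
        *,
        noise_sd_frac: float = 0.05,
        subject_theta_sigma: float | None = None,
    ) -> None:
        self.base_subject = subject if subject is not None else RecoveryParams()
        self.mdp = mdp if mdp is not None else MDPConfig()
        self.controller = controller if controller is not None else ControllerConfig()
        self.guard = guard if guard is not None else ThermalGuard(
            thermal_cap_K=self.controller.thermal_cap_K
        )
        self.noise_sd_frac = noise_sd_frac
        self.subject_theta_sigma = subject_theta_sigma
        self._state: RecoveryState | None = None

    # -- gym-style contract ------------------------------------------------
    def reset(self, seed: int = 0) -> Observation:
        self._rng = np.random.default_rng(seed)
        self.subject = (
            physio.draw_subject(
                self._rng, self.base_subject, theta_sigma=self.subject_theta_sigma
            )
            if self.subject_theta_sigma is not None
            else self.base_subject
        )
        self._state = RecoveryState(self.subject.r0, day=0)
        self._week = 0
        self._bbb = physio.bbb_proxy(self._state)
        obs = Observation(gap=self._measure_gap(day=0), peak_rise_K=0.0, week=0)
        self._last_obs = obs
        return obs

    def _measure_gap(self, day: int) -> float:
        ref = physio.standard_reference(max(day, 0)) if day > 0 else None
        if day == 0:
            # pre-treatment gap against the day-0 reference
            ref = physio.standard_reference(0)
        trace = physio.evoked_emg(
            self._state,
            noise_sd=self.noise_sd_frac * self.subject.A_max,
            seed=int(self._rng.integers(2**31 - 1)),
            params=self.subject,
        )
        return emg_gap(physio.emg_metric(trace), ref)

    def step(self, action: float) -> tuple[Observation, float, bool]:
        if self._state is None:
            raise RuntimeError("call reset() before step()")
        if action not in self.mdp.action_set:
            raise ValueError(f"action {action} not in {self.mdp.action_set}")
        if self._week >= self.mdp.episode_length:
            raise RuntimeError("episode is done; call reset()")

        cfg = self.controller
        peak_rise = 0.0
        for _ in range(cfg.decision_period_days):
            if action == 0.0:
                executed, rise = 0.0, 0.0
            else:
                decision = self.guard.check(action, cfg.duty_ladder)
                executed, rise = decision.duty, decision.predicted_rise_K
            dose = physio.daily_dose_mJ(
                executed,
                sessions_per_day=cfg.sessions_per_day,
                session_length_s=cfg.session_length_s,
            )
            self._state = physio.recovery_step(self._state, dose, self.subject)
            peak_rise = max(peak_rise, rise)

        self._week += 1
        day = self._week * cfg.decision_period_days
        gap = self._measure_gap(day)
        bbb = physio.bbb_proxy(self._state)
        reward = (
            self.mdp.w_bbb * (bbb - self._bbb)
            + self.mdp.w_emg * (-gap)
            - self.mdp.w_thermal_penalty
            * max(0.0, peak_rise - cfg.thermal_cap_K)
        )
        self._bbb = bbb
        obs = Observation(gap=gap, peak_rise_K=peak_rise, week=self._week)
        self._last_obs = obs
        return obs, float(reward), self._week >= self.mdp.episode_length

    # -- observation discretization -----------------------------------------
    def encode(self, obs: Observation) -> tuple[int, int, int]:
        """Bin an observation for the tabular learner."""
        g = int(np.clip((obs.gap + 1.0) / 2.0 * self.mdp.gap_bins, 0,
                        self.mdp.gap_bins - 1))
        r = int(np.clip(
            obs.peak_rise_K / self.controller.thermal_cap_K * self.mdp.rise_bins,
            0, self.mdp.rise_bins - 1,
        ))
        return (g, r, min(obs.week, self.mdp.episode_length - 1))


def q_learning_train(
    env,
    episodes: int = 500,
    *,
    alpha: float = 0.2,
    gamma: float | None = None,
    eps_start: float = 1.0,
    eps_end: float = 0.05,
    seed: int = 0,
) -> dict[tuple, np.ndarray]:
    """Tabular Q-learning with linearly decaying epsilon-greedy exploration.

    ``env`` needs reset(seed)/step(action), an ``encode`` method, and an
    ``mdp.action_set``.  Returns the Q table: encoded observation ->
    action-value vector (ordered like action_set).  Reproducible per seed.
    """
    if episodes < 1:
        raise ValueError("episodes must be >= 1")
    actions = list(env.mdp.action_set)
    if len(actions) == 0:
        raise ValueError("empty action set")
    gamma = gamma if gamma is not None else env.mdp.gamma
    rng = np.random.default_rng(seed)
    q: dict[tuple, np.ndarray] = {}

    def qvec(s) -> np.ndarray:
        if s not in q:
            q[s] = np.zeros(len(actions))
        return q[s]

    for ep in range(episodes):
        eps = eps_start + (eps_end - eps_start) * ep / max(episodes - 1, 1)
        obs = env.reset(seed=int(rng.integers(2**31 - 1)))
        s = env.encode(obs)
        done = False
        while not done:
            if rng.random() < eps:
                a_i = int(rng.integers(len(actions)))
            else:
                a_i = int(np.argmax(qvec(s)))
            obs, reward, done = env.step(actions[a_i])
            s2 = env.encode(obs)
            target = reward if done else reward + gamma * qvec(s2).max()
            qvec(s)[a_i] += alpha * (target - qvec(s)[a_i])
            s = s2
    return q


def greedy_policy(q: dict[tuple, np.ndarray], action_set: Sequence[float]):
    """Greedy policy from a Q table; unseen states fall back to action 0."""
    actions = list(action_set)

    def policy(encoded_obs: tuple) -> float:
        vec = q.get(encoded_obs)
        if vec is None:
            return actions[0]
        return actions[int(np.argmax(vec))]

    return policy


def fixed_duty_policy(duty: float):
    """Policy that always requests the same duty (e.g. the 50% start)."""

    def policy(encoded_obs: tuple) -> float:
        return duty

    return policy


def evaluate_policy(
    policy,
    env,
    n_episodes: int = 20,
    seed: int = 0,
    *,
    gamma: float | None = None,
) -> tuple[float, float, list[EpisodeLog]]:
    """Monte-Carlo mean +/- sd of the discounted return under a policy."""
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    gamma = gamma if gamma is not None else env.mdp.gamma
    rng = np.random.default_rng(seed)
    logs: list[EpisodeLog] = []
    returns = []
    for _ in range(n_episodes):
        obs = env.reset(seed=int(rng.integers(2**31 - 1)))
        observations, actions, rewards = [obs], [], []
        done = False
        while not done:
            a = policy(env.encode(obs))
            obs, r, done = env.step(a)
            observations.append(obs)
            actions.append(a)
            rewards.append(r)
        J = discounted_return(rewards, gamma)
        logs.append(EpisodeLog(observations, actions, rewards, J))
        returns.append(J)
    returns = np.asarray(returns)
    sd = float(returns.std(ddof=1)) if n_episodes > 1 else 0.0
    return float(returns.mean()), sd, logs
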