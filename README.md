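# optocord

A digital twin of a closed-loop optogenetic spinal-cord stimulation device.
The modelled system is a soft implant placed over a rat spinal-cord injury:
a 470 nm µ-LED array photo-activates channelrhodopsin-2 (hChR2)-expressing
transplanted neural stem cells, a resistive temperature sensor guards
against overheating, and evoked electromyography (EMG) from the hind limb
feeds back the functional recovery, which the controller uses to customize
the weekly illumination strategy. `optocord` implements the computational
core of that loop so dosing, safety, and control strategies can be studied
on a desk before (or instead of) an animal.

It is a library for use from Python, with short narrative scripts under
`examples/` and a thin `optocord` CLI for the common table/trace exports.

## What it computes

**Light penetration (`optocord.optics`).** The emitting surface is a
spherical crown of radius ρ = 0.508 mm and height H = 0.150 mm, so the
surface power density is I₀ = P / (2πρH). With tissue scattering
S = 10.3 mm⁻¹, the density at depth z is

    I(z) = ρ² / [(S z + 1)(z + ρ)²] · P / (2πρH),

and the opsin-effective depth is the root of I(z) = 1 mW mm⁻² (the hChR2
excitation threshold), solved by bracketed root finding. PWM duty scales
the mean luminous power proportionally from its 100%-duty value of
4.69 mW.

**Tissue heating (`optocord.thermal`).** A conservative finite-volume
discretisation of the diffusion-only Pennes bioheat equation
ρc ∂T/∂t = ∇·(k∇T) + q on a 2-D axisymmetric layered stack
(muscle / device laminate / dura / cord / lamina), integrated implicitly.
The LED heat load (electrical input minus luminous output) is switched
60 s on / 90 s off; the outer surface exchanges heat convectively
(h = 27 W m⁻² K⁻¹) and radiatively (ε = 0.8) against a 25 °C environment,
net of the thermoregulated 37 °C baseline; deep boundaries are clamped at
core temperature. The headline output is the peak cord temperature rise,
checked against the 2 K biocompatibility bound. A linear RTD model maps
temperature to sensor resistance and back on the 31–43 °C calibrated band.

**Synthetic physiology (`optocord.physio`).** A latent recovery fraction
r ∈ [0, 1] grows logistically with saturating dependence on the daily
illumination dose, dr/dt = kθ·dose/(dose+D50)·r(1−r), with per-subject
log-normal responsiveness θ. Evoked EMG is a train of CMAP-shaped
transients with peak-to-peak amplitude A_max·r plus Gaussian noise; the
standardized reference trajectory is the noiseless metric of the
best-recovery parameter set, and a BBB-style 0–21 proxy maps r linearly.

**Closed-loop control (`optocord.control`).** Three 60 s sessions per day
at the current PWM duty; each week the relative EMG gap
(reference − measured)/reference is evaluated and the duty moves one rung
on the {25, 50, 75, 100}% ladder when the gap exceeds 0.15 — bounded above
by the ladder and, on every session, by a thermal guard that forbids any
duty whose predicted cord rise exceeds 2 K.

**Treatment policy (`optocord.policy`).** The 28-day course as a
finite-horizon decision process ⟨S, A, T, O, R, γ⟩: four weekly decisions,
actions = duty ladder ∪ {off}, observations = binned EMG gap, recent peak
rise and week, reward = w_bbb·ΔBBB + w_emg·(−gap) − w_thermal·max(0,
rise − cap), return J = Σ γᵗ rₜ. A tabular Q-learner with ε-greedy decay
provides the baseline policy optimiser.

## Worked example

```sh
python examples/thermal_safety.py
```

```
heat load while on:   10.94 mW
peak cord rise:       1.171 K at t = 60 s
peak LED rise:        1.757 K
```

At 100% duty the LED dissipates 10.94 mW (15.63 mW electrical input at 30%
wall-plug efficiency minus 4.69 mW of light). The cord surface under the
implant warms by 1.17 K, peaking exactly when the 60 s on-phase ends, and
stays well inside the 2 K biocompatibility bound — so the thermal guard
permits the full duty ladder at the default calibration.

```sh
python examples/light_penetration.py
```

```
 duty  luminous_power_mW  surface_density_mW_mm2  effective_depth_mm
 0.25               1.17                    2.45              0.0802
  0.5               2.35                     4.9                0.17
 0.75               3.52                    7.35               0.236
    1               4.69                     9.8               0.289
```

Every ladder duty exceeds the 1 mW mm⁻² excitation threshold at the cord
surface; the effective depth grows from 80 µm at 25% duty to 289 µm at
100%. The other examples walk through the synthetic cohort, the
closed-loop controller, and policy learning.

The same computations are available from the shell, e.g.
`optocord optics table`, `optocord thermal simulate --duty 1.0 --out trace.csv`,
`optocord closedloop run --subjects 3 --out loop.csv`.

## Configuration

All device constants and modelling defaults live in a validated key-value
configuration (`optocord.config.RunConfig`); any subset can be overridden
from a YAML file passed to `load_config` or `optocord --config`. Each key
carries a provenance tag distinguishing measured device constants from
modelling defaults; see `docs/methods.md` for the scientific rationale
behind the defaults and the model's known limitations.
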