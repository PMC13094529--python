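# Methods

This note records the models implemented in `optocord`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
components can and cannot say about real data.

## Optical model

The µ-LED array's emitting surface is idealised as a spherical crown
(radius ρ = 0.508 mm, height H = 0.150 mm), the cord as a flat, uniform,
ideal diffuser illuminated from one side. Surface power density is
I₀ = P/(2πρH); depth attenuation combines geometric spreading
ρ²/(z+ρ)² with per-thickness scattering 1/(Sz+1), S = 10.3 mm⁻¹ at
470 nm. The effective depth solves I(z) = 1 mW mm⁻² (hChR2 excitation
threshold) with Brent's method on [0, 10] mm; I(z) is continuous and
strictly decreasing, so the root is unique and resolved far below the
1e-6 mm tolerance. Sub-threshold powers return depth 0 with a flag rather
than raising, so the controller can treat them as "no effective dose".

*Effective area.* The default is the growing-cap form A = π(ρ + z_max)²,
labelled model-default; an alternative area model can be injected where
tables are built. No test asserts specific area values: the geometric
provenance of published area figures for such devices is not uniquely
determined by the crown model, and we refuse to reverse-engineer one.
The stated 154° divergence angle is carried on the source object but does
not enter the crown formulas.

*Units.* Canonical internal units are mm, mW, mW mm⁻², s, °C; printed µm
values convert at the boundary.

## Thermal model

The Pennes bioheat equation without the perfusion and metabolic terms,
ρc ∂T/∂t = ∇·(k∇T) + q(t), on a 2-D axisymmetric cylindrical domain:
a horizontal layer stack with the µ-LED heat load as a volumetric source
in a disc inside the device layer. Discretisation is cell-centred finite
volume (harmonic-mean face conductivities), integration backward Euler
(unconditionally stable); the sparse system is LU-factorised once because
the only nonlinearity — surface radiation — is evaluated explicitly from
the previous step (the rises are ~1 K, so the radiative coefficient is
essentially constant; convection is implicit).

*Perturbation form.* The solver tracks θ = T − 37 °C. The outer-surface
exchange applied is the convective (h = 27 W m⁻² K⁻¹) plus radiative
(ε = 0.8, σ = 5.67e-8 W m⁻² K⁻⁴) flux **net of its value at 37 °C**: in
vivo, the baseline surface loss is balanced by the perfusion and
metabolism that the simplified equation drops, so the unloaded animal sits
at its thermoregulated set point. With q = 0 the field therefore stays at
exactly 37 °C, and "temperature rise" needs no reference run. Deep and
lateral boundaries are clamped at core temperature.

*Heat load.* Heat = electrical input − luminous output. Electrical input
at duty d is d·P/η with wall-plug efficiency η = 0.30 by default (config
key `thermal.efficiency`), giving 10.94 mW at 100% duty. The 60 s on /
90 s off cycle mirrors the device's session timing.

*Geometry and materials (all config-overridable).* Layers from the outer
surface down: muscle 2.0 mm (k = 0.50 W m⁻¹K⁻¹), device laminate 0.1 mm,
dura 0.3 mm (0.44), cord 3.0 mm (0.51), lamina 1.0 mm (0.32); standard
soft-tissue/bone property values. The heat source is the equal-area disc
(radius 0.597 mm) of the 2×2 LED array envelope (two 600 µm dies plus a
200 µm gap by two 200 µm rows plus pitch). The device laminate is
anisotropic: through-plane k = 0.2 (polyimide) but effective in-plane
k = 30 W m⁻¹K⁻¹, from a rule of mixtures for ~35 µm copper interconnect
traces at ~20% areal coverage in a 100 µm build-up; the laminate patch
ends at radius 1.75 mm (the implant's main module), beyond which the row
is muscle. This in-plane spreading is the feature that keeps flexible
implants cool: with it, the model's peak cord rise at 100% duty is
~1.17 K, consistent with the ~1.2 K reported for such devices by full 3-D
FEM and in vivo sensing; an isotropic-polyimide variant overpredicts by
~2.5×. The solver itself was verified against the closed-form steady
disc-source solution in a homogeneous medium.

*Probes.* The LED probe is the axis cell at the device layer's
mid-height. The cord probe is a fixed physical point — the axis, 0.05 mm
below the dorsal cord surface — interpolated between cell centres so grid
refinement does not move it; the reported peak rise is taken there.

*Numerics.* Defaults Δr = 0.1 mm, Δz = 0.05 mm, Δt = 0.1 s
(~5100 cells, <1 s per 150 s cycle). Halving Δr, Δz and Δt changes the
peak rise by <2%. The finite-volume form is exactly conservative: with
insulated boundaries the enthalpy gain matches the injected heat to
solver precision (tested at 1%).

*Sensor.* Linear RTD R = R₀(1 + α(T − T₀)) with exact inverse, flagged
outside the calibrated 31–43 °C band. R₀ = 1 kΩ, α = 3.9e-3 K⁻¹ are
generic platinum-like defaults.

## Synthetic physiology

The generator emulates the study conditions of a 28-day post-transection
course with three 60 s illumination sessions per day: daily dose
= sessions × duty × 4.69 mW × 60 s (a duty whose surface density is below
the excitation threshold contributes zero dose). Latent recovery follows
dr/dt = kθ·σ(dose)·r(1−r) with σ = dose/(dose+D50); the per-day update
uses the exact logistic solution, so trajectories are closed-form and
r stays in [0, 1]. Defaults: k = 0.15/day, D50 = 200 mJ, r₀ = 0.05;
the standardized reference is the noiseless best-recovery curve
(k = 0.25/day at saturating dose), reaching ~98% of sham amplitude by
day 28. Subject responsiveness θ is log-normal (σ = 0.5), emulating
inter-animal variability that motivates customized dosing.

Evoked EMG is a train of CMAP-shaped transients (Gaussian-windowed
biphasic wave, 5 ms latency, 3 ms envelope, 120 Hz carrier, template
peak-to-peak normalised on the sample grid) scaled by A_max·r with
A_max = 8 mV (sham-level compound action potential), plus additive
Gaussian noise (default SD 5% of A_max). The extracted feature is the
mean post-stimulus peak-to-peak amplitude. Peak-to-peak of a noisy trace
is upward-biased by the noise extrema; the dose-response calibration
fixture therefore adds noise at the metric level (an unbiased amplitude
readout), and the calibration cohort spreads subjects across the duty
ladder because k and D50 are confounded at any single dose (only
k·σ(dose) is identifiable).

What passing tests show: the feedback loop and learner behave correctly
against a monotone, saturating, noisy dose-response. What they do not
show: any fidelity to real regeneration biology — the dose-response law,
its constants, the waveform shape and the noise model are modelling
constructs; real EMG features, BBB scores and histology are outside the
generator's reach.

## Controller

Weekly decisions (measurement on the last day of each 7-day period):
relative gap g = (reference − measured)/reference; g > 0.15 steps the duty
one rung up the {0.25, 0.5, 0.75, 1.0} ladder, g < −0.15 one rung down
(de-escalation is an extension flag, default on; only escalation is part
of the core strategy), otherwise hold. Start duty 0.5. "With a
limitation" is read as two caps: the ladder maximum and the 2 K thermal
bound, enforced per session by a guard that downgrades to the largest
safe duty (or skips the session if none is safe). The guard consumes a
rise-by-duty table computed once by the bioheat solver and cached; the
perturbation PDE is linear in the heat load, so rise ∝ duty at fixed
efficiency, and a cached full-duty rise with proportional scaling is
exact up to the (negligible) radiative nonlinearity. The 0.15 gap
threshold quantifies "significant gap" and is config-exposed.

## Treatment-policy environment

One episode = one 28-day course = 4 weekly decisions. Action: duty for
the week (ladder ∪ {0}); observation: EMG gap, largest predicted rise of
the past week, week index — what the implanted device can actually sense,
making the deployed problem partially observable while the twin is fully
observed. Reward r = w_bbb·ΔBBB + w_emg·(−gap) − w_thermal·max(0,
rise − cap) with defaults w = (1, 0.5, 10); the penalty weight is large
because the guard should make the penalty branch unreachable. Discount
γ = 0.95. The learner is tabular Q-learning (α = 0.2, linear ε decay
1 → 0.05) over binned observations (gap: 5 bins on [−1, 1]; rise: 3 bins
on [0, cap]; week: 4). These are deliberately simple artifact choices —
the framing specifies no algorithm — and everything is config-exposed.
Training on the twin uses a few hundred episodes; the greedy policy is
compared against the fixed 50%-duty start condition on identical
evaluation seeds.

## Determinism and I/O

Every stochastic path takes a seed; a master seed fans out to per-module
child seeds by stable hashing of module names, so adding a module never
perturbs existing streams. CSVs are UTF-8, '.' decimal, Unix newlines,
9-significant-digit floats, with a provenance comment line
(`# optocord v… seed=…`); reruns with the same seed and config are
byte-identical.

## Known limitations

- The thermal geometry is a 2-D axisymmetric reduction of a 3-D implant
  in a rat trunk; layer thicknesses and the laminate's effective in-plane
  conductivity are literature-derived defaults, not measured properties,
  so the ~1.17 K peak rise is an order-of-magnitude-faithful estimate
  bounded by the 2 K criterion, not a replication of any specific FEM.
- Dropping perfusion makes the thermal model conservative (real tissue
  sheds heat faster); dropping metabolism is absorbed by the
  perturbation-form boundary.
- The dose→recovery law and the EMG amplitude link are constructs; none
  of the recovery, EMG or BBB-proxy numbers should be read as predictions
  for real animals.
- The effective-area default is one defensible geometric choice among
  several; area outputs are labelled model-default.
- The tabular learner needs discretised observations; it is a baseline,
  not a recommendation of Q-learning for clinical dosing.
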