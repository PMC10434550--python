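# Methods

`oxsa` implements a compartmental model of oxygen transport during
obstructive and restricted breathing, together with the severity metrics
used to interpret its output (AHI, percent desaturations, hypoxia burden
scores, interval statistics) and a signal-processing pipeline that turns a
recorded nasal-pressure signal into the model's lung-volume input.

## Model structure

Four coupled pieces, advanced with an explicit finite-difference scheme:

1. **Alveolar compartment.** A single well-mixed gas space whose volume
   `V_A(t)` is prescribed by the breathing pattern. During inspiration
   (`dV_A/dt > 0`),

       V_A dP_A/dt = dV_A/dt (P_I − P_A) − k_l (C_A − C̄_c) R T,

   and during expiration only the membrane-transfer term remains. The
   inspired O2 partial pressure is `P_I = y_O2 (P_B − P_H2O)` (tracheal
   air, water-saturated at body temperature), `C_A = β_p P_A` is the
   dissolved O2 at the membrane and `k_l = D_L,O2 / β_p` the lung
   mass-transfer coefficient. At exactly zero flow the expiration form is
   used; the two forms coincide there.

2. **Pulmonary capillary compartment.** Blood is tracked as a FIFO queue
   of Lagrangian control volumes (default 40) of equal blood volume
   `ΔV = V_pc/N` advected by the pulmonary blood flow. Each parcel
   exchanges oxygen with the (spatially uniform) alveolar membrane,

       ΔV dC_T/dt = k_pc (C_A − C_d),    k_pc = k_l Δz / L_c,

   so the per-parcel relaxation constant `k_pc/ΔV = k_l/V_pc` is uniform
   along the compartment. The parcel entering at `z = 0` carries the
   pulmonary-arterial concentration and exits one transit time `V_pc/Q`
   later as the pulmonary-venous boundary value. The Lagrangian queue has
   no numerical diffusion, and the spatial dissolved-O2 average `C̄_c`
   closes the alveolar equation. End-capillary and alveolar partial
   pressures equilibrate at rest but decouple during rapid transients or
   low saturation, where the steep part of the dissociation curve makes
   the effective parcel relaxation slow — the mechanism behind
   alveolar/end-capillary divergence in severe event trains.

3. **Hemoglobin chemistry.** Total blood O2 is
   `C_T = C_d + 4 C_Hb S(P)` with the rational-function fit
   `S(P) = [1 + 23400/(P³ + 150 P)]⁻¹` and `P = C_d/β_p`. The fit
   constants define the curve and are not configurable. The inverse map
   (total → dissolved) is a safeguarded Newton iteration with bisection
   fallback on `[0, C_T]` (absolute tolerance 1e−12 mol/L); monotonicity
   of `C_T(C_d)` guarantees uniqueness.

4. **Systemic circulation.** All tissue extraction is lumped into one
   systemic compartment traversed by a parcel FIFO; each parcel loses
   total O2 at the constant rate `MR_O2/V_sys_cap`, so a constant-flow
   transit reproduces the Fick principle `ΔC_T = MR_O2/Q` exactly. The
   large vessels are not modeled: pulmonary-venous total O2 equals the
   systemic-arterial value (optionally scaled by an arteriole-leak
   fraction, default 1) and systemic-venous equals pulmonary-arterial.
   Cardiac output is heart rate × stroke volume; transit uses a
   volume-based exit criterion (`∫Q dt = V_sys_cap`), so time-varying
   heart rate shortens or lengthens the delay accordingly.

## Parameters, units, defaults

Internally: mol, L, s, mmHg, K. Configuration accepts clinical units
per field (e.g. diffusing capacity in mL O2·min⁻¹·mmHg⁻¹, converted at
STPD, 22.4 mL/mmol). Key defaults:

| parameter | default | why |
|---|---|---|
| `D_L_O2` | 21 mL/(min·mmHg) | resting normal diffusing capacity; held constant across conditions |
| `β_p` | 1.4 µmol/(L·mmHg) | ratio of the resting arterial (139 µM / 99 mmHg) and venous (57 µM / 41 mmHg) dissolved/pressure pairs |
| `C_Hb` | 2.3 mmol/L | ≈ 14.8 g/dL hemoglobin |
| `MR_O2` | 1.83e−4 mol/s | ≈ 246 mL O2/min; the value forced by the alveolar balance `MR = (P_I − P_A) V̇_A / RT` at the resting operating point P_A ≈ 99 mmHg with V̇_A = 4.2 L/min |
| heart rate / stroke volume | 75 bpm / 0.07 L | cardiac output 5.25 L/min so that the Fick gap `MR_O2/Q` reproduces the resting arteriovenous difference |
| `V_pc` | 0.07 L | pulmonary capillary blood volume |
| `V_sys_cap` | 8.0 L | see below |
| `P_B`, `P_H2O`, `y_O2`, `T` | 760, 47 mmHg, 0.21, 310 K | standard conditions |

**The systemic compartment volume.** Because the model equates
pulmonary-venous with systemic-arterial and systemic-venous with
pulmonary-arterial oxygen, the single Eq-1 compartment is the *only*
systemic blood volume in the loop. Setting it to the anatomic capillary
volume (~0.3 L) leaves the circulation with essentially no oxygen store:
a 40-s apnea then desaturates the arteries to S ≈ 0.73 and recovery takes
~1.5 min — both far from clinical behavior. The default 8 L treats the
compartment as the effective circulating O2 reservoir (blood pool plus
perfused-tissue stores); it yields a lung-to-lung recirculation time
`V_sys_cap/Q ≈ 91 s` (physiologic ≈ 1 min), apnea desaturations in the
clinically observed low-0.9 range after repeated events, and a ~3.6-min
return to normal oxygenation after an isolated 20-s apnea. The steady
state is independent of this volume; only the dynamics depend on it.

**A structural limit worth knowing.** With plug-flow transit and fixed
consumption, lung uptake obeys
`uptake(t) = MR_O2 + Q·(C_sa_T(t) − C_sa_T(t − τ))`: during the first
apnea of a train the alveolar store necessarily drains at close to
`MR_O2`, bounding how shallow the first desaturation can be (≈ 0.85 at
the default operating point). Shallower first-event minima would require
either a much larger cardiac output (incompatible with the resting
venous saturation via the Fick gap) or oxygen returning to the lung
inlet above the pre-event venous level (impossible in a
consumption-only compartment). Later minima in a train, after the
reservoir has begun to drain, are the clinically quoted ≈ 0.90.

## Breathing patterns and event scheduling

Normal breathing is the sinusoid
`V_A = ½V_vent sin(2π b_r t − π/2) + ½V_vent + V_End` with
`V_vent = V_T − V_D`; inspiration and expiration last equally long.
Apneas hold `V_A` at `V_End`; hypopneas scale the oscillation amplitude
by the remaining airflow fraction; hyperventilation overrides `V_T`
and/or `b_r`. After every event the sinusoid restarts at end-expiration
phase so the trace is continuous at `V_End`; the bundled scenarios place
all event boundaries on whole breaths, and a warning flags patterns that
cut a breath mid-cycle. Eleven scenarios ship with the package: the
normal-subject and severe-OSA validation patterns and nine OSA variants
(mild/moderate/severe; with and without unscored short apneas and
sub-criterion hypopneas; equal-obstruction-time comparisons). Event start
times within the 10-min windows are a scheduling choice (events on breath
boundaries, separated widely enough for recovery to be measurable); the
published patterns fix only counts, durations and window lengths.

## Numerics

Explicit forward-Euler stepping at `dt = 0.005 s` (config-exposed), with
an advection constraint `Q·dt ≤ ΔV` per parcel queue checked before each
run (at most one slice per step; exceeding it raises an error naming the
admissible step). Stability of the parcel relaxation requires
`dt < 2 V_pc β_eff/k_l`; at the defaults the relaxation number is ≈ 0.8
at the flattest point of the dissociation curve. Halving `dt` moves the
steady cyclic outputs by < 0.2 %, doubling the slice count by < 0.5 %.
Runs start from uniform initial conditions at the resting arterial point
(P = 99 mmHg) and breathe normally for a 360-s stabilization period
before the scenario events begin; any initialization reaching the same
cyclic state is equivalent.

The production time loop is a numba-compiled kernel mirroring the
reference pure-Python module operations one for one; a test asserts
step-level agreement between the two paths, and the Python path remains
available (`SolverOptions(loop="python")`, also used automatically when
capillary profile snapshots are requested).

## Severity metrics

The normal reference is the final 60 s of the stabilization period.
Percent decreases compare normal averages to scenario minima; the
mass-transfer reduction compares the scenario-averaged systemic
arteriovenous dissolved-O2 difference to its normal value. Per event,
the arterial minimum is read from the raw trace between that event's
onset and the next event's onset. Recovery ("reoxygenation") is the time
from the post-event minimum until the arterial saturation *and*
dissolved concentration re-enter a ±1 % band around their normal
averages; because the raw traces oscillate ±2 % within each breath,
recovery and overshoot are judged on traces smoothed over one breath
period (5 s), and the trailing smoothing window at an event-window edge
is excluded so the next event does not bleed into the judgment. The AHI
counts apnea/hypopnea events per analyzed hour; clinical scoring drops
events shorter than 10 s and hypopneas whose arterial desaturation is
below 4 % (evaluated post-simulation against the normal average).

## Patient signal pipeline

Nasal pressure → flow assumes a laminar (linear) relation with one
fitted total-conductance parameter per patient. The raw pressure is
normalized by subtracting a centered moving average (window
configurable; clinical use: tens of seconds, chosen to sit well above
the breath period); the conductance equates the mean per-breath maximum
of the normalized pressure in a clinician-identified normal segment with
the peak inspiratory flow of an ideal sinusoidal pattern built from the
patient's ideal-body-weight tidal volume (Devine formula, 7 mL/kg IBW)
and a BMI-class functional residual capacity (defaults 2.6 L overweight,
2.1 L obese, 3.0 L otherwise; all configurable). Flow integrates to
volume by cumulative trapezoid; the integrated trace's slow baseline
(moving average, same window) is re-anchored to the ideal mid-tidal
volume `FRC + ½V_vent` to control integrator drift. During apneas this
anchor biases the local baseline upward by up to half a tidal volume —
a known cost of having only the pressure signal; the end-to-end
round-trip error at default recording noise is ~1 % RMS and stays within
3 % in the recovery tests.

The synthetic generator is the exact inverse pipeline (pattern →
flow → pressure) plus minute-scale sinusoidal baseline drift and white
Gaussian noise, with annotations passed through and full determinism
under a seed. Defaults (2 % of a typical peak pressure as noise, 10 % as
drift) emulate a clean clinical nasal-pressure channel. What it does
*not* emulate: obstructed-breathing pressure swings decoupled from true
lung volume, sensor saturation/clipping, mouth breathing, and
position-dependent conductance changes — so passing recovery tests shows
the pipeline's numerics are sound, not that real recordings convert this
accurately.

## Burden scores and interval statistics

The wake baseline is the pooled mean and SD of systemic-arterial
dissolved O2 over clinician-chosen wakefulness intervals. The burden
score of a window is the signed, time-normalized area between the wake
mean and the trace (signed, so scoring wakefulness itself gives ≈ 0; a
`clip_deficit` variant ignores overshoot). The hypoxia-period score
restricts the area to samples below (mean − 1 SD) and normalizes by time
spent below; per-sample threshold crossing with no hysteresis.
Trapezoidal quadrature throughout. The interval analysis subtracts the
whole-study average of each variable from four equal-duration interval
averages (125 s in the clinical design, each holding two obstructive
events) and applies a two-sided one-sample t-test (n−1 df) against zero;
zero variance across intervals raises an explicit error rather than a
silent p-value.

## Known limitations

- No CO2 dynamics or chemoreflex ventilatory control: event schedules
  are inputs, not responses.
- No pulmonary shunt or ventilation/perfusion heterogeneity; no
  arteriolar leakage beyond the optional constant fraction.
- Fixed metabolic rate: no oxygen-supply-limited consumption, so extreme
  parameter choices can drive parcel oxygen to the clamped floor
  (logged, never silent).
- The first-event desaturation depth is structurally bounded (see
  above); trains of events and their relative severity ordering are the
  reliable outputs.
- Lung volume from nasal pressure is used directly as alveolar volume;
  no dead-space gas mixing dynamics beyond `V_vent = V_T − V_D`.
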