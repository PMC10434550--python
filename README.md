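# oxsa

Compartmental oxygen-transport modeling for obstructive sleep apnea
(OSA) severity assessment.

Clinical OSA scoring leans on the apnea–hypopnea index (AHI) and pulse
oximetry, neither of which measures what actually injures tissue: the
dissolved oxygen reaching it. `oxsa` simulates blood oxygenation — in
the alveoli, along the pulmonary capillaries, and in the systemic
arteries and veins — from a time-dependent lung-volume input, which can
be either a simulated breathing pattern or a lung volume reconstructed
from a polysomnography nasal-pressure channel. On top of the simulation
it computes the severity measures a sleep clinician or researcher would
ask for: the AHI, per-event desaturation minima and reoxygenation times,
percent reductions in oxygen mass transfer, and time-normalized hypoxia
burden scores against a wakefulness baseline.

It is aimed at computational physiologists and sleep researchers who
want tissue-level oxygenation estimates from standard polysomnography
signals, with few parameters and transparent assumptions.

## The model

Total blood O2 splits into dissolved and hemoglobin-bound parts,
`C_T = C_d + 4·C_Hb·S(P)`, with the dissociation curve
`S(P) = [1 + 23400/(P³ + 150·P)]⁻¹` and `P = C_d/β_p`. Only dissolved
oxygen drives transfer. The alveolar compartment obeys

    V_A dP_A/dt = dV_A/dt·(P_I − P_A) − k_l (C_A − C̄_c) R T   (inspiration)
    V_A dP_A/dt = − k_l (C_A − C̄_c) R T                        (expiration)

with `k_l = D_L,O2/β_p`. Pulmonary capillary blood is a queue of moving
control volumes exchanging O2 with the membrane
(`ΔV dC_T/dt = k_pc (C_A − C_d)`), which resolves the spatial uptake
profile and lets end-capillary and alveolar pressures diverge during
transients — a feature, not an error, of finite diffusing capacity. The
systemic circulation is a single transiting compartment consuming oxygen
at the basal metabolic rate (`dC_T/dt = −MR_O2/V_sys,cap`), so at steady
state the arteriovenous difference satisfies the Fick principle
`Q·(C_sa,T − C_sv,T) = MR_O2`. Breathing patterns are sinusoidal
(`V_A = ½V_vent sin(2π b_r t − π/2) + ½V_vent + V_End`) with apnea,
hypopnea, and hyperventilation events spliced in.

See `docs/methods.md` for parameter values, numerics, metric
definitions, and known limitations.

## Worked example

Simulate a normal subject at rest (tidal volume 0.5 L, dead space
0.15 L, end-expiration volume 2.3 L, 12 breaths/min):

```python
import numpy as np, oxsa

res = oxsa.run_scenario(oxsa.load_scenario("normal_rest"))
t = res.times; mask = (t >= 390) & (t <= 480)   # after stabilization
sa, sv = res.compartments["sa"], res.compartments["sv"]
print(f"P_A   = {np.mean(res.P_A[mask]):6.1f} mmHg")
print(f"S_sa  = {np.mean(sa.S[mask]):6.3f}   S_sv  = {np.mean(sv.S[mask]):6.3f}")
print(f"C_sa_d = {np.mean(sa.C_d[mask])*1e6:5.1f} uM   C_sv_d = {np.mean(sv.C_d[mask])*1e6:5.1f} uM")
```

prints

```
P_A   =   99.3 mmHg
S_sa  =  0.977   S_sv  =  0.759
C_sa_d = 139.0 uM   C_sv_d =  57.0 uM
```

i.e. a resting alveolar O2 partial pressure of ~99 mmHg, arterial and
venous hemoglobin saturations of 0.98/0.76, and dissolved oxygen of
139 µM arterial / 57 µM venous (≈ 99 and 41 mmHg) — all inside textbook
resting ranges, which is the model's validation anchor.

The same run from the shell, for the bundled severe-OSA pattern (four
40-s apneas in 3.3 min, hyperventilation between):

```sh
$ oxsa simulate --scenario severe_osa --out severe_out
AHI (scored) = 72.0 events/h
wrote severe_out/timeseries.csv, metrics.json, events.csv
```

`metrics.json` then holds the per-apnea arterial saturation minima and
reoxygenation times; `timeseries.csv` the full compartment traces. A
patient analysis runs the nasal-pressure pipeline first:

```sh
oxsa patient --pressure pressure.csv --height 1.78 --weight 84.1 \
     --normal-segment 30:120 --out patient_out
oxsa score --timeseries patient_out/timeseries.csv \
     --wake-intervals 0:300,3000:3300 --out burden.json
```

`oxsa make-synthetic` generates reproducible synthetic nasal-pressure
recordings (with annotations) for any scenario, and `oxsa scenarios
list` shows the eleven bundled breathing patterns.

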