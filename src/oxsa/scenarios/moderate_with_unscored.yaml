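name: moderate_with_unscored
description: >
  Moderate OSA (AHI 24): four 20-s apneas plus six unscored 5-s apneas over
  a 10-min period.
V_T: 0.5
V_D: 0.15
V_End: 2.3
b_r: 12
duration_s: 600
events:
  - {kind: apnea, start_s: 50, duration_s: 20}
  - {kind: apnea, start_s: 100, duration_s: 5}
  - {kind: apnea, start_s: 125, duration_s: 5}
  - {kind: apnea, start_s: 200, duration_s: 20}
  - {kind: apnea, start_s: 250, duration_s: 5}
  - {kind: apnea, start_s: 275, duration_s: 5}
  - {kind: apnea, start_s: 350, duration_s: 20}
  - {kind: apnea, start_s: 425, duration_s: 5}
  - {kind: apnea, start_s: 500, duration_s: 20}
  - {kind: apnea, start_s: 550, duration_s: 5}
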