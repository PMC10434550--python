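name: moderate_long_apneas
description: >
  Moderate OSA (AHI 24): four 30-s apneas over a 10-min period (2 min of
  total obstruction).
V_T: 0.5
V_D: 0.15
V_End: 2.3
b_r: 12
duration_s: 600
events:
  - {kind: apnea, start_s: 50, duration_s: 30}
  - {kind: apnea, start_s: 200, duration_s: 30}
  - {kind: apnea, start_s: 350, duration_s: 30}
  - {kind: apnea, start_s: 500, duration_s: 30}
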