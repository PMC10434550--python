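name: severe_frequent_apneas
description: >
  Severe OSA (AHI 48): eight 15-s apneas over a 10-min period (2 min of
  total obstruction, same as the long-apnea pattern but split into shorter events).
V_T: 0.5
V_D: 0.15
V_End: 2.3
b_r: 12
duration_s: 600
events:
  - {kind: apnea, start_s: 50, duration_s: 15}
  - {kind: apnea, start_s: 120, duration_s: 15}
  - {kind: apnea, start_s: 190, duration_s: 15}
  - {kind: apnea, start_s: 260, duration_s: 15}
  - {kind: apnea, start_s: 330, duration_s: 15}
  - {kind: apnea, start_s: 400, duration_s: 15}
  - {kind: apnea, start_s: 470, duration_s: 15}
  - {kind: apnea, start_s: 540, duration_s: 15}
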