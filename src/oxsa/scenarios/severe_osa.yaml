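name: severe_osa
description: >
  Severe OSA: four 40-s apneas over a 3.3-min period (AHI 72), separated by
  10-s hyperventilation epochs (V_T 1.0 L, b_r 24/min).
V_T: 0.5
V_D: 0.15
V_End: 2.3
b_r: 12
duration_s: 200
events:
  - {kind: apnea, start_s: 0, duration_s: 40}
  - {kind: hyperventilation, start_s: 40, duration_s: 10, override_V_T: 1.0, override_b_r: 24}
  - {kind: apnea, start_s: 50, duration_s: 40}
  - {kind: hyperventilation, start_s: 90, duration_s: 10, override_V_T: 1.0, override_b_r: 24}
  - {kind: apnea, start_s: 100, duration_s: 40}
  - {kind: hyperventilation, start_s: 140, duration_s: 10, override_V_T: 1.0, override_b_r: 24}
  - {kind: apnea, start_s: 150, duration_s: 40}
  - {kind: hyperventilation, start_s: 190, duration_s: 10, override_V_T: 1.0, override_b_r: 24}
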