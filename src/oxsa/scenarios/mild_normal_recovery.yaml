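name: mild_normal_recovery
description: >
  Mild OSA (AHI 12): two 20-s apneas in a 10-min period, normal breathing
  resumes immediately after each apnea.
V_T: 0.5
V_D: 0.15
V_End: 2.3
b_r: 12
duration_s: 600
events:
  - {kind: apnea, start_s: 50, duration_s: 20}
  - {kind: apnea, start_s: 350, duration_s: 20}
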