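name: normal_rest
description: >
  Normal subject at rest: sinusoidal tidal breathing, no obstructive events.
V_T: 0.5
V_D: 0.15
V_End: 2.3
b_r: 12
duration_s: 240
events: []
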