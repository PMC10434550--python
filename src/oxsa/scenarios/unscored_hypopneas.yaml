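name: unscored_hypopneas
description: >
  Unscored hypopneas (AHI 0 under the 4%-desaturation rule): four 25-s
  hypopneas with 50% airflow reduction over a 10-min period.
V_T: 0.5
V_D: 0.15
V_End: 2.3
b_r: 12
duration_s: 600
events:
  - {kind: hypopnea, start_s: 50, duration_s: 25, airflow_fraction: 0.5}
  - {kind: hypopnea, start_s: 200, duration_s: 25, airflow_fraction: 0.5}
  - {kind: hypopnea, start_s: 350, duration_s: 25, airflow_fraction: 0.5}
  - {kind: hypopnea, start_s: 500, duration_s: 25, airflow_fraction: 0.5}
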