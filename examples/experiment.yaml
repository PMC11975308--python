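# A complete desk-scale experiment: simulate a matched feature-payload
# cohort, build pairs at all three horizons, train every approach with the
# 7x6 nested protocol, and evaluate scan-level with bootstrap CIs and the
# baseline-vs-RiskFORM2 DeLong contrast.
seed: 42
out_dir: progrisk_out

simulate:
  n_subjects: 400
  payload: features    # or "image" for the synthetic-radiograph renderer
  n_features: 8
  noise_sd: 0.5

prepare:
  horizons: [1.0, 2.0, 4.0]
  bmi_tol: 0.10
  age_tol: 0           # widen to match +-k years in sparse cohorts

train:
  approaches: [baseline, riskreg, conreg, riskform1, riskform2]
  epochs: 40
  lr: 0.01
  weight_decay: 0.0001
  margin: 2.0
  gamma: 1.0

evaluate:
  n_boot: 1000
  contrasts: [[baseline, riskform2]]
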