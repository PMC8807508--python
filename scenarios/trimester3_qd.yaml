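# 10 mg once daily to steady state at the representative third-trimester
# week (FW 34), reported against the non-pregnant baseline.
name: trimester3_qd
trimester: 3
mode: representative
parameter_mode: table2_canonical
steady_state: true
baseline_fw: 0.0
seed: 0
regimen:
  dose_mg: 10.0
  interval_h: 24.0
  n_doses: 40
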