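# 10 mg once daily to steady state, non-pregnant reference.
name: baseline_qd
fw: 0.0
mode: representative
steady_state: true
seed: 0
regimen:
  dose_mg: 10.0
  interval_h: 24.0
  n_doses: 40
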