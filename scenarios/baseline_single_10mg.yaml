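# Single 10 mg oral dose in the non-pregnant reference adult female.
name: baseline_single_10mg
fw: 0.0
mode: representative
steady_state: false
seed: 0
regimen:
  dose_mg: 10.0
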