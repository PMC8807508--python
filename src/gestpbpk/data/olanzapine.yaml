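# Olanzapine compound parameter set (published whole-body PBPK inputs).
# The fm/fR entries are in-vivo anchors (mass balance + DDI derived), used
# to calibrate per-enzyme hepatic activity scalings; they are model outputs
# in a simulation, not direct rate inputs.
name: olanzapine
logP: 2.85
MW_g_per_mol: 312.4
pKa: 7.24
dissociation_type: monoprotic_base
fu_fraction: 0.07
solubility_ug_per_mL: 145.4
dissolution_t50_min: 10.0
transcellular_permeability_cm_per_min: 3.85e-6
CLint_L_per_h:
  CYP1A2: 26.67
  CYP3A4: 0.82
  CYP2C8: 2.14
  FMO3: 4.05
  UGT1A4: 20.06
GFR_fraction: 1.0
CL_TSspec_L_per_min: 0.31
fR_target: 0.07
fm_targets:
  CYP1A2: 0.50
  CYP3A4: 0.067
  CYP2C8: 0.067
  FMO3: 0.067
  UGT1A4: 0.23
blood_plasma_ratio: 1.0
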