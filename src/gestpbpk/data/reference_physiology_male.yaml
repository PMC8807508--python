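# Reference adult male physiology (ICRP-style reference tables, 73 kg).
version: 1
sex: male
age_range_years: [18, 65]
body_weight_kg: 73.0
hematocrit_fraction: 0.44
cardiac_output_L_per_h: 390.0          # 6.5 L/min at rest
gfr_L_per_h: 7.5                       # 125 mL/min

organ_volumes_L:
  lung: 1.20
  brain: 1.45
  heart: 0.33
  kidney: 0.31
  liver: 1.80
  gut_wall: 1.00
  stomach: 0.15
  spleen: 0.15
  pancreas: 0.14
  muscle: 29.0
  adipose: 14.5
  skin: 3.30
  bone: 10.50
  gonads: 0.035
  portal_vein: 0.09
  arterial_blood: 1.40
  venous_blood: 3.25

blood_flow_fraction_of_CO:
  brain: 0.120
  heart: 0.050
  kidney: 0.170
  liver: 0.065
  stomach: 0.010
  gut_wall: 0.140
  spleen: 0.030
  pancreas: 0.010
  muscle: 0.190
  adipose: 0.100
  skin: 0.0645
  bone: 0.050
  gonads: 0.0005

lumen_volume_mL: 250.0
effective_intestinal_surface_area_m2: 25.0   # effective absorptive mucosal area
absorbable_gut_residence_h: 20.0             # SI + absorptive colon, first-order
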