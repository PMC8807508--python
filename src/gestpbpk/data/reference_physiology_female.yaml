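# Reference adult female physiology (ICRP-style reference tables, 60 kg).
# Units are in the key names. Versioned: bump `version` on any change;
# the test suite pins these values.
version: 1
sex: female
age_range_years: [18, 65]
body_weight_kg: 60.0
hematocrit_fraction: 0.39
cardiac_output_L_per_h: 354.0          # 5.9 L/min at rest
gfr_L_per_h: 6.6                       # 110 mL/min

organ_volumes_L:
  lung: 0.95
  brain: 1.30
  heart: 0.25
  kidney: 0.275
  liver: 1.40
  gut_wall: 0.95
  stomach: 0.14
  spleen: 0.13
  pancreas: 0.12
  muscle: 17.5
  adipose: 19.0
  skin: 2.30
  bone: 7.80
  gonads: 0.011
  portal_vein: 0.08
  arterial_blood: 1.16
  venous_blood: 2.74

# Fractions of cardiac output drawn from the arterial pool. `liver` is the
# hepatic-arterial fraction only; total liver perfusion additionally receives
# the portal drainage of stomach, gut wall, spleen and pancreas.
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

# Oral absorption geometry (single lumped absorbable lumen).
lumen_volume_mL: 250.0
effective_intestinal_surface_area_m2: 25.0   # effective absorptive mucosal area
absorbable_gut_residence_h: 20.0             # SI + absorptive colon, first-order

# Gestational trajectories, all functions of fertilization week (FW, weeks).
# Smooth empirical forms consistent with the pregnancy-physiology literature
# (term weight gain ~12 kg, cardiac output +~45%, GFR +~50%, plasma volume
# +~35%, haemodilution). Absolute liver perfusion is held constant.
gestation:
  term_fw: 38.0
  cardiac_output_rise_fraction: 0.45      # linear to FW 34, flat after
  cardiac_output_rise_end_fw: 34.0
  gfr_rise_fraction: 0.50                 # quadratic, plateau at FW 36
  gfr_rise_end_fw: 36.0
  kidney_volume_rise_fraction: 0.18       # linear to term
  hematocrit_drop: 0.05                   # linear to term
  blood_volume_rise_fraction: 0.35        # linear to term
  adipose_gain_L_at_term: 2.5
  other_gain_kg_at_term: 0.5              # ECF/other tissue water
  placenta_L_at_term: 0.65                # grows as (FW/term)^2
  uterus_L_at_term: 0.98                  # growth above non-pregnant size
  amniotic_fluid_L_at_term: 0.80          # (FW/term)^2
  fetus_kg_at_term: 3.5                   # (FW/term)^3
  mammary_L_at_term: 0.40                 # linear
  # Allocation of the cardiac-output increment to perfused beds.
  extra_co_shares:
    placenta: 0.60
    kidney: 0.15
    mammary: 0.05
    skin: 0.10
    adipose: 0.10
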