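# Tissue composition table for composition-based partitioning.
# Fractions are volume fractions; pH is the effective tissue water pH.
# Values compiled from standard composition tables used by Schmitt-type
# partitioning methods. `plasma` is the reference phase.
version: 1
compositions:
  plasma:     {water: 0.920, neutral_lipid: 0.0023, phospholipid: 0.0013, protein: 0.070, pH: 7.4}
  adipose:    {water: 0.15,  neutral_lipid: 0.790,  phospholipid: 0.0020, protein: 0.050, pH: 7.1}
  bone:       {water: 0.44,  neutral_lipid: 0.074,  phospholipid: 0.0011, protein: 0.200, pH: 7.0}
  brain:      {water: 0.77,  neutral_lipid: 0.051,  phospholipid: 0.0565, protein: 0.080, pH: 7.1}
  gut_wall:   {water: 0.75,  neutral_lipid: 0.049,  phospholipid: 0.0163, protein: 0.150, pH: 7.0}
  heart:      {water: 0.76,  neutral_lipid: 0.0115, phospholipid: 0.0166, protein: 0.160, pH: 7.1}
  kidney:     {water: 0.78,  neutral_lipid: 0.0207, phospholipid: 0.0162, protein: 0.160, pH: 7.22}
  liver:      {water: 0.75,  neutral_lipid: 0.0348, phospholipid: 0.0252, protein: 0.180, pH: 7.23}
  lung:       {water: 0.81,  neutral_lipid: 0.0030, phospholipid: 0.0090, protein: 0.130, pH: 6.6}
  muscle:     {water: 0.76,  neutral_lipid: 0.0238, phospholipid: 0.0072, protein: 0.170, pH: 7.0}
  pancreas:   {water: 0.66,  neutral_lipid: 0.041,  phospholipid: 0.0093, protein: 0.170, pH: 7.0}
  skin:       {water: 0.72,  neutral_lipid: 0.0284, phospholipid: 0.0111, protein: 0.220, pH: 7.0}
  spleen:     {water: 0.79,  neutral_lipid: 0.0201, phospholipid: 0.0198, protein: 0.150, pH: 7.0}
  stomach:    {water: 0.75,  neutral_lipid: 0.032,  phospholipid: 0.0110, protein: 0.150, pH: 7.0}
  gonads:     {water: 0.80,  neutral_lipid: 0.010,  phospholipid: 0.0100, protein: 0.150, pH: 7.0}
  placenta:   {water: 0.78,  neutral_lipid: 0.015,  phospholipid: 0.0100, protein: 0.150, pH: 7.0}
  uterus:     {water: 0.78,  neutral_lipid: 0.015,  phospholipid: 0.0100, protein: 0.150, pH: 7.0}
  mammary:    {water: 0.50,  neutral_lipid: 0.350,  phospholipid: 0.0050, protein: 0.100, pH: 7.0}
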