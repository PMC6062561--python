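# Default generating parameters for the synthetic ADNI-like cohort.
#
# Baseline volumes (mm^3) are generated per label as
#   v = b + c_age*age + c_gender*gender + c_size*head_size + offset(group) + noise
# with head size drawn first and structures conditioned on it.  Follow-up
# volumes apply a log-scale volume-change draw per interval (percent).
# Group sizes, anchor offsets/SDs and volume-change rates follow the
# published ADNI-scale summary statistics; everything else is a documented
# tissue-class-level default.

n_per_group: {HC: 404, sMCI: 166, pMCI: 177, AD: 322}
age_range: [55.0, 90.0]
p_male: 0.543
head_size: {mean: 1200000.0, sd: 110000.0}

# fraction of a structure's reference volume carried by the head-size slope
size_fraction: 0.7
# group offsets relative to the AD offset (amygdala: sMCI -149.4/-452.0,
# pMCI -387.4/-452.0); group SD scale relative to HC (AD 332.0/250.5)
group_offset_scale: {HC: 0.0, sMCI: 0.33, pMCI: 0.86, AD: 1.0}
group_sd_scale: {HC: 1.0, sMCI: 1.10, pMCI: 1.25, AD: 1.33}

# per tissue class: reference volume per label (mm^3, HC at age 75,
# head size 1.2e6), noise SD as fraction of reference, AD offset as
# fraction of reference, age slope fraction per year, gender offset fraction
tissue_defaults:
  cortical_gm:   {baseline: 5245.0,  sd_frac: 0.10, ad_offset_frac: -0.046, age_frac: -0.003, gender_frac: 0.01}
  deep_gm:       {baseline: 3000.0,  sd_frac: 0.10, ad_offset_frac: -0.009, age_frac: -0.002, gender_frac: 0.01}
  wm:            {baseline: 12000.0, sd_frac: 0.10, ad_offset_frac:  0.017, age_frac: -0.001, gender_frac: 0.01}
  ventricle_csf: {baseline: 1600.0,  sd_frac: 0.45, ad_offset_frac:  0.462, age_frac:  0.015, gender_frac: 0.02}
  other_csf:     {baseline: 1500.0,  sd_frac: 0.30, ad_offset_frac:  0.05,  age_frac:  0.010, gender_frac: 0.02}
  other:         {baseline: 3000.0,  sd_frac: 0.10, ad_offset_frac: -0.015, age_frac: -0.002, gender_frac: 0.01}

# absolute reference volumes for labels far from their tissue default
baseline_volumes:
  RightCerebralWhiteMatter: 200000.0
  LeftCerebralWhiteMatter: 200000.0
  RightCerebellumWhiteMatter: 12000.0
  LeftCerebellumWhiteMatter: 12000.0
  RightCerebellumExterior: 50000.0
  LeftCerebellumExterior: 50000.0
  BrainStem: 20000.0
  RightLateralVentricle: 16500.0
  LeftLateralVentricle: 16500.0
  3rdVentricle: 1500.0
  4thVentricle: 1800.0
  RightCaudate: 3500.0
  LeftCaudate: 3500.0
  RightPutamen: 4000.0
  LeftPutamen: 4000.0
  RightPallidum: 1300.0
  LeftPallidum: 1300.0
  RightThalamusProper: 7000.0
  LeftThalamusProper: 7000.0
  RightVentralDC: 4000.0
  LeftVentralDC: 4000.0
  RightAccumbensArea: 400.0
  LeftAccumbensArea: 400.0
  RightBasalForebrain: 400.0
  LeftBasalForebrain: 400.0
  CerebellarVermalLobulesI-V: 3000.0
  CerebellarVermalLobulesVI-VII: 2000.0
  CerebellarVermalLobulesVIII-X: 2500.0
  RightVessel: 50.0
  LeftVessel: 50.0
  OpticChiasm: 80.0
  RightCerebralExterior: 300.0
  LeftCerebralExterior: 300.0
  RightITG: 12100.0
  LeftITG: 12100.0
  RightMTG: 14600.0
  LeftMTG: 14600.0
  RightFuG: 14000.0
  LeftFuG: 14000.0

# fully anchored labels: reference volume, HC noise SD and AD offset/SD (mm^3)
structure_overrides:
  RightAmygdala:    {baseline: 1149.0, hc_sd: 139.4, ad_offset: -232.2, ad_sd: 182.6}
  LeftAmygdala:     {baseline: 1116.0, hc_sd: 135.5, ad_offset: -219.8, ad_sd: 179.7}
  RightHippocampus: {baseline: 3359.0, hc_sd: 339.1, ad_offset: -527.3, ad_sd: 488.0}
  LeftHippocampus:  {baseline: 3196.0, hc_sd: 364.6, ad_offset: -588.1, ad_sd: 423.1}
  RightInfLatVent:  {baseline: 1028.0, hc_sd: 345.0, ad_offset: 681.3, ad_sd: 690.3}
  LeftInfLatVent:   {baseline: 952.0,  hc_sd: 360.6, ad_offset: 649.5, ad_sd: 677.1}
  RightEntA:        {baseline: 2108.0, hc_sd: 343.0, ad_offset: -400.7, ad_sd: 412.0}
  LeftEntA:         {baseline: 2108.0, hc_sd: 343.0, ad_offset: -400.6, ad_sd: 412.0}

# log-scale volume change per interval: mean (SD) in % per group, resolved
# for each label first by merged structure name, then by tissue class
atrophy:
  m12:
    by_structure:
      Hippocampus:     {HC: [-1.1, 1.7], sMCI: [-1.7, 2.2], pMCI: [-4.1, 3.2], AD: [-4.8, 3.7]}
      InfLatVent:      {HC: [1.8, 3.3],  sMCI: [2.6, 3.8],  pMCI: [6.7, 5.6],  AD: [7.5, 5.5]}
      LateralVentricle: {HC: [3.0, 3.2], sMCI: [3.6, 3.3],  pMCI: [7.1, 4.6],  AD: [7.6, 4.9]}
      MTG:             {HC: [-1.1, 1.5], sMCI: [-1.4, 1.8], pMCI: [-3.1, 2.4], AD: [-3.8, 2.7]}
      EntA:            {HC: [-1.2, 1.6], sMCI: [-1.5, 2.0], pMCI: [-4.0, 3.7], AD: [-3.7, 4.1]}
    by_tissue:
      cortical_gm:   {HC: [-0.8, 1.4], sMCI: [-0.8, 1.3], pMCI: [-1.8, 1.7], AD: [-1.9, 2.3]}
      wm:            {HC: [-0.2, 0.7], sMCI: [-0.4, 0.7], pMCI: [-0.6, 0.9], AD: [-0.8, 1.0]}
      deep_gm:       {HC: [-0.8, 1.3], sMCI: [-0.7, 1.3], pMCI: [-1.3, 1.2], AD: [-1.4, 1.6]}
      ventricle_csf: {HC: [2.8, 3.0],  sMCI: [3.4, 3.1],  pMCI: [6.8, 4.3],  AD: [7.2, 4.6]}
      other_csf:     {HC: [1.0, 2.0],  sMCI: [1.2, 2.0],  pMCI: [2.0, 2.5],  AD: [2.2, 2.5]}
      other:         {HC: [-0.5, 0.8], sMCI: [-0.6, 0.8], pMCI: [-1.2, 1.0], AD: [-1.3, 1.1]}
  m24:
    by_structure:
      Hippocampus:     {HC: [-2.0, 2.3], sMCI: [-3.7, 3.8], pMCI: [-8.9, 5.1], AD: [-10.2, 6.2]}
      InfLatVent:      {HC: [3.5, 4.5],  sMCI: [6.2, 6.5],  pMCI: [14.6, 8.9], AD: [15.9, 8.8]}
      LateralVentricle: {HC: [6.3, 4.0], sMCI: [7.5, 6.0],  pMCI: [14.4, 7.9], AD: [15.4, 8.5]}
      MTG:             {HC: [-2.0, 1.6], sMCI: [-2.6, 2.6], pMCI: [-6.1, 3.9], AD: [-6.8, 4.1]}
      EntA:            {HC: [-2.2, 2.4], sMCI: [-2.8, 3.6], pMCI: [-7.4, 4.7], AD: [-7.0, 5.5]}
    by_tissue:
      cortical_gm:   {HC: [-1.6, 1.7], sMCI: [-1.7, 1.5], pMCI: [-3.2, 2.5], AD: [-3.5, 2.4]}
      wm:            {HC: [-0.6, 0.8], sMCI: [-0.8, 1.0], pMCI: [-1.6, 1.3], AD: [-1.8, 1.4]}
      deep_gm:       {HC: [-1.3, 1.3], sMCI: [-1.2, 1.0], pMCI: [-2.1, 1.4], AD: [-2.3, 1.8]}
      ventricle_csf: {HC: [5.8, 3.7],  sMCI: [7.1, 5.6],  pMCI: [13.7, 7.4], AD: [14.7, 7.8]}
      other_csf:     {HC: [2.0, 3.0],  sMCI: [2.4, 3.0],  pMCI: [4.0, 4.0],  AD: [4.4, 4.0]}
      other:         {HC: [-1.1, 0.8], sMCI: [-1.2, 1.0], pMCI: [-2.3, 1.5], AD: [-2.6, 1.3]}
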