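# Null configuration: same demographics as the study cohort but no HIV,
# ART, CD4 or viral-load effects on any test. Case and control T-score
# distributions are exchangeable under this config.
hiv_effects:
  gp_dh: 0.0
  gp_ndh: 0.0
  wais_ds: 0.0
  wais_ss: 0.0
  stroop_color: 0.0
  stroop_word: 0.0
  tmt_a: 0.0
  ctt1: 0.0
art_effect_d: 0.0
cd4_effect_d: 0.0
vl_effect_d: 0.0
seed: 0
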