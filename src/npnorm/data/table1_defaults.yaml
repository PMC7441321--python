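# Synthetic-cohort configuration emulating the norming study cohort
# (all values are also the package defaults; this file makes them explicit).
controls:
  n: 363
  age_mean: 34.3
  age_sd: 10.6
  age_range: [18, 64]
  edu_mean: 12.4
  edu_sd: 4.2
  edu_range: [0, 21]
  male_p: 0.344
cases:
  n: 320
  age_mean: 37.8
  age_sd: 9.4
  age_range: [18, 60]
  edu_mean: 9.6
  edu_sd: 3.7
  edu_range: [2, 20]
  male_p: 0.222
hiv_effects:       # marginal case-control Cohen's d per test
  gp_dh: -0.18
  gp_ndh: -0.10
  wais_ds: -0.25
  wais_ss: -0.03
  stroop_color: -0.09
  stroop_word: -0.19
  tmt_a: -0.18
  ctt1: -0.13
art_effect_d: 0.24
cd4_effect_d: 0.22
vl_effect_d: 0.0
art_p: [0.536, 0.445, 0.019]
cd4_median: 405
vl_detectable_p: 0.428
log10_vl_mean: 4.61
log10_vl_sd: 1.30
seed: 0
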