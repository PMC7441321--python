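{
 "name": "cameroon_2020_tscores",
 "description": "Fractional-polynomial T-score formulas for 8 motor/SIP tests, fitted on HIV-negative Cameroonian adults. Predicted scaled score = intercept + sum(coef * term), with edu_t = (edu+1)/10, age_t = age/100, male in {0,1}; term = var^power * (log(var) if log_mult). T = 50 + 10*(scaled - predicted)/residual_sd.",
 "formulas": [
  {"test_id": "gp_dh", "intercept": 9.9524, "residual_sd": 2.6106,
   "terms": [{"var": "edu", "power": 1, "log_mult": false, "coef": 2.1445},
             {"var": "age", "power": 1, "log_mult": false, "coef": -8.0012},
             {"var": "male", "power": 1, "log_mult": false, "coef": -0.2450}]},
  {"test_id": "gp_ndh", "intercept": 11.1141, "residual_sd": 2.6828,
   "terms": [{"var": "edu", "power": 1, "log_mult": false, "coef": 1.7112},
             {"var": "age", "power": 1, "log_mult": false, "coef": -9.4319},
             {"var": "male", "power": 1, "log_mult": false, "coef": -0.4858}]},
  {"test_id": "wais_ds", "intercept": 8.3622, "residual_sd": 2.1019,
   "terms": [{"var": "edu", "power": 1, "log_mult": false, "coef": 3.9066},
             {"var": "age", "power": 1, "log_mult": false, "coef": -9.8019},
             {"var": "male", "power": 1, "log_mult": false, "coef": -0.5678}]},
  {"test_id": "wais_ss", "intercept": 3.9602, "residual_sd": 2.4067,
   "terms": [{"var": "edu", "power": 1, "log_mult": false, "coef": 3.5142},
             {"var": "age", "power": -2, "log_mult": false, "coef": 0.1238},
             {"var": "male", "power": 1, "log_mult": false, "coef": -0.0233}]},
  {"test_id": "stroop_color", "intercept": 9.2469, "residual_sd": 2.6168,
   "terms": [{"var": "edu", "power": 3, "log_mult": false, "coef": 2.1281},
             {"var": "edu", "power": 3, "log_mult": true, "coef": -2.4993},
             {"var": "age", "power": 1, "log_mult": false, "coef": -5.9936},
             {"var": "male", "power": 1, "log_mult": false, "coef": -0.4210}]},
  {"test_id": "stroop_word", "intercept": 7.9642, "residual_sd": 2.5853,
   "terms": [{"var": "edu", "power": 3, "log_mult": false, "coef": 2.4560},
             {"var": "edu", "power": 3, "log_mult": true, "coef": -2.8511},
             {"var": "age", "power": 1, "log_mult": false, "coef": -3.9559},
             {"var": "male", "power": 1, "log_mult": false, "coef": -0.1437}]},
  {"test_id": "tmt_a", "intercept": 9.1490, "residual_sd": 2.5746,
   "terms": [{"var": "edu", "power": 1, "log_mult": false, "coef": 2.6381},
             {"var": "age", "power": 1, "log_mult": false, "coef": -7.5250},
             {"var": "male", "power": 1, "log_mult": false, "coef": -0.3085}]},
  {"test_id": "ctt1", "intercept": 8.6428, "residual_sd": 2.5560,
   "terms": [{"var": "edu", "power": 1, "log_mult": false, "coef": 2.7874},
             {"var": "age", "power": 1, "log_mult": false, "coef": -6.8461},
             {"var": "male", "power": 1, "log_mult": false, "coef": -0.1505}]}
 ]
}
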