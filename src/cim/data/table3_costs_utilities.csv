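name,value,sd,distribution
invest_total,3022975,,
invest_per_capita,4.5,1.690,gamma
maint_total,44438,,
maint_per_capita,0.066,0.020,gamma
cost_chd_first,22133,8300,gamma
cost_chd_post,21597,8099,gamma
cost_stroke_first,25421,9533,gamma
cost_stroke_post,11962,4486,gamma
cost_t2d,5247,1968,gamma
cost_cancer,13810,5179,gamma
util_healthy,1.00,,
util_cancer,0.74,0.015,beta
util_chd1,0.47,0.016,beta
util_chd1plus,0.56,0.016,beta
util_stroke1,0.50,0.036,beta
util_stroke1plus,0.50,0.036,beta
util_t2d,0.81,0.190,beta
wellbeing_gain_active,0.05,0.013,beta
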