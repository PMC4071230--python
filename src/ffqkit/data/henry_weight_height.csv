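# Henry (Oxford) weight-and-height BMR prediction equations, adults.
# BMR_MJ_per_day = w_coef * weight_kg + h_coef * height_m + intercept
# Age bands are lower-inclusive: [age_min, age_max). version=1
sex,age_min,age_max,w_coef,h_coef,intercept
male,18,30,0.0600,1.31,0.4730
male,30,60,0.0476,2.26,-0.5740
male,60,999,0.0478,2.26,-1.0700
female,18,30,0.0433,2.57,-1.1800
female,30,60,0.0342,2.10,-0.0486
female,60,999,0.0356,1.76,0.0448
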