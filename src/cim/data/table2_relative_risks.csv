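disease,kind,base,lower,upper,distribution,mortality_reference
chd,mortality,3.89,3.81,3.97,lognormal,cvd
stroke,mortality,3.89,3.81,3.97,lognormal,cvd
t2d,mortality,2.61,2.34,2.88,lognormal,cvd
cancer,mortality,4.20,4.00,4.30,lognormal,all_cause
cancer,disease_active,0.55,0.36,0.84,lognormal,
chd,disease_active,0.80,0.75,0.86,lognormal,
stroke,disease_active,0.82,0.77,0.87,lognormal,
t2d,disease_active,0.74,0.72,0.77,lognormal,
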