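sex,factor,beta,reference_mean
male,age,0.065,60.0
male,sbp,0.018,139.7
male,total_chol,0.006,213.6
male,hdl_c,-0.018,52.0
male,diabetes,0.55,0.03
male,smoker,0.45,0.23
male,baseline_survival_10y,0.980,
female,age,0.075,60.0
female,sbp,0.016,139.7
female,total_chol,0.005,213.6
female,hdl_c,-0.020,52.0
female,diabetes,0.65,0.03
female,smoker,0.35,0.23
female,baseline_survival_10y,0.990,
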