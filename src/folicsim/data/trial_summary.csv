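outcome,folic,control,delta
study_drug_cost,1170.46,137.41,1033.05
concomitant_cost,75.13,73.01,2.12
ischemic_stroke_cost,32.95,43.13,-10.17
hemorrhagic_stroke_cost,17.98,19.21,-1.23
other_cvd_cost,10.89,9.98,0.91
total_cost,923.74,217.71,706.03
qaly,3.92,3.90,0.016
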