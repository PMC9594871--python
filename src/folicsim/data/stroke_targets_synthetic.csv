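time_years,cumulative_incidence,arm
4.5,0.034,control
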