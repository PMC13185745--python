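study_id,effect_measure,point,ci_lower,ci_upper,ci_level
TOPCAT,rate_ratio,0.84,0.70,1.02,0.95
TOPCAT-Americas,rate_ratio,0.79,0.64,0.97,0.95
FIDELITY,rate_ratio,0.82,0.72,0.95,0.95
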