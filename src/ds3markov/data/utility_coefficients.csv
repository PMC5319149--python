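term,value
constant,0.880
d_moderate,-0.078
d_marked,-0.122
d_severe,-0.168
bone_pain,-0.098
ssc,0.018
female,-0.049
age_at_init,-0.002
mean_female,0.691
mean_age,53.9
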