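term,value
prev_mild_bp,1.305
prev_mild_ssc,0.840
prev_moderate,2.581
prev_moderate_ssc,1.253
prev_marked,4.504
prev_marked_ssc,3.617
prev_severe,4.213
prev_severe_ssc,6.072
tx_two_years,0.293
tx_three_plus_years,0.315
baseline_moderate,-0.150
baseline_marked,0.873
baseline_severe,1.349
not_splenectomized,-1.089
cutpoint_1,0.740
cutpoint_2,1.662
cutpoint_3,1.727
cutpoint_4,5.054
cutpoint_5,5.835
cutpoint_6,6.577
cutpoint_7,8.808
cutpoint_8,9.066
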