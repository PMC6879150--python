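simulation,condition,measure,value,units
sim2,ecc2_comp1,flow_parsing_gain_mean,84,percent
sim2,ecc4_comp2,flow_parsing_gain_mean,72,percent
sim1,matched_comp1,flow_parsing_gain_mean,67,percent
sim1,matched_comp2,flow_parsing_gain_mean,50,percent
sim1,fast_speeds_band_low,flow_parsing_gain,0.30,gain
sim1,fast_speeds_band_high,flow_parsing_gain,0.40,gain
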