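arm,window,cost_per_participant,qaly_htvas,qaly_sf36
individual_coaching,end_of_trial,1578.37,0.7497,0.7268
education_control,end_of_trial,1114.01,0.7095,0.6872
individual_coaching,five_year,5774.80,3.1761,3.0652
education_control,five_year,5328.30,3.1183,3.0150
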