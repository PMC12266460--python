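arm,month,lt5,m5_10,gt10,dead
individual_coaching,16,0.315,0.242,0.443,0.0
education_control,16,0.543,0.229,0.228,0.0
individual_coaching,22,0.436,0.222,0.342,0.0
education_control,22,0.634,0.196,0.170,0.0
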