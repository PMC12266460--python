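state,htvas,sf36,rx_monthly,other_monthly
lt5,64.71,61.94,44.97,57.37
m5_10,73.73,73.86,40.71,33.69
gt10,82.96,79.68,35.20,43.81
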