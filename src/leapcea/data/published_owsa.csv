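scenario,parameter,direction,new_value,d_cost,d_qaly_htvas,d_qaly_sf36,icer_htvas,icer_sf36
base,base,base,,335.08,0.0342,0.0270,9797.86,12416.15
program_cost,phase2_program_cost_individual,high,666.37,440.81,0.0342,0.0270,12889.07,16333.55
program_cost,phase2_program_cost_individual,low,444.25,229.36,0.0342,0.0270,6706.50,8498.74
rx_cost,rx_monthly_all_states,high,53.22,258.33,0.0342,0.0270,7553.53,9572.13
rx_cost,rx_monthly_all_states,low,35.48,411.84,0.0342,0.0270,12042.04,15260.16
other_cost,other_monthly_all_states,high,70.22,327.49,0.0342,0.0270,9575.81,12134.86
other_cost,other_monthly_all_states,low,46.82,342.68,0.0342,0.0270,10019.75,12697.44
total_cost,total_monthly_all_states,high,123.44,250.74,0.0342,0.0270,7331.55,9290.84
total_cost,total_monthly_all_states,low,82.30,419.43,0.0342,0.0270,12264.01,15541.45
discount_rate,annual_discount_rate,low,0.01,328.44,0.0351,0.0277,9351.99,11867.45
discount_rate,annual_discount_rate,high,0.05,341.20,0.0333,0.0263,10231.79,12949.27
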