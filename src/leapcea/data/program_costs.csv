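arm,phase,line_item,total_usd,n_participants
education_control,1,program_staffing,38225.79,153
education_control,1,program_manuals,5246.83,153
education_control,1,intervention_materials,6271.12,153
education_control,2,program_staffing,4085.13,153
education_control,2,teleconference_service,0.00,153
individual_coaching,1,program_staffing,37226.42,149
individual_coaching,1,program_manuals,5109.66,149
individual_coaching,1,intervention_materials,6107.17,149
individual_coaching,2,program_staffing,80830.13,149
individual_coaching,2,teleconference_service,1911.06,149
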