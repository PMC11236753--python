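parameter,value,unit
diameter_min,2,um
diameter_max,16,um
internodal_distance_min,155,um
internodal_distance_max,1500,um
node_length,2.5,um
specific_axon_resistance,0.7,ohm_m
membrane_conductance_per_area,30.4,mS_per_cm2
membrane_capacitance_per_area,2,uF_per_cm2
resting_potential,-70,mV
threshold_potential,-55,mV
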