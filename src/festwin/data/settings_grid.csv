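mode,key,value
simulation,amplitude_min_mA,1
simulation,amplitude_max_mA,50
simulation,amplitude_step_mA,1
simulation,pw_min_us,1
simulation,pw_max_us,500
experiment,amplitude_min_mA,1
experiment,amplitude_step_mA,1
experiment,pw_grid_us,20;40;60;80;100;150;200;250;300;350;400;450;500
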