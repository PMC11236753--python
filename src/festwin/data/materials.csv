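name,sigma_axial_S_per_m,sigma_radial_S_per_m,epsilon_r_axial,epsilon_r_radial
hydrogel,1/11,1/11,1,1
skin,1/700,1/700,6000,6000
fat,1/33,1/33,25000,25000
muscle,1/3,1/9,120000,40000
bone,1/50,1/50,3000,3000
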