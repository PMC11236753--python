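roi,diff_axial_pct,diff_radial_pct,indiff_axial_pct,indiff_radial_pct,projection
ECU,33.06,9.88,88.00,20.00,minor
ED,33.06,22.03,88.00,20.00,minor
ECRB,25.62,32.11,88.00,20.00,between
ECRL,3.31,30.17,88.00,20.00,minor
FCR,25.62,65.36,91.50,72.00,minor
FDSprox,52.07,75.39,91.50,72.00,between
FDSdist,74.38,71.50,91.50,72.00,between
FCU,13.22,85.13,91.50,72.00,minor
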