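# Default per-muscle ROI placement hints: synthetic plausible values, not from
# any published segmentation. azimuth_deg is measured counterclockwise
# (viewed elbow->wrist) from the reference line; depth_frac in [0,1] places the
# ROI centre between the muscle-layer centre (0) and the muscle-fat boundary
# (1); semi-axes approximate the muscle cross-section size class.
code,azimuth_deg,depth_frac,semi_a_mm,semi_b_mm
FCR,200,0.60,7.0,4.5
FCU,250,0.60,8.0,5.0
FDSdist,220,0.45,8.0,5.0
FDSprox,220,0.45,8.0,5.0
PL,210,0.60,5.0,3.5
PT,190,0.55,7.0,4.5
FDPdist,240,0.30,8.0,5.0
FDPprox,240,0.30,8.0,5.0
FPL,180,0.35,6.0,4.0
PQ,230,0.30,6.0,4.0
ECRB,130,0.60,7.0,4.5
ECRL,150,0.60,7.0,4.5
ECU,40,0.60,7.0,4.5
ED,70,0.60,8.0,5.0
EDM,55,0.55,5.0,3.5
APL,100,0.40,6.0,4.0
EI,60,0.35,5.0,3.5
EPB,110,0.40,5.0,3.5
EPL,90,0.40,5.0,3.5
SUP,140,0.35,6.0,4.0
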