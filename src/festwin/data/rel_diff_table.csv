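muscle,pw_range,ath,mean_rel_diff
ECU,20-200,0.05,0.171
ECU,20-200,0.10,0.139
ECU,20-200,0.15,0.120
ECU,20-200,0.20,0.083
ECU,20-200,0.25,0.050
ECU,20-200,0.30,0.030
ECU,20-200,0.35,0.031
ECU,20-200,0.40,0.087
ECU,20-200,0.45,0.159
ECU,20-200,0.50,0.330
ECU,201-500,0.05,0.054
ECU,201-500,0.10,0.028
ECU,201-500,0.15,0.025
ECU,201-500,0.20,0.010
ECU,201-500,0.25,0.026
ECU,201-500,0.30,0.052
ECU,201-500,0.35,0.079
ECU,201-500,0.40,0.107
ECU,201-500,0.45,0.160
ECU,201-500,0.50,0.266
ED,20-200,0.05,0.085
ED,20-200,0.10,0.041
ED,20-200,0.15,0.0272
ED,20-200,0.20,0.0270
ED,20-200,0.25,0.062
ED,20-200,0.30,0.124
ED,20-200,0.35,0.176
ED,20-200,0.40,0.253
ED,20-200,0.45,0.379
ED,20-200,0.50,0.719
ED,201-500,0.05,0.011
ED,201-500,0.10,0.034
ED,201-500,0.15,0.061
ED,201-500,0.20,0.069
ED,201-500,0.25,0.096
ED,201-500,0.30,0.145
ED,201-500,0.35,0.171
ED,201-500,0.40,0.225
ED,201-500,0.45,0.288
ED,201-500,0.50,0.478
ECRB,20-200,0.05,0.226
ECRB,20-200,0.10,0.146
ECRB,20-200,0.15,0.064
ECRB,20-200,0.20,0.025
ECRB,20-200,0.25,0.119
ECRB,20-200,0.30,0.222
ECRB,20-200,0.35,0.335
ECRB,20-200,0.40,0.486
ECRB,20-200,0.45,0.664
ECRB,20-200,0.50,0.931
ECRB,201-500,0.05,0.108
ECRB,201-500,0.10,0.052
ECRB,201-500,0.15,0.013
ECRB,201-500,0.20,0.046
ECRB,201-500,0.25,0.111
ECRB,201-500,0.30,0.190
ECRB,201-500,0.35,0.254
ECRB,201-500,0.40,0.364
ECRB,201-500,0.45,0.469
ECRB,201-500,0.50,0.589
ECRL,20-200,0.05,0.213
ECRL,20-200,0.10,0.177
ECRL,20-200,0.15,0.147
ECRL,20-200,0.20,0.118
ECRL,20-200,0.25,0.088
ECRL,20-200,0.30,0.062
ECRL,20-200,0.35,0.029
ECRL,20-200,0.40,0.040
ECRL,20-200,0.45,0.099
ECRL,20-200,0.50,0.175
ECRL,201-500,0.05,0.083
ECRL,201-500,0.10,0.059
ECRL,201-500,0.15,0.036
ECRL,201-500,0.20,0.014
ECRL,201-500,0.25,0.008
ECRL,201-500,0.30,0.013
ECRL,201-500,0.35,0.045
ECRL,201-500,0.40,0.084
ECRL,201-500,0.45,0.130
ECRL,201-500,0.50,0.180
FCU,20-200,0.05,0.093
FCU,20-200,0.10,0.038
FCU,20-200,0.15,0.022
FCU,20-200,0.20,0.029
FCU,20-200,0.25,0.076
FCU,20-200,0.30,0.119
FCU,20-200,0.35,0.172
FCU,20-200,0.40,0.236
FCU,20-200,0.45,0.359
FCU,20-200,0.50,0.515
FCU,201-500,0.05,0.013
FCU,201-500,0.10,0.018
FCU,201-500,0.15,0.042
FCU,201-500,0.20,0.071
FCU,201-500,0.25,0.101
FCU,201-500,0.30,0.130
FCU,201-500,0.35,0.160
FCU,201-500,0.40,0.194
FCU,201-500,0.45,0.274
FCU,201-500,0.50,0.640
FDSprox,20-200,0.05,0.045
FDSprox,20-200,0.10,0.062
FDSprox,20-200,0.15,0.186
FDSprox,20-200,0.20,0.294
FDSprox,20-200,0.25,0.468
FDSprox,20-200,0.30,0.748
FDSprox,20-200,0.35,0.911
FDSprox,20-200,0.40,1.367
FDSprox,20-200,0.45,2.173
FDSprox,20-200,0.50,26.652
FDSprox,201-500,0.05,0.020
FDSprox,201-500,0.10,0.095
FDSprox,201-500,0.15,0.179
FDSprox,201-500,0.20,0.241
FDSprox,201-500,0.25,0.371
FDSprox,201-500,0.30,0.483
FDSprox,201-500,0.35,0.634
FDSprox,201-500,0.40,0.762
FDSprox,201-500,0.45,0.900
FDSprox,201-500,0.50,1.071
FDSdist,20-200,0.05,0.170
FDSdist,20-200,0.10,0.096
FDSdist,20-200,0.15,0.044
FDSdist,20-200,0.20,0.050
FDSdist,20-200,0.25,0.144
FDSdist,20-200,0.30,0.242
FDSdist,20-200,0.35,0.369
FDSdist,20-200,0.40,0.517
FDSdist,20-200,0.45,0.713
FDSdist,20-200,0.50,0.937
FDSdist,201-500,0.05,0.045
FDSdist,201-500,0.10,0.017
FDSdist,201-500,0.15,0.054
FDSdist,201-500,0.20,0.105
FDSdist,201-500,0.25,0.159
FDSdist,201-500,0.30,0.226
FDSdist,201-500,0.35,0.304
FDSdist,201-500,0.40,0.362
FDSdist,201-500,0.45,0.479
FDSdist,201-500,0.50,0.613
FCR,20-200,0.05,0.084
FCR,20-200,0.10,0.043
FCR,20-200,0.15,0.013
FCR,20-200,0.20,0.042
FCR,20-200,0.25,0.073
FCR,20-200,0.30,0.117
FCR,20-200,0.35,0.202
FCR,20-200,0.40,0.291
FCR,20-200,0.45,0.409
FCR,20-200,0.50,0.616
FCR,201-500,0.05,0.025
FCR,201-500,0.10,0.005
FCR,201-500,0.15,0.033
FCR,201-500,0.20,0.062
FCR,201-500,0.25,0.082
FCR,201-500,0.30,0.105
FCR,201-500,0.35,0.167
FCR,201-500,0.40,0.229
FCR,201-500,0.45,0.294
FCR,201-500,0.50,0.429
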