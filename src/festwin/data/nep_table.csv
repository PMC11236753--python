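muscle_group,muscle_name,code,proximal_max_pct,median_pct,distal_max_pct,relative_bounds
Superficial flexors,Flexor carpi radialis,FCR,16,25,37,0
Superficial flexors,Flexor carpi ulnaris,FCU,6,13,51,0
Superficial flexors,Flexor digitorum superficialis,FDSdist,-5.5,74,5.5,1
Superficial flexors,Flexor digitorum superficialis,FDSprox,-5.5,51.5,5.5,1
Superficial flexors,Palmaris longus,PL,10,18,35,0
Superficial flexors,Pronator teres,PT,5,16,28,0
Deep flexors,Flexor digitorum profundus,FDPdist,-5.5,36.7,5.5,1
Deep flexors,Flexor digitorum profundus,FDPprox,-5.5,26.5,5.5,1
Deep flexors,Flexor pollicis longus,FPL,25,40,60,0
Deep flexors,Pronator quadratus,PQ,72,85,90,0
Radial extensors,Brachioradialis,BR,-17,-4,12,0
Radial extensors,Extensor carpi radialis brevis,ECRB,12,25,37,0
Radial extensors,Extensor carpi radialis longus,ECRL,-8,3,15,0
Superficial extensors,Extensor carpi ulnaris,ECU,25,33,43,0
Superficial extensors,Extensor digitorum,ED,17,33,52,0
Superficial extensors,Extensor digiti minimi,EDM,34,37,60,0
Deep extensors,Abductor pollicis longus,APL,34,40,52,0
Deep extensors,Extensor indicis,EI,56,65,87,0
Deep extensors,Extensor pollicis brevis,EPB,41,61,70,0
Deep extensors,Extensor pollicis longus,EPL,39,52,67,0
Deep extensors,Supinator,SUP,10,19,31,0
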