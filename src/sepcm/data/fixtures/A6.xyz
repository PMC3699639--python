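17
A6 CCCC[NH3+] charge=1 provenance=RDKit-ETKDG+MMFF94
C     -2.17108445     0.46622438    -1.04463868
C     -0.81993490     0.64812479    -0.36976357
C     -0.23032149    -0.69435647     0.06805836
C      1.07485477    -0.55932199     0.84257633
N      2.14365053    -0.00967176    -0.02413047
H     -2.89036729    -0.00046997    -0.36407856
H     -2.08249965    -0.16292489    -1.93608095
H     -2.57476310     1.43609419    -1.35181544
H     -0.93885554     1.30396513     0.50041627
H     -0.14448277     1.15274673    -1.06896133
H     -0.07684313    -1.33339576    -0.81046691
H     -0.95545898    -1.21023531     0.70960048
H      0.97840849     0.11283284     1.70031425
H      1.42558564    -1.53681278     1.18664477
H      1.94358021     0.95493088    -0.31885380
H      3.04518283     0.00804097     0.47099504
H      2.27334883    -0.57577098    -0.87322614
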