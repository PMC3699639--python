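11
O8 CC(=[OH+])C charge=1 provenance=RDKit-ETKDG+MMFF94
C      1.35174041    -0.40077698     0.20181757
C      0.05684572     0.33868589     0.14906598
O      0.01626909     1.54148436     0.61384039
C     -1.16547017    -0.29678837    -0.42798822
H      1.65206744    -0.67752673    -0.81186358
H      2.12081160     0.22811267     0.65546008
H      1.22457258    -1.31170639     0.79204551
H     -0.87363037     1.96412391     0.54376184
H     -2.01313398     0.38967682    -0.38250903
H     -0.97144354    -0.57080678    -1.46816085
H     -1.39862880    -1.20447841     0.13453029
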