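14
A4 CCC[NH3+] charge=1 provenance=RDKit-ETKDG+MMFF94
C      1.57248744     0.33838060     0.00199696
C      0.55982740    -0.79764381     0.00686172
C     -0.70426107    -0.48257332     0.79484541
N     -1.45716285     0.62150533     0.15445271
H      2.49110245     0.01984193    -0.50125329
H      1.83201642     0.63717070     1.02254914
H      1.19101927     1.21538586    -0.52926392
H      0.30447591    -1.05948040    -1.02684828
H      1.03264725    -1.68228126     0.44963295
H     -0.48443833    -0.16953540     1.81980578
H     -1.37558818    -1.34610082     0.81617578
H     -2.34813008     0.78909694     0.64056257
H     -1.68054221     0.40992678    -0.82717893
H     -0.93345342     1.50630688     0.17221551
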