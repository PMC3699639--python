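13
O4 C[OH+]CC charge=1 provenance=RDKit-ETKDG+MMFF94
C     -1.62755455     0.35772938     0.21932882
O     -0.57694649    -0.37728889     0.81153906
C      0.52795683    -0.64457525    -0.03614052
C      1.58527907     0.43392309     0.11496776
H     -2.09665354    -0.22876754    -0.57589762
H     -2.37685053     0.57465080     0.98580162
H     -1.25646192     1.30394165    -0.18324457
H     -0.91634563    -1.20648440     1.23759816
H      0.20544156    -0.73195398    -1.07944882
H      0.95260734    -1.61122948     0.25756076
H      1.92013957     0.51483173     1.15477373
H      1.20358165     1.41386742    -0.18983438
H      2.45580665     0.20135547    -0.50629883
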