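7
O1 C[OH2+] charge=1 provenance=RDKit-ETKDG+MMFF94
C     -0.56386093    -0.02132557     0.01067203
O      0.79890266     0.10496941    -0.30401867
H     -1.00960595    -0.79491168    -0.61900926
H     -0.67118286    -0.29701923     1.06254258
H     -1.06644548     0.93131778    -0.17236554
H      1.28217577    -0.75365145    -0.19388343
H      1.23001679     0.83062073     0.21606228
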