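10
O2 CC[OH2+] charge=1 provenance=RDKit-ETKDG+MMFF94
C     -1.13963673     0.05394942     0.06333427
C      0.26447079    -0.36048082    -0.32851700
O      1.20091924     0.57337662     0.15911420
H     -1.87018795    -0.66470056    -0.32072309
H     -1.38681752     1.04176768    -0.34040898
H     -1.24840232     0.10228977     1.15225215
H      0.35685221    -0.40698830    -1.41804374
H      0.50537097    -1.34589804     0.08225800
H      2.10909767     0.40099686    -0.19950494
H      1.20833365     0.60568735     1.15023914
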