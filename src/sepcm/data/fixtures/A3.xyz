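11
A3 CC[NH3+] charge=1 provenance=RDKit-ETKDG+MMFF94
C      1.21362776     0.28369461    -0.13413835
C      0.00406155    -0.30631201     0.55713427
N     -1.19982453    -0.05858589    -0.27003284
H      1.36809081    -0.17108622    -1.11822299
H      1.10270941     1.36433068    -0.27208614
H      2.11338403     0.10953566     0.46409249
H      0.09465909    -1.38942930     0.67629790
H     -0.17315893     0.15999144     1.53012207
H     -1.11690515    -0.49048727    -1.20008218
H     -1.36545968     0.94740580    -0.40769865
H     -2.04118437    -0.44905750     0.17461440
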