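11
A8 C[NH2+]C charge=1 provenance=RDKit-ETKDG+MMFF94
C     -1.22402130     0.29312398    -0.17703353
N     -0.02569432    -0.26111075     0.50705600
C      1.24528250    -0.07706563    -0.24253528
H     -1.33750251    -0.21530334    -1.13733542
H     -1.07819813     1.36777770    -0.30898371
H     -2.08591863     0.09839229     0.46492969
H     -0.17152784    -1.26481710     0.68194406
H      0.06424765     0.17461831     1.43513486
H      1.15483925    -0.58894527    -1.20344861
H      1.41414173     0.99413429    -0.37509572
H      2.04435161    -0.52080449     0.35536764
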