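14
A10 C[NH+](C)C charge=1 provenance=RDKit-ETKDG+MMFF94
C     -0.83506978    -1.16959411    -0.08653529
N     -0.04696956     0.08251265    -0.34619119
C      1.42652865    -0.12908042    -0.14537997
C     -0.56157901     1.24618463     0.45214363
H     -0.45454064    -1.95286219    -0.74736753
H     -1.88357473    -0.96433353    -0.31787077
H     -0.71247114    -1.44856273     0.96345487
H     -0.18160428     0.31902650    -1.33851620
H      1.60367989    -0.38295189     0.90319123
H      1.94201191     0.79573762    -0.41740878
H      1.74542760    -0.94070416    -0.80460675
H     -1.61753617     1.38561411     0.20612657
H      0.00808214     2.13352515     0.16383260
H     -0.43238489     1.02548837     1.51512758
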