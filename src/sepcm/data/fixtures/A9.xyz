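17
A9 CC[NH2+]CC charge=1 provenance=RDKit-ETKDG+MMFF94
C     -2.14610513     0.39664067    -1.08822782
C     -0.83955650     0.69532053    -0.38102241
N     -0.22751523    -0.59388178     0.06803026
C      1.02615747    -0.47215855     0.87447737
C      2.19439059    -0.07452400    -0.00462899
H     -2.85087201    -0.11015876    -0.42079301
H     -1.98519420    -0.24191392    -1.96308487
H     -2.61210885     1.32650537    -1.42881752
H     -1.00372721     1.31184781     0.50779312
H     -0.13452047     1.18623034    -1.05698796
H     -0.05296257    -1.19792741    -0.74744914
H     -0.91988015    -1.09891966     0.63866721
H      0.84396520     0.25003997     1.67611831
H      1.20047589    -1.45816538     1.31623112
H      2.06708607     0.93122233    -0.41591214
H      3.11979239    -0.07686012     0.58020727
H      2.32057470    -0.77329742    -0.83801117
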