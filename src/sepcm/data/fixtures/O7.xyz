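17
O7 C[OH+]c1ccccc1 charge=1 provenance=RDKit-ETKDG+MMFF94
C     -2.54140299     0.35412861     0.00121276
O     -1.52263159     0.14550609    -0.95268831
C     -0.22379945    -0.01957761    -0.41616735
C      0.30834926    -1.30825930    -0.30950427
C      1.59490768    -1.48741695     0.19892974
C      2.34882003    -0.38379759     0.59541170
C      1.82139115     0.90220505     0.48493562
C      0.53526266     1.08988495    -0.02296774
H     -3.50519650     0.36088206    -0.51637922
H     -2.40913640     1.31776911     0.50227264
H     -2.55201887    -0.45357675     0.73946261
H     -1.53860474     0.81996224    -1.67772610
H     -0.25967431    -2.18558617    -0.61425280
H      2.01609772    -2.48795043     0.28810071
H      3.35304128    -0.52724536     0.99276369
H      2.42027473     1.75636418     0.79871210
H      0.15432032     2.10670788    -0.09211579
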