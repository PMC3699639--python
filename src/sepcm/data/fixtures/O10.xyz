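12
O10 COC(=[OH+])C charge=1 provenance=RDKit-ETKDG+MMFF94
C     -1.81192601    -0.35682348    -0.12926967
O     -0.42747938    -0.68669757    -0.27362598
C      0.50039960     0.21964290     0.08456297
O      0.28069608     1.39301352     0.55981822
C      1.90085211    -0.24166417    -0.11294874
H     -2.04438782    -0.16299597     0.92181232
H     -2.40348286    -1.21096909    -0.46912934
H     -2.05795338     0.51085806    -0.74812485
H     -0.67232104     1.60577876     0.65340728
H      2.06410636    -0.47336545    -1.16852064
H      2.59398088     0.54333972     0.19819152
H      2.07751546    -1.14011724     0.48382691
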