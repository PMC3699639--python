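23
O9 CC(C)C(=[OH+])C(C)C charge=1 provenance=RDKit-ETKDG+MMFF94
C     -2.11048969    -0.49367832    -0.61541902
C     -1.38547944     0.14418891     0.56276513
C     -1.43128538     1.66570651     0.50345680
C      0.04300737    -0.34642516     0.64247030
O      0.43608345    -1.00813709     1.68090289
C      1.04985008    -0.09440266    -0.45510136
C      2.20821111     0.72238968     0.10415860
C      1.53152639    -1.42899740    -1.01058864
H     -1.69149194    -0.17158902    -1.57447694
H     -3.17227934    -0.22599495    -0.60686077
H     -2.03573432    -1.58574176    -0.57312865
H     -1.88982871    -0.17388405     1.48279333
H     -0.87504900     2.10447627     1.33895626
H     -2.46462101     2.02385751     0.55886565
H     -0.99245947     2.05076529    -0.42296148
H     -0.26700249    -1.13964956     2.36150799
H      0.57463163     0.47285095    -1.26139394
H      1.85137286     1.67476838     0.51114174
H      2.94342365     0.94160065    -0.67698036
H      2.72004408     0.19093572     0.91424523
H      2.02067702    -2.03254099    -0.23785084
H      2.24571851    -1.27664510    -1.82636349
H      0.69117465    -2.01385380    -1.40013842
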