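14
O5 C1C[OH+]CC1 charge=1 provenance=RDKit-ETKDG+MMFF94
C     -0.90596107     0.76069337    -0.09664233
C     -1.03233493    -0.75124297    -0.02717772
O      0.26281080    -1.24887282    -0.34193032
C      1.22901248    -0.20608774    -0.28272722
C      0.51761369     0.96807902     0.36787913
H     -1.64200782     1.27541390     0.52677052
H     -1.02397252     1.10820379    -1.13016804
H     -1.30263855    -1.08222984     0.98166166
H     -1.76436062    -1.13796942    -0.74076622
H      0.51114829    -2.01742711     0.23378426
H      2.10477671    -0.52570396     0.28885779
H      1.53666146     0.03122349    -1.30654226
H      0.57614416     0.89247128     1.46046025
H      0.93310794     1.93344903     0.06654049
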