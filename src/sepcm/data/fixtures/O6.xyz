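16
O6 CC[OH+]CC charge=1 provenance=RDKit-ETKDG+MMFF94
C     -2.10828880     0.03418627     0.58056908
C     -1.05945517    -0.98281639     0.16646003
O      0.25537332    -0.51574295     0.41608899
C      0.81456221     0.32048682    -0.58154262
C      2.28358631     0.55983856    -0.27990179
H     -2.02817079     0.95443068    -0.00683813
H     -2.00469232     0.30157575     1.63763041
H     -3.11214467    -0.37526054     0.43015826
H     -1.17505368    -1.25268476    -0.88878745
H     -1.19369696    -1.89989473     0.75071622
H      0.34628747    -0.12795691     1.32464546
H      0.27976859     1.27547684    -0.60127700
H      0.71870867    -0.15804665    -1.56202915
H      2.41315804     1.05117218     0.69052406
H      2.83955049    -0.38361084    -0.25366058
H      2.73050727     1.19884667    -1.04779795
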