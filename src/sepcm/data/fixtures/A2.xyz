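8
A2 C[NH3+] charge=1 provenance=RDKit-ETKDG+MMFF94
C      0.75022630     0.05147017    -0.04157822
N     -0.71972876    -0.04937784     0.03988811
H      1.15055816    -0.08466125     0.96481650
H      0.99595042     1.04110018    -0.43129635
H      1.10205986    -0.73356696    -0.71355870
H     -1.11072058     0.66953812     0.66288697
H     -1.01292884    -0.96600450     0.40275349
H     -1.15541655     0.07150207    -0.88391180
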