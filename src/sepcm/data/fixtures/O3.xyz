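10
O3 C[OH+]C charge=1 provenance=RDKit-ETKDG+MMFF94
C      1.16025311    -0.02809463     0.28114721
O      0.08307242    -0.26972165    -0.59821105
C     -1.19269516    -0.04556258    -0.03772604
H      1.17685292     1.02386734     0.58026363
H      1.07893229    -0.66695808     1.16506560
H      2.09461618    -0.26371612    -0.23591570
H      0.19506369     0.22341138    -1.45160036
H     -1.30362727     1.00544591     0.24413396
H     -1.95221066    -0.29373015    -0.78435480
H     -1.34025751    -0.68494143     0.83719757
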