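14
A5 CC([NH3+])C charge=1 provenance=RDKit-ETKDG+MMFF94
C     -0.81158522    -1.19351493    -0.06538137
C     -0.03723051     0.06577146    -0.42028726
N      1.38604444    -0.13011052    -0.03107699
C     -0.56995052     1.29274748     0.30229201
H     -0.40215179    -2.06550650    -0.58678437
H     -1.86268504    -1.09398534    -0.35604339
H     -0.77737894    -1.39743991     1.01056827
H     -0.04155460     0.22634215    -1.50324289
H      1.79946846    -0.93916025    -0.51393518
H      1.95783653     0.69036778    -0.27295176
H      1.48870394    -0.28966021     0.98032861
H     -1.61245448     1.48072504     0.02470890
H      0.01086433     2.18414685     0.04166697
H     -0.52792661     1.16927690     1.39013844
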