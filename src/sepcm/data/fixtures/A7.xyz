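17
A7 CC([NH3+])(C)C charge=1 provenance=RDKit-ETKDG+MMFF94
C     -0.93693910     0.22714768    -1.19607143
C     -0.02252621     0.01069988     0.00882438
N      1.25206557    -0.59472655    -0.49048944
C     -0.64292775    -0.96856645     1.00427095
C      0.32625417     1.33688030     0.68289589
H     -0.47885327     0.90003907    -1.92995311
H     -1.89040717     0.67086270    -0.88837296
H     -1.15908793    -0.71808600    -1.70439335
H      1.08657560    -1.49633573    -0.95833178
H      1.91655337    -0.76718977     0.27624042
H      1.72337543     0.01845300    -1.16948877
H     -1.58401087    -0.57519225     1.40462275
H     -0.86013223    -1.93394552     0.53302484
H      0.02647403    -1.15506627     1.85181230
H      1.01198447     1.18923261     1.52502538
H      0.80562552     2.02846817    -0.01932720
H     -0.57402363     1.82732512     1.06971114
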